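"""PDB parsing, rigid superposition, complex assembly, contact detection."""

import numpy as np
import pytest

from garpbind import (
    AlignmentMap,
    Atom,
    StructureModel,
    build_complex,
    compare_contact_maps,
    find_contacts,
    read_structure,
    superpose,
    write_structure,
)
from garpbind.synthetic import generate_toy_complex

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      3  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       8.000   8.000   8.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.50  0.00           C
ATOM      2  CA BALA A   1       1.500   2.500   3.500  0.50  0.00           C
ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
END
"""


def toy_model(seed=0, **kw):
    return generate_toy_complex(8, 30, {3, 7}, seed=seed, **kw)


def quaternion_superpose_rmsd(P, Q):
    """Independent Horn quaternion-method superposition oracle."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    Sxx = P.T @ Q
    K = np.empty((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    ssd = (P**2).sum() + (Q**2).sum() - 2.0 * lam
    return np.sqrt(max(ssd, 0.0) / len(P))


class TestReadWrite:
    def test_model_selection(self):
        m1 = read_structure(TWO_MODEL_PDB, model=1)
        m2 = read_structure(TWO_MODEL_PDB, model=2)
        assert len(m1.atoms) == 2 and len(m2.atoms) == 2
        assert m1.atoms[0].x == 1.0 and m2.atoms[0].x == 9.0

    def test_missing_model_lists_available(self):
        with pytest.raises(ValueError, match=r"available models: \[1, 2\]"):
            read_structure(TWO_MODEL_PDB, model=5)

    def test_altloc_resolved_to_one_conformer(self):
        m = read_structure(ALTLOC_PDB)
        assert len(m.atoms) == 2
        assert m.atoms[0].x == 1.0  # conformer A kept

    def test_round_trip_at_pdb_precision(self):
        toy = toy_model()
        comp = StructureModel(atoms=toy.protein.atoms + toy.dna.atoms)
        back = read_structure(write_structure(comp))
        assert len(back.atoms) == len(comp.atoms)
        assert np.abs(back.coords() - comp.coords()).max() < 1e-3
        assert [a.chain for a in back.atoms] == [a.chain for a in comp.atoms]

    def test_hydrogen_detection_via_element_and_name(self):
        assert Atom("A", 1, "ALA", "HB2", "H", 0, 0, 0).is_hydrogen
        assert Atom("A", 1, "ALA", "1HB", "", 0, 0, 0).is_hydrogen
        assert not Atom("A", 1, "ALA", "CA", "C", 0, 0, 0).is_hydrogen
        # blank element: HG here would be a sidechain hydrogen name
        assert not Atom("A", 1, "HIS", "CG", "", 0, 0, 0).is_hydrogen


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        toy = toy_model()
        amap = AlignmentMap.identity(toy.protein, "P")
        res = superpose(toy.protein, toy.protein, amap)
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovery(self):
        toy = toy_model(apply_transform=True)
        amap = AlignmentMap.identity(toy.protein, "P")
        res = superpose(toy.protein, toy.protein_reference, amap)
        assert res.rmsd < 1e-6
        # recovered transform inverts the applied one
        assert np.allclose(res.rotation @ toy.rotation, np.eye(3), atol=1e-6)

    def test_matches_quaternion_oracle_on_perturbed_copy(self, rng):
        toy = toy_model()
        P = np.array([a.coords for a in toy.protein.atoms if a.name == "CA"])
        Q = P + rng.normal(0, 0.5, P.shape)
        target_atoms = [
            Atom("P", i + 1, "ALA", "CA", "C", *Q[i]) for i in range(len(Q))
        ]
        target = StructureModel(atoms=target_atoms)
        amap = AlignmentMap.identity(toy.protein, "P")
        res = superpose(toy.protein, target, amap)
        assert res.rmsd == pytest.approx(quaternion_superpose_rmsd(P, Q), rel=1e-6)

    def test_too_few_pairs(self):
        toy = toy_model()
        amap = AlignmentMap([(("P", 1), ("P", 1)), (("P", 2), ("P", 2))])
        with pytest.raises(ValueError, match=">= 3"):
            superpose(toy.protein, toy.protein, amap)

    def test_missing_ca_named(self):
        toy = toy_model()
        amap = AlignmentMap([(("P", 1), ("P", 1)), (("P", 2), ("P", 2)),
                             (("P", 99), ("P", 3))])
        with pytest.raises(ValueError, match="P99"):
            superpose(toy.protein, toy.protein, amap)

    def test_duplicate_residues_rejected(self):
        with pytest.raises(ValueError):
            AlignmentMap([(("P", 1), ("P", 1)), (("P", 1), ("P", 2)),
                          (("P", 3), ("P", 3))])


class TestBuildComplex:
    def test_self_mapping_preserves_contacts(self):
        toy = toy_model()
        ref = StructureModel(atoms=toy.protein.atoms + toy.dna.atoms)
        amap = AlignmentMap.identity(toy.protein, "P")
        built = build_complex(toy.protein, ref, amap, {"D"})
        direct = find_contacts(ref, {"P"}, {"D"})
        rebuilt = find_contacts(built, built.chains() - {"D"}, {"D"})
        assert rebuilt.residue_numbers == direct.residue_numbers

    def test_transformed_protein_recovers_planted_contacts(self):
        toy = toy_model(apply_transform=True)
        ref = StructureModel(atoms=toy.protein_reference.atoms + toy.dna.atoms)
        amap = AlignmentMap.identity(toy.protein, "P")
        built = build_complex(toy.protein, ref, amap, {"D"})
        cmap = find_contacts(built, built.chains() - {"D"}, {"D"})
        assert cmap.residue_numbers == toy.contact_truth

    def test_chain_collision_renamed_and_recorded(self):
        toy = toy_model()
        # rename the DNA chain to collide with the protein chain id
        from dataclasses import replace

        dna = StructureModel(
            atoms=[replace(a, chain="P") for a in toy.dna.atoms]
        )
        ref = StructureModel(atoms=toy.protein.atoms + dna.atoms)
        amap = AlignmentMap.identity(toy.protein, "P")
        built = build_complex(toy.protein, ref, amap, {"P"})
        assert built.chain_renames  # the protein chain had to move
        new_chain = built.chain_renames["P"]
        cmap = find_contacts(built, {new_chain}, {"P"})
        assert cmap.residue_numbers == toy.contact_truth

    def test_empty_dna_chains_rejected(self):
        toy = toy_model()
        ref = StructureModel(atoms=toy.protein.atoms + toy.dna.atoms)
        amap = AlignmentMap.identity(toy.protein, "P")
        with pytest.raises(ValueError):
            build_complex(toy.protein, ref, amap, set())


def pair_complex(distance: float) -> StructureModel:
    atoms = [
        Atom("B", 1, "DA", "C1'", "C", 0.0, 0.0, 0.0),
        Atom("A", 1, "ALA", "CA", "C", distance, 0.0, 0.0),
    ]
    return StructureModel(atoms=atoms)


class TestFindContacts:
    def test_below_threshold_is_contact(self):
        cmap = find_contacts(pair_complex(3.9), {"A"}, {"B"})
        assert cmap.residue_numbers == {1}
        assert cmap.residues[("A", 1, "ALA")] == pytest.approx(3.9)

    def test_exactly_at_threshold_is_not(self):
        # strict inequality: a pair at exactly 4.0 A did not fall below it
        assert find_contacts(pair_complex(4.0), {"A"}, {"B"}).residues == {}

    def test_hydrogens_ignored_on_both_sides(self):
        atoms = pair_complex(6.0).atoms + [
            Atom("A", 1, "ALA", "HA", "H", 1.0, 0.0, 0.0),
            Atom("B", 1, "DA", "H1'", "H", 5.5, 0.0, 0.0),
        ]
        cmap = find_contacts(StructureModel(atoms=atoms), {"A"}, {"B"})
        assert cmap.residues == {}

    def test_monotone_in_threshold(self):
        toy = toy_model(seed=4)
        comp = StructureModel(atoms=toy.protein.atoms + toy.dna.atoms)
        sets = [
            find_contacts(comp, {"P"}, {"D"}, threshold=t).residue_numbers
            for t in (3.0, 4.0, 6.0, 10.0)
        ]
        for small, big in zip(sets, sets[1:]):
            assert small <= big

    def test_matches_brute_force_oracle(self):
        toy = toy_model(seed=5)
        comp = StructureModel(atoms=toy.protein.atoms + toy.dna.atoms)
        expected = set()
        dna = [a for a in comp.atoms if a.chain == "D" and not a.is_hydrogen]
        for a in comp.atoms:
            if a.chain != "P" or a.is_hydrogen:
                continue
            for b in dna:
                if np.linalg.norm(a.coords - b.coords) < 4.0:
                    expected.add(a.resnum)
        assert find_contacts(comp, {"P"}, {"D"}).residue_numbers == expected

    def test_no_dna_raises(self):
        prot = StructureModel(atoms=[Atom("A", 1, "ALA", "CA", "C", 0, 0, 0)])
        with pytest.raises(ValueError, match="no DNA"):
            find_contacts(prot, {"A"}, {"B"})


class TestCompareMaps:
    def _cmap(self, residues):
        from garpbind.structure import ContactMap

        return ContactMap({("A", r, "ALA"): 3.5 for r in residues})

    def test_identical_maps_all_agree(self):
        maps = [("x", self._cmap({3, 7})), ("y", self._cmap({3, 7}))]
        cols = [{"x": ("A", r), "y": ("A", r)} for r in (3, 5, 7)]
        table = compare_contact_maps(maps, cols)
        assert table["all_agree"].all()

    def test_partial_overlap(self):
        maps = [("x", self._cmap({3, 7})), ("y", self._cmap({7, 9}))]
        cols = [{"x": ("A", r), "y": ("A", r)} for r in (3, 7, 9)]
        table = compare_contact_maps(maps, cols)
        assert list(table["all_agree"]) == [False, True, False]
        assert list(table["x"]) == [True, True, False]

    def test_three_protein_fixture(self):
        maps = [
            ("p1", self._cmap({1, 2})),
            ("p2", self._cmap({2})),
            ("p3", self._cmap({2, 3})),
        ]
        cols = [
            {"p1": ("A", 1), "p2": ("A", 1), "p3": ("A", 1)},
            {"p1": ("A", 2), "p2": ("A", 2), "p3": ("A", 2)},
            {"p1": ("A", 3), "p2": None, "p3": ("A", 3)},
        ]
        table = compare_contact_maps(maps, cols)
        assert list(table["all_agree"]) == [False, True, False]
        assert list(table["p3"]) == [False, True, True]
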