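"""Structure superposition and protein--DNA contact mapping.

Rigid-body, RMSD-minimizing superposition over aligned C-alpha pairs
assembles protein--DNA complexes by mapping a protein onto the protein
chain of a reference complex and borrowing the reference's DNA.  A protein
residue counts as a DNA contact when the minimum Euclidean distance between
its heavy atoms and any DNA heavy atom falls strictly below a threshold
(default 4.0 A); hydrogens and deuteriums are ignored on both sides, and the
strict inequality follows the "fell below" reading of the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Residue names recognized as DNA (PDB v3 plus legacy single-letter).
DNA_RESNAMES = {"DA", "DC", "DG", "DT", "DI", "DU", "A", "C", "G", "T", "I", "U"}

WATER_RESNAMES = {"HOH", "WAT", "DOD"}


@dataclass
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float
    het: bool = False

    @property
    def is_hydrogen(self) -> bool:
        el = self.element.strip().upper()
        if el:
            return el in {"H", "D"}
        # fallback: digit-stripped atom name starting with H or D
        stripped = self.name.strip().lstrip("0123456789")
        return stripped[:1].upper() in {"H", "D"}

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class StructureModel:
    """A flat list of atoms with chain/residue identity."""

    atoms: list
    model_number: int = 1
    label: str = ""
    chain_renames: dict = field(default_factory=dict)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def chains(self) -> set:
        return {a.chain for a in self.atoms}

    def select(self, chains=None, heavy_only=False, include_het=True):
        out = []
        for a in self.atoms:
            if chains is not None and a.chain not in chains:
                continue
            if heavy_only and a.is_hydrogen:
                continue
            if not include_het and a.het:
                continue
            out.append(a)
        return out

    def ca_atom(self, chain: str, resnum: int):
        for a in self.atoms:
            if a.chain == chain and a.resnum == resnum and a.name.strip() == "CA":
                return a
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        """New model with coordinates x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        xyz = self.coords() @ R.T + t
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return StructureModel(atoms=atoms, model_number=self.model_number,
                              label=self.label)


def read_structure(pdb_text: str, model: int = 1) -> StructureModel:
    """Parse PDB text, keeping one MODEL and one altloc per atom group.

    Only the requested MODEL's atoms are kept (a file without MODEL records
    counts as model 1); alternate locations are resolved to the blank or 'A'
    conformer.  The element comes from the element column, with an
    atom-name heuristic as fallback.  Parsing is delegated to gemmi.
    """
    import gemmi

    st = gemmi.read_pdb_string(pdb_text)
    available = [m.num for m in st]
    if not available:
        raise ValueError("no models in PDB input")
    chosen = None
    for m in st:
        if m.num == model:
            chosen = m
            break
    if chosen is None:
        raise ValueError(f"model {model} not found; available models: {available}")
    atoms = []
    for chain in chosen:
        for res in chain:
            for at in res:
                if at.altloc not in ("\0", "", "A"):
                    continue
                el = at.element.name if at.element else ""
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name.strip(),
                        name=at.name,
                        element=el,
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        het=res.het_flag == "H",
                    )
                )
    return StructureModel(atoms=atoms, model_number=model, label=st.name or "")


def write_structure(model: StructureModel) -> str:
    """Serialize to minimal fixed-column PDB ATOM/HETATM records."""
    lines = []
    serial = 1
    for a in model.atoms:
        rec = "HETATM" if a.het else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        el = (a.element or "").strip().rjust(2)[:2]
        lines.append(
            f"{rec}{serial:5d} {name:<4s} {a.resname:<3s} {a.chain[:1]}"
            f"{a.resnum:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {el}"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class AlignmentMap:
    """Ordered residue correspondences used for C-alpha superposition."""

    pairs: list  # [((mobile_chain, mobile_resnum), (target_chain, target_resnum))]

    def __post_init__(self):
        mob = [p[0] for p in self.pairs]
        tgt = [p[1] for p in self.pairs]
        if len(set(mob)) != len(mob) or len(set(tgt)) != len(tgt):
            raise ValueError("duplicate residues in alignment map")

    @classmethod
    def from_tsv(cls, path) -> "AlignmentMap":
        df = pd.read_csv(path, sep="\t")
        need = {"mobile_chain", "mobile_resnum", "target_chain", "target_resnum"}
        if not need <= set(df.columns):
            raise ValueError(f"alignment map needs columns {sorted(need)}")
        pairs = [
            ((str(r.mobile_chain), int(r.mobile_resnum)),
             (str(r.target_chain), int(r.target_resnum)))
            for r in df.itertuples(index=False)
        ]
        return cls(pairs)

    @classmethod
    def identity(cls, model: StructureModel, chain: str) -> "AlignmentMap":
        resnums = sorted(
            {a.resnum for a in model.atoms if a.chain == chain and a.name == "CA"}
        )
        return cls([((chain, r), (chain, r)) for r in resnums])


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float  # A, over the mapped C-alpha pairs after transformation
    transformed: StructureModel
    n_pairs: int


def superpose(
    mobile: StructureModel, target: StructureModel, amap: AlignmentMap
) -> SuperpositionResult:
    """Least-squares rigid superposition (proper rotation) on mapped CAs."""
    from scipy.spatial.transform import Rotation

    if len(amap.pairs) < 3:
        raise ValueError("need >= 3 aligned residue pairs")
    mob_pts, tgt_pts, missing = [], [], []
    for (mc, mr), (tc, tr) in amap.pairs:
        am = mobile.ca_atom(mc, mr)
        at = target.ca_atom(tc, tr)
        if am is None:
            missing.append(f"mobile {mc}{mr}")
        if at is None:
            missing.append(f"target {tc}{tr}")
        if am is not None and at is not None:
            mob_pts.append(am.coords)
            tgt_pts.append(at.coords)
    if missing:
        raise ValueError("missing C-alpha atoms: " + ", ".join(missing))
    P = np.array(mob_pts)
    Q = np.array(tgt_pts)
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - qc, P - pc)
    R = rot.as_matrix()
    t = qc - R @ pc
    moved = (P - pc) @ R.T + qc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd,
        transformed=mobile.transformed(R, t), n_pairs=len(mob_pts),
    )


def build_complex(
    protein: StructureModel,
    reference_complex: StructureModel,
    amap: AlignmentMap,
    dna_chains: set,
) -> StructureModel:
    """Superpose ``protein`` onto the reference's protein chain and add the
    reference's DNA chains unchanged.

    Chain-id collisions between the incoming protein and the reference DNA
    are resolved by renaming the protein chain; the applied renames are
    recorded in the result's ``chain_renames``.
    """
    dna_chains = set(dna_chains)
    if not dna_chains:
        raise ValueError("dna_chains must not be empty")
    missing = dna_chains - reference_complex.chains()
    if missing:
        raise ValueError(f"reference complex lacks DNA chains {sorted(missing)}")
    sup = superpose(protein, reference_complex, amap)
    moved = sup.transformed
    renames = {}
    used = set(dna_chains)
    alphabet = "PQRSTUVWXYZABCDEFGHIJKLMNO0123456789"
    atoms = []
    for a in moved.atoms:
        chain = a.chain
        if chain in used:
            if chain not in renames:
                new = next(c for c in alphabet if c not in used and c not in
                           renames.values())
                renames[chain] = new
            chain = renames[chain]
        atoms.append(replace(a, chain=chain))
    for a in reference_complex.atoms:
        if a.chain in dna_chains:
            atoms.append(replace(a))
    out = StructureModel(atoms=atoms, label=f"complex[{protein.label}]")
    out.chain_renames = renames
    return out


@dataclass
class ContactMap:
    """Protein residues in contact with DNA, with minimum distances (A)."""

    residues: dict  # (chain, resnum, resname) -> min heavy-atom distance
    threshold: float = 4.0
    label: str = ""

    @property
    def residue_numbers(self) -> set:
        return {key[1] for key in self.residues}

    def to_frame(self) -> pd.DataFrame:
        rec = [
            {"chain": c, "resnum": n, "resname": rn, "min_dist_A": d}
            for (c, n, rn), d in sorted(self.residues.items(),
                                        key=lambda kv: (kv[0][0], kv[0][1]))
        ]
        return pd.DataFrame.from_records(
            rec, columns=["chain", "resnum", "resname", "min_dist_A"]
        )


def find_contacts(
    complex_model: StructureModel,
    protein_chains: set,
    dna_chains: set,
    threshold: float = 4.0,
    include_het: bool = False,
) -> ContactMap:
    """Protein residues whose heavy atoms come strictly closer than
    ``threshold`` A to any DNA heavy atom.

    DNA residues are identified by residue name within ``dna_chains``;
    waters and (by default) non-standard HETATM residues are excluded on
    both sides.  Distances use a KD-tree over the DNA heavy atoms.
    """
    from scipy.spatial import cKDTree

    def keep(a: Atom) -> bool:
        if a.resname in WATER_RESNAMES or a.is_hydrogen:
            return False
        if a.het and not include_het:
            return False
        return True

    dna_atoms = [
        a for a in complex_model.atoms
        if a.chain in dna_chains and a.resname in DNA_RESNAMES
        and not a.is_hydrogen and a.resname not in WATER_RESNAMES
    ]
    if not dna_atoms:
        raise ValueError(f"no DNA residues found in chains {sorted(dna_chains)}")
    prot_atoms = [
        a for a in complex_model.atoms
        if a.chain in protein_chains and a.resname not in DNA_RESNAMES and keep(a)
    ]
    tree = cKDTree(np.array([[a.x, a.y, a.z] for a in dna_atoms]))
    dists, _ = tree.query(np.array([[a.x, a.y, a.z] for a in prot_atoms]))
    residues: dict = {}
    for a, d in zip(prot_atoms, dists):
        key = (a.chain, a.resnum, a.resname)
        if d < residues.get(key, np.inf):
            residues[key] = float(d)
    contacts = {k: d for k, d in residues.items() if d < threshold}
    return ContactMap(residues=contacts, threshold=threshold,
                      label=complex_model.label)


def compare_contact_maps(maps: list, alignment_columns: list) -> pd.DataFrame:
    """Per-alignment-column contact annotation across several proteins.

    ``maps`` is a list of (label, ContactMap); ``alignment_columns`` is a
    list of dicts mapping each label to the (chain, resnum) occupying that
    column (or None for a gap).  The result is the table behind a
    contact-emphasis alignment figure: one row per column, one boolean
    contact flag per protein, plus an all-agree flag.
    """
    labels = [lbl for lbl, _ in maps]
    bykey = {
        lbl: {(c, n) for (c, n, _rn) in cmap.residues} for lbl, cmap in maps
    }
    rows = []
    for i, col in enumerate(alignment_columns):
        row = {"column": i}
        flags = []
        for lbl in labels:
            res = col.get(lbl)
            flag = bool(res is not None and tuple(res) in bykey[lbl])
            row[lbl] = flag
            flags.append(flag)
        row["all_agree"] = len(set(flags)) == 1
        rows.append(row)
    return pd.DataFrame.from_records(rows)
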