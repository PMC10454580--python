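"""Seeded synthetic inputs for the whole pipeline.

Raw MST traces, FCS curves, promoter sequences and protein--DNA complexes
from the original experiments are not publicly deposited, so every
downstream stage is exercised on synthetic inputs with the statistical
structure those stages assume:

* MST time traces with a temperature-jump quench, an exponential-approach
  thermophoretic depletion, and laser-off recovery, mixed linearly between
  bound and free amplitudes by the 1:1 fraction bound;
* 16-capillary 1:3 serial titrations at fixed labeled-protein
  concentration;
* single/multi-component 3D-diffusion FCS autocorrelation curves;
* random promoter sequences with an exact planted count of CRM/ECRM motifs;
* toy protein--DNA coordinate sets with known contact residues.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import binding
from .mst import MSTTrace


@dataclass
class TraceParams:
    """Phenomenological parameters of a synthetic MST time trace.

    The defaults describe the study conditions emulated throughout: a
    700-count baseline, a fast (tau ~ 0.25 s) temperature-jump quench whose
    amplitude differs slightly between free (5%) and bound (8%) protein, a
    slow (tau ~ 8 s) thermophoretic depletion with a larger bound/free
    contrast (10% vs 22%, giving per-mille binding-curve spans of a few tens
    to ~100, comparable to typical MST data), back diffusion slower than
    depletion (tau ~ 12 s), ~1% Gaussian counting noise, and 10 Hz sampling
    over a 5 s / 30 s / 5 s laser cycle.
    """

    baseline_fluorescence: float = 700.0  # counts
    tj_amp_free: float = 0.05     # T-jump fractional quench, free state
    tj_amp_bound: float = 0.08    # T-jump fractional quench, bound state
    tmf_amp_free: float = 0.10    # thermophoretic fractional depletion, free
    tmf_amp_bound: float = 0.22   # thermophoretic fractional depletion, bound
    tau_tj: float = 0.25          # s, T-jump time constant (also inverse T-jump)
    tau_tmf: float = 8.0          # s, thermophoresis time constant
    tau_bd: float = 12.0          # s, back-diffusion time constant
    noise_sd: float = 7.0         # counts
    sampling_rate: float = 10.0   # Hz
    t_laser_on: float = 5.0       # s
    t_laser_off: float = 35.0     # s
    t_end: float = 40.0           # s
    seed: int = 0

    def __post_init__(self):
        for name in ("tj_amp_free", "tj_amp_bound", "tmf_amp_free", "tmf_amp_bound"):
            a = getattr(self, name)
            if not (0.0 <= a < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("tau_tj", "tau_tmf", "tau_bd", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.t_laser_on < self.t_laser_off < self.t_end):
            raise ValueError("need t_laser_on < t_laser_off < t_end")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def trace_model(t: np.ndarray, params: TraceParams, fraction_bound: float) -> np.ndarray:
    """Noiseless piecewise trace model m(t).

    Before laser-on the signal sits at the baseline F0.  During heating two
    multiplicative factors act: a T-jump quench 1 - A_TJ*(1 - e^{-dt/tau_TJ})
    and a thermophoretic depletion 1 - A_T*(1 - e^{-dt/tau_TMF}), with each
    amplitude mixed linearly between the free and bound values by the
    fraction bound (fast-exchange, single-population approximation).  After
    laser-off both factors relax back toward 1, the T-jump with tau_TJ
    (inverse T-jump) and the depletion with tau_BD (back diffusion).
    """
    fb = float(fraction_bound)
    if not (0.0 <= fb <= 1.0):
        raise ValueError("fraction_bound must be in [0, 1]")
    p = params
    a_tj = (1.0 - fb) * p.tj_amp_free + fb * p.tj_amp_bound
    a_t = (1.0 - fb) * p.tmf_amp_free + fb * p.tmf_amp_bound
    t = np.asarray(t, dtype=float)
    f1 = np.ones_like(t)
    f2 = np.ones_like(t)
    on = (t >= p.t_laser_on) & (t < p.t_laser_off)
    dt_on = t[on] - p.t_laser_on
    f1[on] = 1.0 - a_tj * (1.0 - np.exp(-dt_on / p.tau_tj))
    f2[on] = 1.0 - a_t * (1.0 - np.exp(-dt_on / p.tau_tmf))
    off = t >= p.t_laser_off
    span_on = p.t_laser_off - p.t_laser_on
    d1 = a_tj * (1.0 - np.exp(-span_on / p.tau_tj))
    d2 = a_t * (1.0 - np.exp(-span_on / p.tau_tmf))
    dt_off = t[off] - p.t_laser_off
    f1[off] = 1.0 - d1 * np.exp(-dt_off / p.tau_tj)
    f2[off] = 1.0 - d2 * np.exp(-dt_off / p.tau_bd)
    return p.baseline_fluorescence * f1 * f2


def simulate_trace(
    params: TraceParams,
    fraction_bound: float,
    ligand_conc: float = 0.0,
    replicate_id: int = 0,
    capillary_id: int = 0,
    rng: np.random.Generator | None = None,
) -> MSTTrace:
    """One capillary's trace: :func:`trace_model` plus Gaussian noise.

    The same ``params.seed`` always yields a bit-identical trace (unless an
    explicit ``rng`` is supplied, as the titration simulator does to derive
    per-replicate sub-streams).
    """
    p = params
    n = int(round(p.t_end * p.sampling_rate))
    t = np.arange(n) / p.sampling_rate
    m = trace_model(t, p, fraction_bound)
    if p.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(p.seed)
        m = m + rng.normal(0.0, p.noise_sd, size=n)
    return MSTTrace(
        time=t, fluorescence=m, t_laser_on=p.t_laser_on,
        t_laser_off=p.t_laser_off, ligand_conc=ligand_conc,
        replicate_id=replicate_id, capillary_id=capillary_id,
    )


@dataclass
class TitrationDesign:
    """Serial-dilution layout of an MST titration.

    16 capillaries, a 1:3 serial dilution of the ligand (span 3^15, about
    seven orders of magnitude) and 250 nM labeled protein throughout, with
    three replicate traces per capillary.
    """

    n_capillaries: int = 16
    top_ligand: float = 30000.0   # nM, capillary 1
    dilution_factor: float = 3.0
    protein_total: float = 250.0  # nM
    replicates: int = 3

    def __post_init__(self):
        if self.n_capillaries < 2:
            raise ValueError("n_capillaries must be >= 2")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.top_ligand <= 0 or self.protein_total <= 0:
            raise ValueError("concentrations must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def concentrations(self) -> np.ndarray:
        """Ligand concentration per capillary, strictly decreasing."""
        k = np.arange(self.n_capillaries)
        return self.top_ligand / self.dilution_factor**k


@dataclass
class TitrationSeries:
    """A set of per-capillary traces plus the generating truth manifest."""

    traces: list
    manifest: dict = field(default_factory=dict)
    label: str = ""


def simulate_titration(
    design: TitrationDesign, params: TraceParams, true_kd: float
) -> TitrationSeries:
    """Simulate a full MST titration with known ground truth.

    Capillary k receives ligand at top_ligand / dilution_factor^(k-1); its
    fraction bound follows the 1:1 mass-action model at ``true_kd``.  Each
    replicate trace draws noise from a distinct sub-stream derived from
    (params.seed, capillary, replicate), so the whole series is a pure
    function of its arguments.  The manifest records every true value needed
    by recovery tests.
    """
    if true_kd <= 0:
        raise ValueError("true_kd must be > 0")
    concs = design.concentrations()
    fbs = [
        binding.fraction_bound(design.protein_total, float(c), true_kd)
        for c in concs
    ]
    traces = []
    for i, (c, fb) in enumerate(zip(concs, fbs)):
        for rep in range(design.replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(params.seed) % 2**31, i, rep])
            )
            traces.append(
                simulate_trace(
                    params, fb, ligand_conc=float(c), replicate_id=rep,
                    capillary_id=i + 1, rng=rng,
                )
            )
    manifest = {
        "true_kd": true_kd,
        "protein_total": design.protein_total,
        "ligand_concs": [float(c) for c in concs],
        "fraction_bound": [float(f) for f in fbs],
        "design": asdict(design),
        "params": asdict(params),
    }
    return TitrationSeries(traces=traces, manifest=manifest,
                           label=f"synthetic kd={true_kd:g} nM")


# ---------------------------------------------------------------------------
# FCS curves


def simulate_fcs(
    components,
    n_particles: float,
    structure_param: float,
    lag_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic FCS autocorrelation curve for a diffusing mixture.

    ``components`` is a list of (fraction, tau_d) pairs whose fractions must
    sum to 1 within 1e-9; the noiseless curve is the fraction-weighted sum of
    single-species 3D-diffusion terms (see :func:`garpbind.fcs.model_g`)
    plus optional Gaussian noise.
    """
    from .fcs import CorrelationCurve, model_g

    fractions = np.array([f for f, _ in components], dtype=float)
    taus = np.array([td for _, td in components], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("component fractions must sum to 1")
    if np.any(taus <= 0):
        raise ValueError("diffusion times must be > 0")
    lag = np.asarray(lag_grid, dtype=float)
    g = np.zeros_like(lag)
    for f, td in zip(fractions, taus):
        g += f * model_g(lag, 1.0, td, structure_param)
    g /= n_particles
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g + rng.normal(0.0, noise_sd, size=lag.size)
    return CorrelationCurve(lag=lag, g=g, label=f"synthetic seed={seed}")


# ---------------------------------------------------------------------------
# Promoter sequences with planted motifs


def generate_promoter(
    length: int, n_crm: int, n_ecrm: int, seed: int = 0, max_retries: int = 500
) -> str:
    """Random promoter with an exact planted motif content.

    The returned sequence scans to exactly ``n_crm`` standalone CRM hits
    (CRMs not contained in an ECRM) and ``n_ecrm`` ECRM hits over both
    strands; the background is rejection-sampled so there are no accidental
    matches, and planted motif strands are randomized.  Deterministic per
    seed; raises after ``max_retries`` failed packings.
    """
    from .motifs import count_motifs

    rng = np.random.default_rng(seed)
    need = n_crm * 5 + n_ecrm * 8
    slots = n_crm + n_ecrm
    if need + slots > length:  # require >= 1 nt spacing between motifs
        raise ValueError("planted motifs do not fit in the requested length")
    bases = np.array(list("ACGT"))
    for _ in range(max_retries):
        seq = list(rng.choice(bases, size=length))
        # choose non-overlapping placements, left to right with random gaps
        widths = [5] * n_crm + [8] * n_ecrm
        kinds = ["CRM"] * n_crm + ["ECRM"] * n_ecrm
        order = rng.permutation(slots)
        widths = [widths[i] for i in order]
        kinds = [kinds[i] for i in order]
        slack = length - need - slots
        cuts = np.sort(rng.integers(0, slack + 1, size=slots)) if slots else np.array([], int)
        gaps = np.diff(np.concatenate([[0], cuts]))
        pos = 0
        placements = []
        for j, (w, kind) in enumerate(zip(widths, kinds)):
            start = pos + int(gaps[j]) + (1 if j > 0 else 0)
            placements.append((start, w, kind))
            pos = start + w
        if placements and placements[-1][0] + placements[-1][1] > length:
            continue
        for start, w, kind in placements:
            if kind == "CRM":
                motif = rng.choice(["A", "G"]) + "GAT" + rng.choice(["T", "C"])
            else:
                motif = "AAGAT" + rng.choice(["T", "C"]) + "TT"
            if rng.random() < 0.5:
                motif = _revcomp(motif)
            seq[start:start + w] = list(motif)
        out = "".join(seq)
        if count_motifs(out) == (n_crm, n_ecrm):
            return out
    raise RuntimeError(
        f"could not pack {n_crm} CRM + {n_ecrm} ECRM into {length} nt "
        f"after {max_retries} attempts"
    )


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(comp)[::-1]


# ---------------------------------------------------------------------------
# Toy protein--DNA complexes


@dataclass
class ToyComplex:
    """A synthetic protein/DNA pair with known contact truth.

    ``protein`` is the (optionally rigidly transformed) protein model;
    ``protein_reference`` keeps the untransformed coordinates so that
    superposition tests can recover the recorded ``rotation``/``translation``.
    """

    protein: object
    dna: object
    contact_truth: set
    protein_reference: object = None
    rotation: np.ndarray = None
    translation: np.ndarray = None


def generate_toy_complex(
    n_protein_residues: int,
    n_dna_atoms: int,
    contact_residues: set,
    seed: int = 0,
    apply_transform: bool = False,
) -> ToyComplex:
    """Toy coordinates exercising the 4.0 A contact rule.

    DNA heavy atoms lie along the x axis (chain D); protein residues (chain
    P, three backbone atoms each) sit above them, with each designated
    contact residue's minimum heavy-atom distance to DNA drawn from
    [3.0, 3.9] A and every other residue at >= 5.0 A.  With
    ``apply_transform`` a random proper rotation + translation is applied to
    the protein (recorded in the result) for superposition round-trips.
    """
    from .structure import Atom, StructureModel

    contact_residues = set(contact_residues)
    if not contact_residues <= set(range(1, n_protein_residues + 1)):
        raise ValueError("contact_residues must be protein residue numbers")
    rng = np.random.default_rng(seed)

    dna_atoms = []
    dna_resnames = ["DA", "DC", "DG", "DT"]
    for i in range(n_dna_atoms):
        dna_atoms.append(
            Atom(chain="D", resnum=i // 4 + 1, resname=dna_resnames[(i // 4) % 4],
                 name=f"C{i % 4 + 1}'", element="C",
                 x=1.5 * i, y=0.0, z=0.0)
        )
    dna = StructureModel(atoms=dna_atoms, label="toy DNA")

    aa = ["ALA", "GLY", "SER", "VAL"]
    prot_atoms = []
    x_max = 1.5 * (n_dna_atoms - 1)
    for r in range(1, n_protein_residues + 1):
        # anchor each residue directly above some DNA atom x position
        x0 = 1.5 * int(rng.integers(0, n_dna_atoms))
        if r in contact_residues:
            y = rng.uniform(3.0, 3.9)
        else:
            y = rng.uniform(5.5, 9.0)
        # CA at the controlled minimum distance; N/C pushed farther away
        prot_atoms.append(Atom("P", r, aa[r % 4], "CA", "C", x0, y, 0.0))
        prot_atoms.append(Atom("P", r, aa[r % 4], "N", "N",
                               min(x0 + 0.8, x_max + 0.8), y + 1.0, 0.6))
        prot_atoms.append(Atom("P", r, aa[r % 4], "C", "C",
                               max(x0 - 0.8, -0.8), y + 1.2, -0.6))
    protein_ref = StructureModel(atoms=prot_atoms, label="toy protein")

    rotation = None
    translation = None
    protein = protein_ref
    if apply_transform:
        from scipy.spatial.transform import Rotation

        rotation = Rotation.random(rng=rng).as_matrix()
        translation = rng.uniform(-20.0, 20.0, size=3)
        protein = protein_ref.transformed(rotation, translation)
        protein.label = "toy protein (transformed)"
    return ToyComplex(
        protein=protein, dna=dna,
        contact_truth=set(contact_residues),
        protein_reference=protein_ref,
        rotation=rotation, translation=translation,
    )


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
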