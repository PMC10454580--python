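"""MST time-trace zone analysis.

A microscale-thermophoresis experiment records the fluorescence of a labeled
protein in a capillary before, during and after IR-laser heating.  Binding
is read out as the normalized fluorescence

    F_n = (mean fluorescence in a Subject window /
           mean fluorescence in a Reference window) * 1000,

computed per capillary for a set of zones: the temperature jump (TJ) at
laser-on, ten thermophoresis (TMF) windows scanning the depletion phase,
the inverse T-jump (InvTJ) at laser-off, and the back-diffusion (BdF)
recovery.  Window means are unweighted arithmetic means of the samples whose
timestamps fall in the half-open window [start, start + span).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class MSTTrace:
    """One capillary's fluorescence-versus-time record."""

    time: np.ndarray          # s, strictly increasing, uniform sampling
    fluorescence: np.ndarray  # counts
    t_laser_on: float         # s
    t_laser_off: float        # s
    ligand_conc: float        # nM
    replicate_id: int = 0
    capillary_id: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.ligand_conc < 0:
            raise ValueError("ligand_conc must be >= 0")


@dataclass(frozen=True)
class ZoneDefinition:
    """Reference/Subject window pair defining one thermophoretic metric."""

    name: str
    reference_start: float  # s
    reference_span: float   # s
    subject_start: float    # s
    subject_span: float     # s

    def __post_init__(self):
        if self.reference_span <= 0 or self.subject_span <= 0:
            raise ValueError("window spans must be > 0")
        if self.reference_start >= self.subject_start and not self.name.startswith(
            "TMF"
        ):
            # TJ/InvTJ/BdF references precede their subjects; TMF shares one
            # reference for all ten subjects, which also precedes them.
            raise ValueError("reference window must precede subject window")


#: Canonical zone order of the scan table.
ZONE_ORDER = ["TJ"] + [f"TMF_{k}" for k in range(1, 11)] + ["InvTJ", "BdF"]


def default_zones(
    scheme: str = "even",
    t_laser_on: float = 5.0,
    t_laser_off: float = 35.0,
) -> list[ZoneDefinition]:
    """Default zone placements for a 5 s / 30 s / 5 s trace.

    TJ: reference [2.44, 3.44) s (laser still off), subject [5.94, 6.44) s,
    capturing the end of the ~1 s temperature-jump transient.  TMF: one
    reference [6.8, 7.8) s shared by ten 1 s subject windows anchored at
    [9, 10) s (TMF_1) and [34, 35) s (TMF_10); the default ``scheme="even"``
    spaces the intermediate starts evenly between those two anchors, while
    ``scheme="gapped"`` uses literal 1 s gaps (starts 9, 11, 13, ... s).
    InvTJ and BdF mirror the TJ construction after laser-off:
    InvTJ reference [34, 35), subject [35.94, 36.44); BdF reference
    [36.5, 37.0), subject [39.5, 40.0).
    """
    zones = [ZoneDefinition("TJ", 2.44, 1.0, 5.94, 0.5)]
    if scheme == "even":
        starts = np.linspace(9.0, 34.0, 10)
    elif scheme == "gapped":
        starts = 9.0 + 2.0 * np.arange(10)
    else:
        raise ValueError(f"unknown TMF scheme {scheme!r}")
    for k, s in enumerate(starts, start=1):
        zones.append(ZoneDefinition(f"TMF_{k}", 6.8, 1.0, float(s), 1.0))
    zones.append(ZoneDefinition("InvTJ", 34.0, 1.0, 35.94, 0.5))
    zones.append(ZoneDefinition("BdF", 36.5, 0.5, 39.5, 0.5))
    return zones


def _window_mean(trace: MSTTrace, start: float, span: float, label: str) -> float:
    sel = (trace.time >= start) & (trace.time < start + span)
    if not np.any(sel):
        raise ValueError(
            f"{label} window [{start}, {start + span}) s contains no samples"
        )
    return float(trace.fluorescence[sel].mean())


def compute_fn(trace: MSTTrace, zone: ZoneDefinition) -> float:
    """Normalized fluorescence F_n = (F_Subject / F_Reference) * 1000."""
    f_ref = _window_mean(trace, zone.reference_start, zone.reference_span,
                         f"{zone.name} reference")
    f_sub = _window_mean(trace, zone.subject_start, zone.subject_span,
                         f"{zone.name} subject")
    if f_ref <= 0:
        raise ValueError(f"{zone.name}: non-positive reference fluorescence")
    return f_sub / f_ref * 1000.0


@dataclass
class BindingCurve:
    """Per-zone F_n versus ligand concentration with replicate spread."""

    ligand_concs: np.ndarray  # nM, strictly increasing
    fn_mean: np.ndarray       # per-mille
    fn_sd: np.ndarray         # per-mille
    n_replicates: np.ndarray  # per concentration
    zone_name: str = ""
    single_replicate: bool = False

    def __post_init__(self):
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        self.fn_mean = np.asarray(self.fn_mean, dtype=float)
        self.fn_sd = np.asarray(self.fn_sd, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates, dtype=int)
        n = self.ligand_concs.size
        if not (self.fn_mean.size == self.fn_sd.size == self.n_replicates.size == n):
            raise ValueError("binding-curve arrays must have equal length")
        if n > 1 and np.any(np.diff(self.ligand_concs) <= 0):
            raise ValueError("ligand concentrations must be strictly increasing")
        if np.any(self.fn_sd < 0):
            raise ValueError("fn_sd must be >= 0")


def build_binding_curve(series, zone: ZoneDefinition) -> BindingCurve:
    """Average F_n over replicates at each ligand concentration.

    ``series`` is any object with a ``traces`` attribute (e.g. a synthetic
    :class:`~garpbind.synthetic.TitrationSeries`).  Replicate means and
    standard deviations (ddof=1) are reported per concentration, sorted by
    ascending concentration; a single replicate yields sd 0 with the
    ``single_replicate`` flag set.
    """
    import warnings

    by_conc: dict[float, list[float]] = {}
    for tr in series.traces:
        by_conc.setdefault(tr.ligand_conc, []).append(compute_fn(tr, zone))
    concs = np.array(sorted(by_conc))
    if concs.size < 2:
        raise ValueError("need >= 2 ligand concentrations")
    counts = np.array([len(by_conc[c]) for c in concs])
    if counts.max() != counts.min():
        warnings.warn(
            "unequal replicate counts across concentrations; using available",
            stacklevel=2,
        )
    means = np.array([np.mean(by_conc[c]) for c in concs])
    sds = np.array(
        [np.std(by_conc[c], ddof=1) if len(by_conc[c]) > 1 else 0.0 for c in concs]
    )
    return BindingCurve(
        ligand_concs=concs, fn_mean=means, fn_sd=sds, n_replicates=counts,
        zone_name=zone.name, single_replicate=bool(counts.max() == 1),
    )


@dataclass
class QCReport:
    """Initial-fluorescence quality control for a titration series."""

    capillary_ids: list
    initial_fluorescence: np.ndarray  # counts, pre-laser mean per capillary
    capillary_pass: np.ndarray        # bool per capillary
    relative_fluctuation: float       # max |F - median| / median over series
    series_pass: bool
    low: float = 300.0
    high: float = 2000.0
    fluctuation_limit: float = 0.20

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "capillary_id": self.capillary_ids,
                "initial_fluorescence": self.initial_fluorescence,
                "pass": self.capillary_pass,
            }
        )


def qc_series(series, low: float = 300.0, high: float = 2000.0,
              fluctuation_limit: float = 0.20) -> QCReport:
    """Flag capillaries with out-of-range pre-laser fluorescence.

    A capillary fails when its pre-laser mean is < ``low`` or >= ``high``
    counts; the series fails when the maximum relative deviation of
    pre-laser fluorescence from the series median exceeds
    ``fluctuation_limit`` (default 20%).  Report-only: nothing is raised.
    """
    by_cap: dict[int, list[float]] = {}
    for tr in series.traces:
        pre = tr.fluorescence[tr.time < tr.t_laser_on]
        if pre.size == 0:
            raise ValueError(f"capillary {tr.capillary_id}: no pre-laser samples")
        by_cap.setdefault(tr.capillary_id, []).append(float(pre.mean()))
    ids = sorted(by_cap)
    init = np.array([np.mean(by_cap[i]) for i in ids])
    cap_pass = (init >= low) & (init < high)
    med = float(np.median(init))
    fluct = float(np.max(np.abs(init - med)) / med) if med > 0 else np.inf
    return QCReport(
        capillary_ids=ids, initial_fluorescence=init, capillary_pass=cap_pass,
        relative_fluctuation=fluct, series_pass=bool(fluct <= fluctuation_limit),
        low=low, high=high, fluctuation_limit=fluctuation_limit,
    )


# ---------------------------------------------------------------------------
# CSV interchange

TRACE_COLUMNS = ["capillary_id", "replicate", "ligand_nM", "time_s", "fluorescence"]


def traces_to_frame(traces: list[MSTTrace]) -> pd.DataFrame:
    chunks = []
    for tr in traces:
        chunks.append(
            pd.DataFrame(
                {
                    "capillary_id": tr.capillary_id,
                    "replicate": tr.replicate_id,
                    "ligand_nM": tr.ligand_conc,
                    "time_s": tr.time,
                    "fluorescence": tr.fluorescence,
                }
            )
        )
    return pd.concat(chunks, ignore_index=True)


def traces_from_frame(
    df: pd.DataFrame,
    t_laser_on: float = 5.0,
    t_laser_off: float = 35.0,
    column_map: dict | None = None,
) -> list[MSTTrace]:
    """Rebuild traces from the tabular schema (optionally column-remapped)."""
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    traces = []
    for (cap, rep, conc), grp in df.groupby(
        ["capillary_id", "replicate", "ligand_nM"], sort=True
    ):
        grp = grp.sort_values("time_s")
        traces.append(
            MSTTrace(
                time=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                t_laser_on=t_laser_on,
                t_laser_off=t_laser_off,
                ligand_conc=float(conc),
                replicate_id=int(rep),
                capillary_id=int(cap),
            )
        )
    return traces


def binding_curves_to_frame(curves: list[BindingCurve]) -> pd.DataFrame:
    rec = []
    for c in curves:
        for conc, m, s, n in zip(c.ligand_concs, c.fn_mean, c.fn_sd, c.n_replicates):
            rec.append(
                {"zone": c.zone_name, "ligand_nM": conc, "fn_mean": m,
                 "fn_sd": s, "n": n}
            )
    return pd.DataFrame.from_records(rec)
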