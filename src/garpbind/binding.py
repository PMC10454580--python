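"""One-to-one binding-model fits for MST binding curves.

The central quantity is the equilibrium dissociation constant ``K_D`` of a
1:1 protein--ligand interaction, obtained from per-mille normalized
fluorescence (F_n) titration curves with the labeled-protein concentration
held fixed.  Confidence bounds come from the error-surface-projection (ESP)
method: the sum-of-squares objective is profiled over K_D (the two signal
amplitudes re-optimized at each trial value, a closed-form linear
sub-problem) and the interval is the connected region around the optimum
where the profile stays below an F-statistic threshold.  A side on which the
profile never crosses the threshold within the search limits is reported as
unbounded -- the "Un" entries of a zone-scan table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import optimize, stats

if TYPE_CHECKING:  # pragma: no cover
    from .mst import BindingCurve, ZoneDefinition
    from .synthetic import TitrationSeries


class _Unbounded(float):
    """Sentinel for an ESP bound that never crossed the threshold ("Un")."""

    def __new__(cls):
        return super().__new__(cls, np.inf)

    def __repr__(self) -> str:
        return "Un"

    __str__ = __repr__


#: Singleton sentinel used for unbounded ESP interval sides.
UNBOUNDED = _Unbounded()

#: K_D search and report limits in nM; a profile still below the ESP
#: threshold at a limit is reported as UNBOUNDED on that side.
KD_SEARCH_LIMITS = (1e-3, 1e10)


def fraction_bound(protein_total: float, ligand_total: float, kd: float) -> float:
    """Fraction of total protein bound at equilibrium (1:1 mass action).

    Solves P_free * L_free = K_D * PL with conservation of both species:

        fB = (P + L + K_D - sqrt((P + L + K_D)^2 - 4 P L)) / (2 P)

    evaluated through the numerically stable conjugate branch
    ``fB = 2 L / (b + sqrt(b^2 - 4 P L))`` so that P*L << b^2 does not
    cancel catastrophically.

    Parameters
    ----------
    protein_total : float
        Total (labeled) protein concentration, nM.  Must be > 0.
    ligand_total : float
        Total titrated ligand concentration, nM.  Must be >= 0.
    kd : float
        Dissociation constant, nM.  Must be > 0.
    """
    P = np.asarray(protein_total, dtype=float)
    L = np.asarray(ligand_total, dtype=float)
    if np.any(P <= 0):
        raise ValueError("protein_total must be > 0")
    if np.any(L < 0):
        raise ValueError("ligand_total must be >= 0")
    if np.any(np.asarray(kd, dtype=float) <= 0):
        raise ValueError("kd must be > 0")
    b = P + L + kd
    disc = np.sqrt(b * b - 4.0 * P * L)
    fb = 2.0 * L / (b + disc)
    # guard the exact-zero-ligand corner and round-off above 1
    fb = np.clip(fb, 0.0, 1.0)
    if np.ndim(fb) == 0:
        return float(fb)
    return fb


def predict_fn(
    kd: float,
    f_free: float,
    f_bound: float,
    protein_total: float,
    ligand: float,
) -> float:
    """Model F_n (per-mille) at a ligand concentration under the 1:1 model.

    ``f_free`` and ``f_bound`` are the asymptotic per-mille F_n levels of the
    fully free and fully bound labeled protein; the observed signal is their
    mix weighted by :func:`fraction_bound`.
    """
    fb = fraction_bound(protein_total, ligand, kd)
    return f_free + (f_bound - f_free) * fb


@dataclass
class FitResult:
    """Outcome of a 1:1 binding fit to a single binding curve."""

    kd: float                      # nM
    f_free: float                  # per-mille F_n of the free state
    f_bound: float                 # per-mille F_n of the bound state
    kd_sd: float                   # linearized symmetric standard error, nM
    kd_lower: float = UNBOUNDED    # ESP lower bound, nM (or UNBOUNDED)
    kd_upper: float = UNBOUNDED    # ESP upper bound, nM (or UNBOUNDED)
    chi2: float = 0.0              # residual sum of squares at the optimum
    n_points: int = 0
    converged: bool = True
    saturated: bool = False
    identifiable: bool = True
    protein_total: float = 250.0
    messages: list = field(default_factory=list)

    @property
    def span(self) -> float:
        """Signal amplitude |f_bound - f_free| in per-mille."""
        return abs(self.f_bound - self.f_free)


def _profile_chi2(
    kd_grid: np.ndarray,
    concs: np.ndarray,
    y: np.ndarray,
    protein_total: float,
    weights: np.ndarray | None = None,
):
    """Profile SSR over K_D with amplitudes solved in closed form.

    For each trial K_D the model is affine in (f_free, span):
    y ~ f_free + span * fB, an ordinary (optionally weighted) least-squares
    problem solved analytically, which makes the K_D profile one-dimensional.

    Returns (ssr, f_free, span) arrays over the grid.
    """
    P = protein_total
    L = concs[None, :]
    kd = np.asarray(kd_grid, dtype=float)[:, None]
    b = P + L + kd
    fb = 2.0 * L / (b + np.sqrt(b * b - 4.0 * P * L))
    w = np.ones_like(y) if weights is None else weights
    sw = w.sum()
    xm = (w * fb).sum(axis=1) / sw
    ym = (w * y).sum() / sw
    sxx = (w * (fb - xm[:, None]) ** 2).sum(axis=1)
    sxy = (w * (fb - xm[:, None]) * (y - ym)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        span = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
    intercept = ym - span * xm
    resid = y[None, :] - (intercept[:, None] + span[:, None] * fb)
    ssr = (w * resid**2).sum(axis=1)
    return ssr, intercept, span


def fit_curve(
    curve: "BindingCurve",
    protein_total: float = 250.0,
    weighted: bool = False,
    n_grid: int = 161,
) -> FitResult:
    """Fit the 1:1 binding model to a binding curve.

    Minimizes the (by default unweighted) sum of squared residuals between
    ``fn_mean`` and :func:`predict_fn` over (K_D, f_free, f_bound).  The two
    amplitudes are solved in closed form at each trial K_D, so the search is
    a one-dimensional profile over log K_D: a coarse log grid across
    ``KD_SEARCH_LIMITS`` followed by a bounded scalar polish.

    ``kd_sd`` is the symmetric linearized standard error obtained from the
    numerical curvature of the SSR profile at the optimum, scaled by the
    reduced chi-square.  The ``saturated`` flag is set when the fitted curve
    at the highest ligand concentration comes within 5% of the bound-state
    amplitude, mirroring the saturated/non-saturated dichotomy used to judge
    whether a K_D is informative.
    """
    concs = np.asarray(curve.ligand_concs, dtype=float)
    y = np.asarray(curve.fn_mean, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need >= 4 points to fit a binding curve")
    pos = concs[concs > 0]
    if pos.size and pos.max() / pos.min() < 100.0:
        warnings.warn("ligand series spans < 2 orders of magnitude", stacklevel=2)

    weights = None
    if weighted:
        sd = np.asarray(curve.fn_sd, dtype=float)
        floor = max(sd[sd > 0].min(), 1e-9) if np.any(sd > 0) else 1.0
        weights = 1.0 / np.maximum(sd, floor) ** 2

    lo, hi = KD_SEARCH_LIMITS
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    ssr, _, _ = _profile_chi2(grid, concs, y, protein_total, weights)
    i = int(np.argmin(ssr))

    def f(logkd: float) -> float:
        return float(
            _profile_chi2(np.array([10.0**logkd]), concs, y, protein_total, weights)[0][0]
        )

    a = np.log10(grid[max(i - 1, 0)])
    b = np.log10(grid[min(i + 1, n_grid - 1)])
    res = optimize.minimize_scalar(f, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    logkd = float(res.x)
    kd = 10.0**logkd
    ssr_min, intercept, span = _profile_chi2(
        np.array([kd]), concs, y, protein_total, weights
    )
    chi2 = float(ssr_min[0])
    f_free = float(intercept[0])
    f_bound = float(intercept[0] + span[0])

    messages: list[str] = []
    converged = bool(res.success)
    at_limit = kd <= lo * 1.01 or kd >= hi / 1.01
    if at_limit:
        converged = False
        messages.append("K_D optimum at search limit; fit unreliable")

    # linearized SE from profile curvature, scaled by reduced chi-square
    dof = max(n - 3, 1)
    h = 0.05
    c2 = (f(logkd + h) - 2.0 * chi2 + f(logkd - h)) / h**2
    if c2 > 0:
        var_log = 2.0 * (chi2 / dof) / c2          # Var(log10 K_D)
        kd_sd = kd * np.log(10.0) * np.sqrt(var_log)
    else:
        kd_sd = np.inf
        messages.append("non-positive profile curvature at optimum")

    noise_scale = np.sqrt(chi2 / dof)
    identifiable = abs(f_bound - f_free) > max(2.0 * noise_scale, 1e-12)
    if not identifiable:
        messages.append("amplitude span below noise; K_D not identifiable")

    fn_top = predict_fn(kd, f_free, f_bound, protein_total, float(concs.max()))
    span_abs = abs(f_bound - f_free)
    saturated = span_abs > 0 and abs(fn_top - f_bound) <= 0.05 * span_abs

    return FitResult(
        kd=kd, f_free=f_free, f_bound=f_bound, kd_sd=float(kd_sd),
        chi2=chi2, n_points=n, converged=converged, saturated=saturated,
        identifiable=identifiable, protein_total=protein_total,
        messages=messages,
    )


def esp_interval(
    curve: "BindingCurve",
    fit: FitResult,
    level: float = 0.683,
    n_grid: int = 321,
    weighted: bool = False,
) -> tuple[float, float]:
    """Error-surface-projection confidence interval for K_D.

    The SSR is profiled over a log grid of K_D spanning ``KD_SEARCH_LIMITS``
    (amplitudes re-optimized at each point) and the interval is the connected
    region around the optimum where

        chi2(K_D) <= chi2_min * (1 + F_crit(1, n-3; level) / (n-3)).

    Boundaries are refined by bisection to 1% relative.  A side on which the
    profile never exceeds the threshold within the limits is returned as
    :data:`UNBOUNDED` -- the situation in which no function minimum can be
    localized and the fitted K_D is not a reliable estimate.

    A perfect fit (chi2_min == 0) is handled by flooring chi2_min at a
    machine-epsilon scale; the result is then essentially a point interval.
    """
    concs = np.asarray(curve.ligand_concs, dtype=float)
    y = np.asarray(curve.fn_mean, dtype=float)
    n = y.size
    dof = max(n - 3, 1)
    weights = None
    if weighted:
        sd = np.asarray(curve.fn_sd, dtype=float)
        floor = max(sd[sd > 0].min(), 1e-9) if np.any(sd > 0) else 1.0
        weights = 1.0 / np.maximum(sd, floor) ** 2

    chi2_min = fit.chi2
    if chi2_min <= 0.0:
        chi2_min = n * (np.finfo(float).eps * max(1.0, np.abs(y).max())) ** 2
    fcrit = stats.f.ppf(level, 1, dof)
    threshold = chi2_min * (1.0 + fcrit / dof)

    lo, hi = KD_SEARCH_LIMITS
    grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    prof, _, _ = _profile_chi2(grid, concs, y, fit.protein_total, weights)

    i0 = int(np.argmin(np.abs(np.log10(grid) - np.log10(fit.kd))))
    below = prof <= threshold
    if not below[i0]:
        # numerical slack: the polished optimum may sit between grid points
        below[i0] = True

    def profile_at(kd: float) -> float:
        return float(
            _profile_chi2(np.array([kd]), concs, y, fit.protein_total, weights)[0][0]
        )

    def refine(inside: float, outside: float) -> float:
        # bisection on log K_D for the threshold crossing, to 1% relative
        a, b = np.log10(inside), np.log10(outside)
        while abs(b - a) > np.log10(1.01):
            m = 0.5 * (a + b)
            if profile_at(10.0**m) <= threshold:
                a = m
            else:
                b = m
        return 10.0 ** (0.5 * (a + b))

    # walk left from the optimum; bisect from the innermost point known to
    # satisfy the threshold (the polished optimum itself when no grid
    # neighbor does)
    j = i0
    while j > 0 and below[j - 1]:
        j -= 1
    if j == 0:
        lower: float = UNBOUNDED
    else:
        inside = grid[j] if j < i0 else fit.kd
        lower = refine(inside, grid[j - 1])
    # walk right
    k = i0
    while k < n_grid - 1 and below[k + 1]:
        k += 1
    if k == n_grid - 1:
        upper: float = UNBOUNDED
    else:
        inside = grid[k] if k > i0 else fit.kd
        upper = refine(inside, grid[k + 1])
    return lower, upper


@dataclass
class ZoneScanResult:
    """Per-zone K_D summary: the machine twin of a zone-scan table."""

    rows: list  # list of (zone_name, experiment_label, FitResult)

    def to_frame(self):
        import pandas as pd

        def fmt(b: float) -> str:
            return "Un" if b is UNBOUNDED or np.isinf(b) else f"{b:.6g}"

        rec = []
        for zone, label, fr in self.rows:
            rec.append(
                {
                    "zone": zone,
                    "experiment": label,
                    "kd_nM": fr.kd,
                    "lower": fmt(fr.kd_lower),
                    "upper": fmt(fr.kd_upper),
                    "sd_nM": fr.kd_sd,
                    "chi2": fr.chi2,
                    "converged": fr.converged,
                    "saturated": fr.saturated,
                    "identifiable": fr.identifiable,
                }
            )
        return pd.DataFrame.from_records(rec)


def zone_scan(
    series: "TitrationSeries",
    zones: "list[ZoneDefinition] | None" = None,
    protein_total: float = 250.0,
    level: float = 0.683,
    label: str | None = None,
) -> ZoneScanResult:
    """Fit the 1:1 model in every MST zone of a titration series.

    Produces one row per zone in the canonical order TJ, TMF_1..TMF_10,
    InvTJ, BdF with K_D, ESP bounds and SD.  Per-zone failures are captured
    as non-converged rows; the scan never aborts the whole table.
    """
    from .mst import build_binding_curve, default_zones

    if zones is None:
        zones = default_zones()
    if label is None:
        label = getattr(series, "label", "")
    rows = []
    for zone in zones:
        try:
            curve = build_binding_curve(series, zone)
            fr = fit_curve(curve, protein_total=protein_total)
            fr.kd_lower, fr.kd_upper = esp_interval(curve, fr, level=level)
        except Exception as exc:  # propagate as a diagnostic row
            fr = FitResult(
                kd=np.nan, f_free=np.nan, f_bound=np.nan, kd_sd=np.nan,
                chi2=np.nan, n_points=0, converged=False,
                messages=[f"fit failed: {exc}"],
            )
        rows.append((zone.name, label, fr))
    return ZoneScanResult(rows)
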