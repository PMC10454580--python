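"""Fluorescence correlation spectroscopy: 3D diffusion fits and the
competition equilibrium.

The autocorrelation of intensity fluctuations in a confocal volume is
modeled by the standard single-species 3D Gaussian-volume diffusion form

    G(tau) = (1/N) (1 + tau/tau_D)^-1 (1 + tau/(S^2 tau_D))^-1/2

with N the mean particle number, tau_D the lateral diffusion time and S the
axial-to-lateral structure parameter of the observation volume.  tau_D
converts to a diffusion coefficient via D = w0^2 / (4 tau_D) given the beam
waist w0.  Curves distorted by aggregates are excluded by a robust residual
rule.  The competition experiment (labeled oligo challenged with an excess
of unlabeled oligo sharing the same K_D) is modeled by solving the coupled
1:1 equilibria for the free protein concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class CorrelationCurve:
    lag: np.ndarray  # s, strictly increasing, > 0
    g: np.ndarray    # unitless
    label: str = ""

    def __post_init__(self):
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lag.shape != self.g.shape:
            raise ValueError("lag and g must have equal length")
        if np.any(self.lag <= 0) or np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag must be strictly increasing and > 0")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("g must be finite")


@dataclass
class FCSFitResult:
    n_particles: float
    tau_d: float                      # s
    structure_param: float
    structure_param_fitted: bool
    diffusion_coefficient: float = np.nan  # um^2/s, requires beam waist
    residual_rms: float = np.nan
    converged: bool = True
    excluded: bool = False
    label: str = ""


def model_g(lag, n_particles: float, tau_d: float, structure_param: float):
    """Single-component 3D diffusion autocorrelation."""
    if n_particles <= 0 or tau_d <= 0 or structure_param <= 0:
        raise ValueError("parameters must be > 0")
    tau = np.asarray(lag, dtype=float)
    return (
        1.0
        / n_particles
        / (1.0 + tau / tau_d)
        / np.sqrt(1.0 + tau / (structure_param**2 * tau_d))
    )


def model_g_two_component(lag, n_particles, frac1, tau_d1, tau_d2, structure_param):
    """Two-species mixture sharing one observation volume."""
    tau = np.asarray(lag, dtype=float)
    g1 = model_g(tau, 1.0, tau_d1, structure_param)
    g2 = model_g(tau, 1.0, tau_d2, structure_param)
    return (frac1 * g1 + (1.0 - frac1) * g2) / n_particles


def fit_correlation(
    curve: CorrelationCurve,
    fix_structure_param: float | None = 5.0,
    beam_waist: float | None = None,
) -> FCSFitResult:
    """Least-squares fit of (N, tau_D[, S]) to an autocorrelation curve.

    ``fix_structure_param`` fixes S (default 5, a typical confocal value);
    pass None to fit it.  If ``beam_waist`` (um) is given, the diffusion
    coefficient is filled in.  Non-convergence is flagged, not raised.
    """
    lag = curve.lag
    g = curve.g
    if lag.size < 10:
        raise ValueError("need >= 10 lag points spanning the decay")
    g0 = max(float(np.mean(g[: max(2, lag.size // 20)])), 1e-12)
    n0 = 1.0 / g0
    half = g0 / 2.0
    idx = int(np.argmin(np.abs(g - half)))
    tau0 = float(lag[idx]) if g[idx] > 0 else float(np.sqrt(lag[0] * lag[-1]))

    try:
        if fix_structure_param is None:
            popt, _ = optimize.curve_fit(
                lambda t, n, td, s: model_g(t, n, td, s),
                lag, g, p0=[n0, tau0, 5.0],
                bounds=([1e-12, 1e-12, 1.0], [np.inf, np.inf, 100.0]),
                maxfev=20000,
            )
            n_fit, tau_fit, s_fit = popt
            fitted_s = True
        else:
            s_fixed = float(fix_structure_param)
            popt, _ = optimize.curve_fit(
                lambda t, n, td: model_g(t, n, td, s_fixed),
                lag, g, p0=[n0, tau0],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
            n_fit, tau_fit = popt
            s_fit = s_fixed
            fitted_s = False
        converged = True
    except RuntimeError:
        n_fit, tau_fit = n0, tau0
        s_fit = 5.0 if fix_structure_param is None else float(fix_structure_param)
        fitted_s = fix_structure_param is None
        converged = False

    resid = g - model_g(lag, n_fit, tau_fit, s_fit)
    rms = float(np.sqrt(np.mean(resid**2)))
    d = diffusion_coefficient(tau_fit, beam_waist) if beam_waist else np.nan
    return FCSFitResult(
        n_particles=float(n_fit), tau_d=float(tau_fit),
        structure_param=float(s_fit), structure_param_fitted=fitted_s,
        diffusion_coefficient=d, residual_rms=rms, converged=converged,
        label=curve.label,
    )


def exclude_irregular(
    fits: list[FCSFitResult], threshold: float = 3.0
) -> tuple[list[FCSFitResult], list[FCSFitResult]]:
    """Split fits into (kept, excluded) by a robust residual rule.

    A curve is irregular -- e.g. distorted by a bright aggregate transit --
    when its residual RMS exceeds ``threshold`` times the batch median
    residual RMS.  Non-converged fits are always excluded.
    """
    rms = np.array([f.residual_rms for f in fits], dtype=float)
    med = float(np.median(rms)) if rms.size else 0.0
    kept, excluded = [], []
    for f in fits:
        bad = (not f.converged) or (med > 0 and f.residual_rms > threshold * med)
        f.excluded = bad
        (excluded if bad else kept).append(f)
    return kept, excluded


def diffusion_coefficient(tau_d: float, beam_waist: float) -> float:
    """D = w0^2 / (4 tau_D); tau_d in s, beam_waist in um, D in um^2/s."""
    if tau_d <= 0 or beam_waist <= 0:
        raise ValueError("tau_d and beam_waist must be > 0")
    return beam_waist**2 / (4.0 * tau_d)


def competitive_fraction(
    protein_total: float,
    labeled_ligand: float,
    unlabeled_ligand: float,
    kd: float,
) -> tuple[float, float]:
    """Bound fractions of labeled and unlabeled ligand sharing one K_D.

    Both ligands compete for the same protein; at equilibrium each ligand's
    bound fraction is P_free / (K_D + P_free) where P_free solves the
    protein-conservation equation

        P_free + sum_i L_i_total * P_free / (K_D + P_free) = P_total,

    found by bracketed root-finding (brentq) to ~1e-12 relative.  With zero
    unlabeled ligand this reduces to the single-ligand mass-action result.
    """
    if min(protein_total, kd) <= 0 or min(labeled_ligand, unlabeled_ligand) < 0:
        raise ValueError("concentrations must be >= 0 and protein, kd > 0")

    ltot = labeled_ligand + unlabeled_ligand

    def balance(pf: float) -> float:
        return pf + ltot * pf / (kd + pf) - protein_total

    if ltot == 0:
        pf = protein_total
    else:
        pf = optimize.brentq(
            balance, 0.0, protein_total, xtol=1e-300, rtol=1e-15, maxiter=200
        )
    frac = pf / (kd + pf)
    return frac, frac


def curves_to_frame(fits: list[FCSFitResult]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "label": f.label,
                "N": f.n_particles,
                "tau_d_s": f.tau_d,
                "S": f.structure_param,
                "D_um2_s": f.diffusion_coefficient,
                "residual_rms": f.residual_rms,
                "excluded": f.excluded,
            }
            for f in fits
        ]
    )
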