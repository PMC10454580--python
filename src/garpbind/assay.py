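"""Bench-adjacent arithmetic: eGFP quantification against a FITC standard,
GFP loading normalization, and serial-dilution / labeling-scheme bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Fluorophore constants of the eGFP-vs-FITC quantification formula:
# molar extinction, quantum yield and the fixed 478-492 nm window factor.
FITC_EXTINCTION = 76000.0
FITC_QY = 0.92
FITC_WINDOW_FACTOR = 0.33
EGFP_EXTINCTION = 56000.0
EGFP_QY = 0.6
EGFP_WINDOW_FACTOR = 0.25
WINDOW_NM = (478.0, 492.0)


@dataclass
class EmissionSpectrum:
    wavelength: np.ndarray  # nm, increasing
    intensity: np.ndarray   # counts, >= 0
    fluorophore: str = ""

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have equal length")
        if self.wavelength.size > 1 and np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelengths must be increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def window_sum(self, lo: float, hi: float) -> float:
        if self.wavelength.min() > lo or self.wavelength.max() < hi:
            raise ValueError(
                f"spectrum does not cover the {lo:g}-{hi:g} nm window"
            )
        sel = (self.wavelength >= lo) & (self.wavelength <= hi)
        return float(self.intensity[sel].sum())


def egfp_conc_from_fitc(
    egfp_spectrum: EmissionSpectrum,
    fitc_spectrum: EmissionSpectrum,
    fitc_conc: float,
) -> float:
    """eGFP concentration from its emission relative to a FITC standard.

    conc_eGFP = fitc_conc
        * (0.33 * 76000 * 0.92 * sum_478-492 I_FITC)
        / (0.25 * 56000 * 0.60 * sum_478-492 I_eGFP)

    The window factors, extinction coefficients and quantum yields are the
    module-level constants above.  Raises if either spectrum misses the
    window or the eGFP window sum is zero.
    """
    lo, hi = WINDOW_NM
    s_fitc = fitc_spectrum.window_sum(lo, hi)
    s_egfp = egfp_spectrum.window_sum(lo, hi)
    if s_egfp <= 0:
        raise ValueError("eGFP intensity sum over 478-492 nm is zero")
    num = FITC_WINDOW_FACTOR * FITC_EXTINCTION * FITC_QY * s_fitc
    den = EGFP_WINDOW_FACTOR * EGFP_EXTINCTION * EGFP_QY * s_egfp
    return fitc_conc * num / den


def loading_factors(gfp_signals, background: float = 0.0) -> np.ndarray:
    """Linear dilution factors with the weakest signal set to 1."""
    s = np.asarray(gfp_signals, dtype=float) - background
    if np.any(s <= 0):
        raise ValueError("all signals must exceed the background")
    return s / s.min()


@dataclass
class MixStep:
    """One ideal-mixing step: combine the carried solution with a partner."""

    input_volume: float        # uL of the solution carrying the species
    partner_volume: float      # uL of diluent or partner solution
    partner_concentration: float = 0.0  # nM of the tracked species in partner

    def __post_init__(self):
        if self.input_volume <= 0 or self.partner_volume <= 0:
            raise ValueError("volumes must be > 0")
        if self.partner_concentration < 0:
            raise ValueError("partner concentration must be >= 0")


def mix_concentration(steps: list, start_conc: float) -> float:
    """Tracked-species concentration after sequential ideal mixing.

    Amount of substance is conserved at each step:
    c_out = (c_in*V_in + c_partner*V_partner) / (V_in + V_partner).
    """
    c = float(start_conc)
    for step in steps:
        v_tot = step.input_volume + step.partner_volume
        c = (c * step.input_volume
             + step.partner_concentration * step.partner_volume) / v_tot
    return c


def serial_dilution(
    start_conc: float,
    n_tubes: int,
    transfer_volume: float,
    tube_volume: float,
) -> np.ndarray:
    """Tube concentrations of a serial transfer scheme (before any dye add).

    Tube 1 holds ``start_conc``; each subsequent tube receives
    ``transfer_volume`` of the previous one into ``tube_volume`` of buffer.
    """
    out = [float(start_conc)]
    f = transfer_volume / (transfer_volume + tube_volume)
    for _ in range(1, n_tubes):
        out.append(out[-1] * f)
    return np.array(out)


def labeling_ratio(protein_conc: float, dye_conc: float) -> float:
    """Protein:dye labeling ratio, e.g. 500/25 = 20."""
    if dye_conc <= 0:
        raise ValueError("dye_conc must be > 0")
    return protein_conc / dye_conc
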