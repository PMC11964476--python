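"""Closed-form photophysics: fluorescence yield, Beer-Lambert absorbance,
Stokes shift, band integration, and penetration depth.

All functions are pure and operate in the units stated in their docstrings.
Constants (default molar absorptivity at 540 nm, hemoglobin molar mass) live
in :mod:`hemafluor.config`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import HEMOGLOBIN_MOLAR_MASS_G_PER_MOL
from .spectra import Spectrum1D


@dataclass(frozen=True)
class PhotophysicalParams:
    """Inputs of the fluorescence-intensity and absorbance relations.

    quantum_yield : fraction of absorbed photons re-emitted, in [0, 1]
    epsilon       : molar absorptivity, L mol^-1 cm^-1
    concentration : mol/L
    path_length   : cm
    incident_intensity : a.u.
    """

    quantum_yield: float
    epsilon: float
    concentration: float
    path_length: float = 1.0
    incident_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum_yield must lie in [0, 1]")
        for name in ("epsilon", "concentration", "path_length", "incident_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SpectralSummary:
    """Scalar summary of an (absorption, emission) spectrum pair."""

    total_intensity: float
    stokes_shift_nm: float
    penetration_depth: float
    absorption_peak_nm: float
    emission_peak_nm: float

    def __post_init__(self) -> None:
        expected = self.emission_peak_nm - self.absorption_peak_nm
        if abs(self.stokes_shift_nm - expected) > 1e-9:
            raise ValueError("stokes_shift_nm must equal emission_peak - absorption_peak")


def fluorescence_intensity(p: PhotophysicalParams) -> float:
    """Emitted intensity: quantum yield x incident intensity x concentration x
    molar absorptivity. Linear in every factor."""
    return p.quantum_yield * p.incident_intensity * p.concentration * p.epsilon


def absorbance(epsilon: float, concentration: float, path_length: float) -> tuple[float, float]:
    """Beer-Lambert absorbance and the transmitted fraction I/I0 = 10**(-A).

    Returns
    -------
    (A, transmitted_fraction)
    """
    if epsilon < 0 or concentration < 0 or path_length < 0:
        raise ValueError("epsilon, concentration, and path_length must be non-negative")
    a = epsilon * concentration * path_length
    return a, 10.0 ** (-a)


def hemoglobin_gL_from_absorbance(a540: float, epsilon540: float, path_length: float) -> float:
    """Hemoglobin mass concentration (g/L) from absorbance at 540 nm.

    Inverts Beer-Lambert for the molar concentration and converts with the
    64 500 g/mol molar mass of hemoglobin.
    """
    if epsilon540 <= 0:
        raise ValueError("epsilon540 must be positive")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    if a540 < 0:
        raise ValueError("absorbance must be non-negative")
    return (a540 / (epsilon540 * path_length)) * HEMOGLOBIN_MOLAR_MASS_G_PER_MOL


class AntiStokesError(ValueError):
    """Raised when the emission peak is blue of the absorption peak."""


def stokes_shift(emission_peak_nm: float, absorption_peak_nm: float) -> float:
    """Emission peak minus absorption peak, in nm. Must be non-negative."""
    if emission_peak_nm <= 0 or absorption_peak_nm <= 0:
        raise ValueError("peak wavelengths must be positive")
    shift = emission_peak_nm - absorption_peak_nm
    if shift < 0:
        raise AntiStokesError(
            f"emission peak {emission_peak_nm} nm is blue of absorption peak "
            f"{absorption_peak_nm} nm"
        )
    return shift


def integrate_intensity(s: Spectrum1D, lam_min: float, lam_max: float) -> float:
    """Trapezoidal integral of intensity over [lam_min, lam_max] (a.u. x nm).

    Bounds must lie within the grid span. Endpoints off the grid are handled
    by linear interpolation, which makes the integral exactly additive over
    adjacent sub-intervals.
    """
    if lam_min >= lam_max:
        raise ValueError("lam_min must be strictly below lam_max")
    lo, hi = s.span
    if lam_min < lo or lam_max > hi:
        raise ValueError(
            f"integration bounds [{lam_min}, {lam_max}] outside grid span [{lo}, {hi}]"
        )
    wl, ii = s.wavelengths, s.intensities
    inside = (wl > lam_min) & (wl < lam_max)
    xs = np.concatenate(([lam_min], wl[inside], [lam_max]))
    ys = np.concatenate(
        ([np.interp(lam_min, wl, ii)], ii[inside], [np.interp(lam_max, wl, ii)])
    )
    return float(np.trapezoid(ys, xs))


def penetration_depth(epsilon: float, concentration: float) -> float:
    """Depth 1 / (epsilon x C).

    Returned verbatim as the reciprocal of the absorptivity-concentration
    product (cm when epsilon is in L mol^-1 cm^-1 and C in mol/L). Note that a
    1/e attenuation depth would carry an additional 1/ln(10) factor which is
    deliberately not applied here.
    """
    prod = epsilon * concentration
    if prod <= 0:
        raise ValueError("epsilon * concentration must be positive")
    return 1.0 / prod
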