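"""Erythrocyte morphology, deformability, and colloidal interaction.

Shape factor and deformability index from scattering profiles, deformability
versus zeta potential (exponential and logarithmic models), DLVO interaction
energy, empirical diameter calibration, and the full-spectrum internal
composition index.

Unit conventions: zeta potential is taken in mV at the user surface for the
deformability models (the logarithm acts on the numeric mV magnitude); the
DLVO computation is fully SI (volts, meters, joules).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .photophysics import integrate_intensity
from .spectra import Spectrum1D


@dataclass
class ScatteringProfile:
    """A scattering trace plus the derived peak and size quantities."""

    spectrum: Spectrum1D
    mean_diameter_um: float
    calibration_k_um_per_nm: float

    def __post_init__(self) -> None:
        if self.spectrum.role != "scattering":
            raise ValueError("ScatteringProfile requires a scattering-role spectrum")
        if self.mean_diameter_um <= 0 or self.calibration_k_um_per_nm <= 0:
            raise ValueError("diameter and calibration constant must be positive")

    @property
    def peak_intensity(self) -> float:
        return float(np.max(self.spectrum.intensities))

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.spectrum.wavelengths[int(np.argmax(self.spectrum.intensities))])

    @classmethod
    def from_spectrum(cls, s: Spectrum1D, k_um_per_nm: float) -> "ScatteringProfile":
        """Build a profile, inferring the diameter from the scattering peak."""
        lam_peak = float(s.wavelengths[int(np.argmax(s.intensities))])
        return cls(
            spectrum=s,
            mean_diameter_um=diameter_from_scattering(lam_peak, k_um_per_nm),
            calibration_k_um_per_nm=k_um_per_nm,
        )


@dataclass(frozen=True)
class DeformabilityModel:
    """Deformability-index response to zeta potential.

    ``exponential``: DI = a * exp(b * zeta) + c
    ``logarithmic``: DI = a * ln(-zeta) + c (requires zeta < 0 mV)
    """

    kind: Literal["exponential", "logarithmic"] = "exponential"
    a: float = 1.5
    b_per_mv: float = -0.05
    c: float = 0.5

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.kind not in ("exponential", "logarithmic"):
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass(frozen=True)
class DLVOParams:
    """SI parameters of the pairwise erythrocyte interaction energy."""

    permittivity_f_per_m: float  # medium permittivity
    radius_m: float  # erythrocyte radius
    zeta_v: float  # zeta potential, volts (any sign)
    inverse_debye_per_m: float  # 1 / Debye length
    separation_m: float  # surface-to-surface distance
    hamaker_j: float  # Hamaker constant

    def __post_init__(self) -> None:
        for name in ("permittivity_f_per_m", "radius_m", "inverse_debye_per_m", "separation_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hamaker_j < 0:
            raise ValueError("hamaker_j must be non-negative")


@dataclass(frozen=True)
class EnergyDecomposition:
    """Repulsive, attractive, and total interaction energies (J)."""

    e_rep: float
    e_vdw: float
    e_total: float
    regime: Literal["repulsion_dominates", "attraction_dominates"]

    def __post_init__(self) -> None:
        if self.e_rep < 0:
            raise ValueError("repulsive energy must be non-negative")
        if self.e_vdw > 0:
            raise ValueError("van der Waals energy must be non-positive")
        if abs(self.e_total - (self.e_rep + self.e_vdw)) > 1e-12 * max(
            1.0, abs(self.e_rep), abs(self.e_vdw)
        ):
            raise ValueError("e_total must equal e_rep + e_vdw")


def shape_factor(p: ScatteringProfile) -> float:
    """Peak scattering intensity over mean diameter (a.u./um).

    Lower values indicate a more biconcave cell; higher values a spherical
    or distorted one.
    """
    return p.peak_intensity / p.mean_diameter_um


def classify_shape(value: float, biconcave_below: float = 10.0) -> str:
    """Qualitative shape label for a shape-factor value."""
    return "more biconcave" if value < biconcave_below else "spherical or distorted"


def deformability_from_scattering(
    p: ScatteringProfile, lam_min: float, lam_max: float
) -> float:
    """Deformability index: integrated scattering intensity over the band,
    divided by the mean diameter (a.u. nm / um)."""
    return integrate_intensity(p.spectrum, lam_min, lam_max) / p.mean_diameter_um


def di_zeta(zeta_mv: float, model: DeformabilityModel | None = None) -> float:
    """Deformability index as a function of zeta potential (mV)."""
    m = model or DeformabilityModel()
    if m.kind == "exponential":
        return m.a * math.exp(m.b_per_mv * zeta_mv) + m.c
    if zeta_mv >= 0:
        raise ValueError("logarithmic model requires a negative zeta potential")
    return m.a * math.log(-zeta_mv) + m.c


def dlvo_energy(p: DLVOParams) -> EnergyDecomposition:
    """Screened electrostatic repulsion plus van der Waals attraction.

    E_rep = pi * eps * R * zeta^2 * exp(-kappa * d)
    E_vdw = -A * R / (12 * d)

    A positive total means repulsion dominates (no aggregation); a negative
    total means attraction dominates (aggregation promoted). The exact-zero
    boundary is classified as repulsion-dominated.
    """
    e_rep = (
        math.pi
        * p.permittivity_f_per_m
        * p.radius_m
        * p.zeta_v**2
        * math.exp(-p.inverse_debye_per_m * p.separation_m)
    )
    e_vdw = -p.hamaker_j * p.radius_m / (12.0 * p.separation_m)
    e_total = e_rep + e_vdw
    regime = "repulsion_dominates" if e_total >= 0 else "attraction_dominates"
    return EnergyDecomposition(e_rep=e_rep, e_vdw=e_vdw, e_total=e_total, regime=regime)


def diameter_from_scattering(lam_peak_nm: float, k_um_per_nm: float) -> float:
    """Empirical diameter calibration R = k * lambda_peak (um)."""
    if lam_peak_nm <= 0 or k_um_per_nm <= 0:
        raise ValueError("peak wavelength and calibration constant must be positive")
    return k_um_per_nm * lam_peak_nm


def internal_composition_index(s: Spectrum1D) -> float:
    """Full-grid integral of fluorescence intensity (a.u. nm).

    Higher values indicate a higher concentration of fluorescent components
    within the cell. Only emission-role spectra qualify.
    """
    if s.role != "emission":
        raise ValueError(f"internal composition index requires an emission spectrum, got {s.role!r}")
    lo, hi = s.span
    return integrate_intensity(s, lo, hi)


def zeta_sweep(
    zetas_mv: np.ndarray, model: DeformabilityModel | None = None
) -> np.ndarray:
    """Vectorized :func:`di_zeta` over an array of zeta potentials (mV)."""
    return np.array([di_zeta(float(z), model) for z in np.asarray(zetas_mv, dtype=float)])
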