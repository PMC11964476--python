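"""Synthetic blood-spectroscopy inputs.

Generates every input the pipeline consumes — excitation-emission matrices,
hemoglobin absorption spectra, full-range two-patient spectra, scattering
profiles, and CBC records — with the statistical structure the downstream
analysis assumes. All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .spectra import CLIPPED_ROLES, EEMatrix, Spectrum1D, gaussian

SourceKind = Literal["deuterium", "halogen", "deuterium+halogen", "UV"]
LifecyclePhase = Literal["young", "mature", "old"]
Condition = Literal["none", "iron_deficiency", "b12_deficiency"]

#: Relative integrated-intensity multiplier per erythrocyte life-cycle phase.
#: Young cells fluoresce the most, old cells the least.
LIFECYCLE_MULTIPLIER: dict[str, float] = {"young": 1.25, "mature": 1.0, "old": 0.6}

#: MCH reference ranges (pg) by age bin; closed on the left, open on the
#: right. Ages >= 45 reuse the adult 18-44 range.
MCH_AGE_BINS: list[tuple[float, float, float, float]] = [
    (0.5, 9.0, 24.0, 30.0),
    (9.0, 12.0, 26.0, 32.0),
    (12.0, 18.0, 26.0, 34.0),
    (18.0, float("inf"), 27.0, 34.0),
]


@dataclass(frozen=True)
class FluorophoreSpec:
    """A single fluorophore: Gaussian excitation/emission bands plus the
    photophysical factors that set its emitted intensity."""

    name: str
    ex_center: float  # nm
    ex_width: float  # Gaussian sigma, nm
    em_center: float  # nm
    em_width: float  # Gaussian sigma, nm
    quantum_yield: float  # [0, 1]
    molar_absorptivity: float  # L mol^-1 cm^-1 at ex_center
    concentration: float  # mol/L (or a.u. for relative work)

    def __post_init__(self) -> None:
        if self.ex_center >= self.em_center:
            raise ValueError(
                f"{self.name}: excitation center {self.ex_center} must be blue of "
                f"emission center {self.em_center} (Stokes-positive)"
            )
        if self.ex_width <= 0 or self.em_width <= 0:
            raise ValueError(f"{self.name}: band widths must be positive")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError(f"{self.name}: quantum yield must lie in [0, 1]")
        if self.molar_absorptivity < 0:
            raise ValueError(f"{self.name}: molar absorptivity must be non-negative")
        if self.concentration < 0:
            raise ValueError(f"{self.name}: concentration must be non-negative")

    @property
    def amplitude(self) -> float:
        """Intensity prefactor: yield x absorptivity x concentration."""
        return self.quantum_yield * self.molar_absorptivity * self.concentration


def default_blood_library() -> list[FluorophoreSpec]:
    """The endogenous blood fluorophores: tryptophan, NADH, flavins.

    Band centers are midpoints of the literature excitation/emission ranges
    (tryptophan 280-300 / 340-350 nm, NADH 340-360 / 450-460 nm, flavins
    450-470 / 520-530 nm); sigmas are half the range widths. Yields,
    absorptivities and concentrations are chosen so NADH carries the
    strongest signal, matching its dominant metabolic fluorescence.
    """
    return [
        FluorophoreSpec(
            name="tryptophan",
            ex_center=290.0, ex_width=10.0,
            em_center=345.0, em_width=5.0,
            quantum_yield=0.13, molar_absorptivity=5_600.0, concentration=1e-5,
        ),
        FluorophoreSpec(
            name="NADH",
            ex_center=350.0, ex_width=10.0,
            em_center=455.0, em_width=5.0,
            quantum_yield=0.45, molar_absorptivity=6_220.0, concentration=2e-5,
        ),
        FluorophoreSpec(
            name="flavins",
            ex_center=460.0, ex_width=10.0,
            em_center=525.0, em_width=5.0,
            quantum_yield=0.25, molar_absorptivity=12_500.0, concentration=1e-5,
        ),
    ]


@dataclass(frozen=True)
class ExcitationSource:
    """A lamp with a smooth non-negative power profile over 200-900 nm."""

    kind: SourceKind

    def power(self, wavelengths_nm: np.ndarray | float) -> np.ndarray:
        """Relative spectral power I0(lambda), in [0, 1]."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        if self.kind == "deuterium":
            # UV-strong, rolls off past ~400 nm
            profile = 1.0 / (1.0 + np.exp((lam - 420.0) / 25.0))
        elif self.kind == "halogen":
            # visible/NIR, negligible below ~380 nm
            profile = 1.0 / (1.0 + np.exp((390.0 - lam) / 25.0))
        elif self.kind == "deuterium+halogen":
            profile = np.maximum(
                1.0 / (1.0 + np.exp((lam - 420.0) / 25.0)),
                1.0 / (1.0 + np.exp((390.0 - lam) / 25.0)),
            )
        elif self.kind == "UV":
            # narrow UV window centered near 300 nm
            profile = 1.0 / (
                (1.0 + np.exp((lam - 400.0) / 15.0)) * (1.0 + np.exp((230.0 - lam) / 15.0))
            )
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown source kind {self.kind!r}")
        return profile


@dataclass(frozen=True)
class ConcentrationField:
    """Spatial erythrocyte concentration C(x, y, z) on a finite grid."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    concentration: np.ndarray  # shape (nx, ny, nz), mol/L

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        expected = (len(self.x), len(self.y), len(self.z))
        if c.shape != expected:
            raise ValueError(f"concentration shape {c.shape} != grid shape {expected}")
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative everywhere")
        if not np.all(np.isfinite(c)):
            raise ValueError("concentration must be finite")
        object.__setattr__(self, "concentration", c)

    def total(self) -> float:
        """Integral of C over the spatial grid (trapezoid in each axis)."""
        c = np.trapezoid(self.concentration, np.asarray(self.x, float), axis=0)
        c = np.trapezoid(c, np.asarray(self.y, float), axis=0)
        return float(np.trapezoid(c, np.asarray(self.z, float), axis=0))


@dataclass(frozen=True)
class PatientProfile:
    """Physiological knobs behind one synthetic full-range patient spectrum."""

    hemoglobin_gdl: float
    oxygen_fraction: float
    glycation_pct: float = 5.0
    plasma_fraction: float = 0.5
    lifecycle_phase: LifecyclePhase = "mature"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hemoglobin_gdl <= 0:
            raise ValueError("hemoglobin_gdl must be positive")
        if not 0.0 <= self.oxygen_fraction <= 1.0:
            raise ValueError("oxygen_fraction must lie in [0, 1]")
        if not 0.0 <= self.plasma_fraction <= 1.0:
            raise ValueError("plasma_fraction must lie in [0, 1]")
        if self.glycation_pct < 0:
            raise ValueError("glycation_pct must be non-negative")
        if self.lifecycle_phase not in LIFECYCLE_MULTIPLIER:
            raise ValueError(f"unknown lifecycle phase {self.lifecycle_phase!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CBCRecord:
    """Complete-blood-count values for one subject (clinical units)."""

    hb_gdl: float
    rbc_1e6_per_ul: float
    hct_pct: float
    age_years: float
    sex: str
    mch_pg: float | None = None
    neutrophils_pct: float | None = None
    lymphocytes_pct: float | None = None
    eosinophils_pct: float | None = None
    basophils_pct: float | None = None
    condition: str = "none"

    def __post_init__(self) -> None:
        for name in ("hb_gdl", "rbc_1e6_per_ul", "hct_pct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("neutrophils_pct", "lymphocytes_pct", "eosinophils_pct", "basophils_pct"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")


def _validate_grid(grid: np.ndarray, name: str = "grid") -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError(f"{name} must be a 1-D array with at least 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError(f"{name} must be strictly increasing")
    return grid


def generate_eem(
    fluorophores: Sequence[FluorophoreSpec],
    source: ExcitationSource,
    ex_grid: np.ndarray,
    em_grid: np.ndarray,
    field_: ConcentrationField | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EEMatrix:
    """Excitation-emission matrix of a fluorophore mixture.

    Each component contributes a separable product of unit-height Gaussians
    in excitation and emission, scaled by quantum yield, source power at the
    excitation wavelength, molar absorptivity, and concentration. When a
    spatial concentration field is given, its integral replaces the scalar
    concentration as a common multiplier. Gaussian noise (sd ``noise_sd``)
    is added and the result clipped at zero.
    """
    if not fluorophores:
        raise ValueError("at least one fluorophore is required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    ex_grid = _validate_grid(ex_grid, "ex_grid")
    em_grid = _validate_grid(em_grid, "em_grid")

    field_factor = field_.total() if field_ is not None else 1.0

    intensity = np.zeros((ex_grid.size, em_grid.size))
    for f in fluorophores:
        ex_profile = (
            f.quantum_yield
            * source.power(ex_grid)
            * f.molar_absorptivity
            * f.concentration
            * field_factor
            * gaussian(ex_grid, f.ex_center, f.ex_width)
        )
        em_profile = gaussian(em_grid, f.em_center, f.em_width)
        intensity += np.outer(ex_profile, em_profile)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.shape)
        intensity = np.clip(intensity, 0.0, None)

    return EEMatrix(
        ex_wavelengths=ex_grid,
        em_wavelengths=em_grid,
        intensities=intensity,
        meta={
            "source": source.kind,
            "fluorophores": [f.name for f in fluorophores],
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# Hemoglobin absorption model parameters: a single dominant band at 550 nm
# whose height grows with oxygenation and shrinks (and broadens) with
# glycation.
HB_ABSORPTION_CENTER_NM = 550.0
HB_ABSORPTION_SIGMA_NM = 30.0
HB_DEOXY_BASE_AMPLITUDE = 0.4
HB_OXY_GAIN = 0.6
HB_GLYCATION_DECAY_PER_PCT = 0.08
HB_GLYCATION_BROADENING_PER_PCT = 0.03


def generate_absorption_spectrum(
    oxygen_fraction: float,
    glycation_pct: float,
    grid: np.ndarray,
    background: float = 0.0,
) -> Spectrum1D:
    """Simulated hemoglobin absorption spectrum on ``grid`` (nm).

    A single band centered at 550 nm: height strictly increasing in
    ``oxygen_fraction``, strictly decreasing and broadening with
    ``glycation_pct``. Deterministic (no noise).
    """
    if not 0.0 <= oxygen_fraction <= 1.0:
        raise ValueError("oxygen_fraction must lie in [0, 1]")
    if glycation_pct < 0:
        raise ValueError("glycation_pct must be non-negative")
    grid = _validate_grid(grid)
    if grid[0] > 400.0 or grid[-1] < 700.0:
        raise ValueError("grid must cover 400-700 nm")

    amplitude = (HB_DEOXY_BASE_AMPLITUDE + HB_OXY_GAIN * oxygen_fraction) * np.exp(
        -HB_GLYCATION_DECAY_PER_PCT * glycation_pct
    )
    sigma = HB_ABSORPTION_SIGMA_NM * (1.0 + HB_GLYCATION_BROADENING_PER_PCT * glycation_pct)
    intensities = background + amplitude * gaussian(grid, HB_ABSORPTION_CENTER_NM, sigma)
    return Spectrum1D(
        wavelengths=grid,
        intensities=intensities,
        role="absorbance",
        meta={
            "oxygen_fraction": oxygen_fraction,
            "glycation_pct": glycation_pct,
            "background": background,
        },
    )


# Band-component line shapes of the full-range patient model.
_BAND_SHAPES = {
    "hb_oxy": (550.0, 35.0),  # oxy/total hemoglobin, 400-600 nm region
    "deoxy": (650.0, 25.0),  # deoxyhemoglobin, 600-700 nm region
    "plasma": (850.0, 25.0),  # plasma/water, 800-900 nm region
}
_HB_OXY_SCALE = 1.0 / 15.0
_DEOXY_SCALE = 1.0 / 5.0
_PLASMA_SCALE = 1.0


def patient_band_components(
    profile: PatientProfile, source: ExcitationSource, grid: np.ndarray
) -> dict[str, np.ndarray]:
    """Noise-free per-band contributions of :func:`generate_patient_spectrum`."""
    grid = _validate_grid(grid)
    if grid[0] > 200.0 or grid[-1] < 900.0:
        raise ValueError("grid must span 200-900 nm")
    life = LIFECYCLE_MULTIPLIER[profile.lifecycle_phase]
    power = source.power(grid)
    amplitudes = {
        "hb_oxy": _HB_OXY_SCALE * profile.hemoglobin_gdl * profile.oxygen_fraction,
        "deoxy": _DEOXY_SCALE * profile.hemoglobin_gdl * (1.0 - profile.oxygen_fraction),
        "plasma": _PLASMA_SCALE * profile.plasma_fraction,
    }
    return {
        band: life * amp * power * gaussian(grid, center, sigma)
        for band, (center, sigma) in _BAND_SHAPES.items()
        for amp in (amplitudes[band],)
    }


def generate_patient_spectrum(
    profile: PatientProfile, source: ExcitationSource, grid: np.ndarray
) -> Spectrum1D:
    """Full-range (200-900 nm) spectrum of one synthetic patient.

    Superposition of three band components — oxy/total hemoglobin
    (400-600 nm), deoxyhemoglobin (600-700 nm), plasma/water (800-900 nm) —
    scaled by the source power profile and a life-cycle multiplier, plus
    Gaussian noise. Noise is clipped at zero except under UV excitation,
    where background-subtracted difference spectra legitimately go negative.
    """
    components = patient_band_components(profile, source, grid)
    grid = _validate_grid(grid)
    intensity = np.sum(list(components.values()), axis=0)

    if profile.noise_sd > 0:
        rng = np.random.default_rng(profile.seed)
        intensity = intensity + rng.normal(0.0, profile.noise_sd, intensity.shape)
        if source.kind != "UV" and "emission" in CLIPPED_ROLES:
            intensity = np.clip(intensity, 0.0, None)

    return Spectrum1D(
        wavelengths=grid,
        intensities=intensity,
        role="emission",
        source=source.kind,
        meta={
            "hemoglobin_gdl": profile.hemoglobin_gdl,
            "oxygen_fraction": profile.oxygen_fraction,
            "plasma_fraction": profile.plasma_fraction,
            "lifecycle_phase": profile.lifecycle_phase,
            "noise_sd": profile.noise_sd,
            "seed": profile.seed,
        },
    )


def mch_range_for_age(age_years: float) -> tuple[float, float]:
    """MCH reference range (pg) for an age; ages >= 45 reuse the adult bin."""
    if age_years < 0.5:
        raise ValueError("age below the youngest reference bin (6 months)")
    for lo, hi, mch_lo, mch_hi in MCH_AGE_BINS:
        if lo <= age_years < hi:
            return mch_lo, mch_hi
    raise AssertionError("unreachable: bins cover [0.5, inf)")


_DEFAULT_MCV_FL = (80.0, 96.0)
_DEFAULT_RBC_1E6 = (4.2, 5.8)


def generate_cbc(
    age_years: float,
    sex: str,
    condition: Condition = "none",
    seed: int = 0,
) -> CBCRecord:
    """One synthetic CBC record, self-consistent by construction.

    MCH is drawn uniformly within the age-appropriate reference range;
    iron deficiency shifts it below the lower bound, B12 deficiency above
    the upper bound. Hemoglobin is derived exactly as RBC x MCH and
    hematocrit as RBC x MCV, so the record satisfies the clinical identity
    Hb[g/dL] = RBC[10^6/uL] x MCH[pg] / 10.
    """
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    if condition not in ("none", "iron_deficiency", "b12_deficiency"):
        raise ValueError(f"unknown condition {condition!r}")
    mch_lo, mch_hi = mch_range_for_age(age_years)
    rng = np.random.default_rng(seed)

    if condition == "iron_deficiency":
        mch = rng.uniform(max(mch_lo - 8.0, 14.0), mch_lo - 0.5)
    elif condition == "b12_deficiency":
        mch = rng.uniform(mch_hi + 0.5, mch_hi + 8.0)
    else:
        mch = rng.uniform(mch_lo, mch_hi)

    rbc = rng.uniform(*_DEFAULT_RBC_1E6)
    mcv = rng.uniform(*_DEFAULT_MCV_FL)
    hb_gdl = rbc * mch / 10.0
    hct_pct = rbc * mcv / 10.0

    neut = rng.uniform(45.0, 70.0)
    lymph = rng.uniform(20.0, min(40.0, 98.0 - neut))
    eos = rng.uniform(0.5, 6.0)
    baso = rng.uniform(0.1, min(2.0, 100.0 - neut - lymph - eos))

    return CBCRecord(
        hb_gdl=hb_gdl,
        rbc_1e6_per_ul=rbc,
        hct_pct=hct_pct,
        mch_pg=mch,
        age_years=age_years,
        sex=sex,
        neutrophils_pct=neut,
        lymphocytes_pct=lymph,
        eosinophils_pct=eos,
        basophils_pct=baso,
        condition=condition,
    )


SCATTER_PEAK_SIGMA_NM = 30.0
SCATTER_PEAK_HEIGHT = 100.0


def generate_scattering_profile(
    true_diameter_um: float,
    k_um_per_nm: float,
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum1D:
    """Single-peaked scattering profile whose peak encodes cell diameter.

    The peak sits at the grid point nearest ``true_diameter / k`` so that the
    empirical diameter calibration R = k * lambda_peak round-trips.
    """
    if true_diameter_um <= 0:
        raise ValueError("true_diameter must be positive")
    if k_um_per_nm <= 0:
        raise ValueError("k must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = _validate_grid(grid)
    lam_peak = true_diameter_um / k_um_per_nm
    if not grid[0] <= lam_peak <= grid[-1]:
        raise ValueError(
            f"implied peak wavelength {lam_peak:.1f} nm outside grid span "
            f"[{grid[0]}, {grid[-1]}]"
        )
    lam_peak = float(grid[np.argmin(np.abs(grid - lam_peak))])

    intensity = SCATTER_PEAK_HEIGHT * gaussian(grid, lam_peak, SCATTER_PEAK_SIGMA_NM)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = np.clip(intensity + rng.normal(0.0, noise_sd, intensity.shape), 0.0, None)

    return Spectrum1D(
        wavelengths=grid,
        intensities=intensity,
        role="scattering",
        meta={
            "true_diameter_um": true_diameter_um,
            "k_um_per_nm": k_um_per_nm,
            "lam_peak_nm": lam_peak,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def demo_patient_profiles() -> tuple[PatientProfile, PatientProfile]:
    """The bundled two-patient fixture.

    Patient 1: higher hemoglobin, well oxygenated, plasma-rich. Patient 2:
    lower hemoglobin, poorly oxygenated, plasma-poor. Under any broadband
    source patient 1 wins the 400-600 and 800-900 nm bands and patient 2
    wins the 600-700 nm band.
    """
    p1 = PatientProfile(
        hemoglobin_gdl=16.4, oxygen_fraction=0.95, plasma_fraction=0.7,
        lifecycle_phase="mature", noise_sd=0.0, seed=11,
    )
    p2 = PatientProfile(
        hemoglobin_gdl=12.6, oxygen_fraction=0.60, plasma_fraction=0.3,
        lifecycle_phase="mature", noise_sd=0.0, seed=22,
    )
    return p1, p2


def demo_cbc_records() -> tuple[CBCRecord, CBCRecord]:
    """CBC records for the bundled two-patient fixture (clinical units)."""
    c1 = CBCRecord(
        hb_gdl=16.4, rbc_1e6_per_ul=5.32, hct_pct=46.9,
        age_years=35.0, sex="M",
        neutrophils_pct=50.0, lymphocytes_pct=37.3,
        eosinophils_pct=7.2, basophils_pct=4.2,
    )
    c2 = CBCRecord(
        hb_gdl=12.6, rbc_1e6_per_ul=4.36, hct_pct=38.5,
        age_years=35.0, sex="M",
        neutrophils_pct=65.4, lymphocytes_pct=28.0,
        eosinophils_pct=1.5, basophils_pct=0.5,
    )
    return c1, c2
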