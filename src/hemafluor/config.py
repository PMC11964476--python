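"""Pipeline configuration: every default that influences a number.

A :class:`PipelineConfig` validates on load and can be echoed into output
metadata so each run records the effective settings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

# Physical constants used across modules.
HEMOGLOBIN_MOLAR_MASS_G_PER_MOL = 64_500.0
DEFAULT_EPSILON_540 = 54_000.0  # L mol^-1 cm^-1; configurable placeholder


@dataclass
class GridConfig:
    lam_min_nm: float = 200.0
    lam_max_nm: float = 900.0
    step_nm: float = 0.5

    def __post_init__(self) -> None:
        if self.lam_min_nm >= self.lam_max_nm:
            raise ValueError("grid lam_min must be below lam_max")
        if self.step_nm <= 0:
            raise ValueError("grid step must be positive")


@dataclass
class PreprocessingConfig:
    baseline_window_nm: float = 50.0
    smooth_sigma_nm: float = 2.0
    prominence_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_window_nm <= 0:
            raise ValueError("baseline window must be positive")
        if self.smooth_sigma_nm < 0:
            raise ValueError("smoothing sigma must be non-negative")
        if not 0 < self.prominence_fraction < 1:
            raise ValueError("prominence fraction must lie in (0, 1)")


@dataclass
class PhotophysicsConfig:
    epsilon_540: float = DEFAULT_EPSILON_540
    hemoglobin_molar_mass: float = HEMOGLOBIN_MOLAR_MASS_G_PER_MOL
    path_length_cm: float = 1.0


@dataclass
class BiophysicsConfig:
    # Deformability-vs-zeta model constants.
    di_a: float = 1.5
    di_b_per_mv: float = -0.05
    di_c: float = 0.5
    # Scattering-diameter calibration, um per nm.
    scatter_k_um_per_nm: float = 0.009


@dataclass
class DiagnosticsConfig:
    tie_threshold: float = 0.01  # relative difference below which bands tie


@dataclass
class PipelineConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    photophysics: PhotophysicsConfig = field(default_factory=PhotophysicsConfig)
    biophysics: BiophysicsConfig = field(default_factory=BiophysicsConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "grid": GridConfig,
            "preprocessing": PreprocessingConfig,
            "photophysics": PhotophysicsConfig,
            "biophysics": BiophysicsConfig,
            "diagnostics": DiagnosticsConfig,
        }
        for key, typ in sections.items():
            if key in data:
                kwargs[key] = typ(**data[key])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        unknown = set(data) - set(sections) - {"seed"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
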