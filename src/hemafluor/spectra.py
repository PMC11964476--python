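"""Core spectral containers shared by every pipeline stage.

A :class:`Spectrum1D` is a single wavelength-resolved trace (emission,
absorbance, or scattering); an :class:`EEMatrix` is fluorescence intensity
over a 2-D (excitation, emission) wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Roles whose intensities are physically non-negative; additive noise is
#: clipped at zero for these. Absorbance and UV-difference traces may carry
#: negative excursions and are never clipped.
CLIPPED_ROLES = frozenset({"emission", "scattering"})

VALID_ROLES = ("emission", "absorbance", "scattering")


@dataclass
class Spectrum1D:
    """One spectrum: a strictly increasing wavelength grid plus intensities.

    Parameters
    ----------
    wavelengths
        Grid in nm, strictly increasing, at least 8 points.
    intensities
        Arbitrary-unit intensities, same length as ``wavelengths``. May be
        negative for difference spectra (UV background subtraction).
    role
        One of ``emission``, ``absorbance``, ``scattering``.
    source
        Excitation source kind this trace was recorded (or simulated) under.
    meta
        Free-form provenance: seeds, processing chain, config echo.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    role: str = "emission"
    source: str | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D arrays")
        if self.wavelengths.size != self.intensities.size:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavelengths.size < 8:
            raise ValueError("a spectrum needs at least 8 points")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {VALID_ROLES}")

    @property
    def step(self) -> float:
        """Median grid step in nm (grids are usually uniform)."""
        return float(np.median(np.diff(self.wavelengths)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def copy_with(self, intensities: np.ndarray, **meta: Any) -> "Spectrum1D":
        """New spectrum on the same grid with updated intensities and merged meta."""
        return Spectrum1D(
            wavelengths=self.wavelengths.copy(),
            intensities=np.asarray(intensities, dtype=float),
            role=self.role,
            source=self.source,
            meta={**self.meta, **meta},
        )

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class EEMatrix:
    """Excitation-emission matrix: intensity[i, j] at (ex[i], em[j])."""

    ex_wavelengths: np.ndarray
    em_wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ex_wavelengths = np.asarray(self.ex_wavelengths, dtype=float)
        self.em_wavelengths = np.asarray(self.em_wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        for name, grid in (("ex", self.ex_wavelengths), ("em", self.em_wavelengths)):
            if grid.ndim != 1 or grid.size < 2:
                raise ValueError(f"{name} grid must be 1-D with at least 2 points")
            if not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} grid must be strictly increasing")
        expected = (self.ex_wavelengths.size, self.em_wavelengths.size)
        if self.intensities.shape != expected:
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match grids {expected}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def argmax_wavelengths(self) -> tuple[float, float]:
        """(excitation nm, emission nm) of the global intensity maximum."""
        i, j = np.unravel_index(int(np.argmax(self.intensities)), self.intensities.shape)
        return float(self.ex_wavelengths[i]), float(self.em_wavelengths[j])


def gaussian(x: np.ndarray | float, center: float, sigma: float) -> np.ndarray | float:
    """Unit-height Gaussian line shape used for all synthetic peaks."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-0.5 * ((np.asarray(x, dtype=float) - center) / sigma) ** 2)
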