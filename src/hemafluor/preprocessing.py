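"""Spectral preprocessing chain and peak identification.

The chain is maximum-intensity normalization, rolling-minimum baseline
correction, and Gaussian smoothing, followed by prominence-gated local-maximum
detection with per-peak least-squares Gaussian refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, signal

from .spectra import EEMatrix, Spectrum1D
from .synthetic import FluorophoreSpec


@dataclass
class PeakFit:
    """One fitted spectral peak."""

    center: float  # nm
    sigma: float  # nm
    height: float  # a.u.
    assigned_fluorophore: str | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")


def normalize_max(s: Spectrum1D) -> Spectrum1D:
    """Divide by the maximum absolute intensity so max |value| = 1.

    Uses the absolute maximum (not the signed maximum) so that difference
    spectra with negative lobes normalize stably.
    """
    peak = float(np.max(np.abs(s.intensities)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return s.copy_with(s.intensities / peak, normalized=True, normalization_factor=peak)


def baseline_correct(s: Spectrum1D, window_nm: float = 50.0) -> Spectrum1D:
    """Subtract a rolling-minimum baseline, smoothed to avoid staircase edges.

    ``window_nm`` must be at least 3 grid steps and no larger than the grid
    span. Works for slowly varying backgrounds (constants, gentle ramps)
    under peaks narrower than the window.
    """
    step = s.step
    span = s.wavelengths[-1] - s.wavelengths[0]
    if window_nm < 3 * step:
        raise ValueError(f"baseline window {window_nm} nm is below 3 grid steps ({3 * step} nm)")
    if window_nm > span:
        raise ValueError(f"baseline window {window_nm} nm exceeds the grid span ({span} nm)")

    window_pts = max(3, int(round(window_nm / step)))
    baseline = ndimage.minimum_filter1d(s.intensities, size=window_pts, mode="nearest")
    baseline = ndimage.gaussian_filter1d(baseline, sigma=window_pts / 4.0, mode="nearest")
    return s.copy_with(s.intensities - baseline, baseline_window_nm=window_nm)


def _gaussian_kernel(sigma_pts: float) -> np.ndarray:
    radius = max(1, int(math.ceil(4.0 * sigma_pts)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma_pts) ** 2)
    return kernel / kernel.sum()


def gaussian_smooth(s: Spectrum1D, sigma_nm: float) -> Spectrum1D:
    """Convolve with a normalized, truncated (4 sigma) Gaussian kernel.

    Boundaries are handled by reflection, so constants are preserved exactly;
    sigma 0 is the identity.
    """
    if sigma_nm < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_nm == 0:
        return s.copy_with(s.intensities.copy(), smooth_sigma_nm=0.0)
    sigma_pts = sigma_nm / s.step
    kernel = _gaussian_kernel(sigma_pts)
    radius = (kernel.size - 1) // 2
    padded = np.pad(s.intensities, radius, mode="reflect")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return s.copy_with(smoothed, smooth_sigma_nm=sigma_nm)


def preprocess(
    s: Spectrum1D,
    baseline_window_nm: float = 50.0,
    smooth_sigma_nm: float = 2.0,
) -> Spectrum1D:
    """The full chain: normalize -> baseline -> smooth."""
    out = normalize_max(s)
    out = baseline_correct(out, baseline_window_nm)
    out = gaussian_smooth(out, smooth_sigma_nm)
    out.meta["preprocessing_chain"] = ["normalize_max", "baseline_correct", "gaussian_smooth"]
    return out


def _gauss_model(x: np.ndarray, height: float, center: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _refine_gaussian(
    wl: np.ndarray, ii: np.ndarray, idx: int, window_pts: int
) -> tuple[float, float, float]:
    """Least-squares single-Gaussian fit in a window around index ``idx``.

    Falls back to the raw sample if the fit fails or wanders out of window.
    """
    lo = max(0, idx - window_pts)
    hi = min(wl.size, idx + window_pts + 1)
    x, y = wl[lo:hi], ii[lo:hi]
    step = float(np.median(np.diff(wl)))
    h0 = float(ii[idx])
    c0 = float(wl[idx])
    # crude width guess: half-height crossing distance, else a few grid steps
    half = h0 / 2.0
    above = y >= half
    s0 = max((x[above][-1] - x[above][0]) / 2.355, 2.0 * step) if above.any() else 5.0
    try:
        popt, _ = optimize.curve_fit(
            _gauss_model, x, y, p0=(h0, c0, s0),
            # sigma below one grid step would let a single noisy sample
            # masquerade as an arbitrarily tall delta spike
            bounds=((0.0, x[0], step), (np.inf, x[-1], np.inf)),
            maxfev=2000,
        )
        height, center, sigma = float(popt[0]), float(popt[1]), float(popt[2])
        if height <= 0 or not np.isfinite([height, center, sigma]).all():
            raise RuntimeError("degenerate fit")
        if height > 2.0 * max(h0, 1e-300):
            raise RuntimeError("fit height inconsistent with data")
        return height, center, sigma
    except (RuntimeError, ValueError):
        return h0, c0, s0


def fit_peaks(
    s: Spectrum1D,
    max_peaks: int = 10,
    prominence_fraction: float = 0.05,
    fit_window_nm: float = 30.0,
) -> list[PeakFit]:
    """Detect and refine up to ``max_peaks`` peaks.

    Local maxima whose prominence exceeds ``prominence_fraction`` of the
    maximum absolute intensity are each refined by a least-squares Gaussian
    fit in a +-``fit_window_nm`` window. The result is sorted by descending
    height, ties broken by ascending wavelength. A flat or featureless
    spectrum yields an empty list.
    """
    scale = float(np.max(np.abs(s.intensities)))
    if scale == 0.0:
        return []
    idxs, _props = signal.find_peaks(s.intensities, prominence=prominence_fraction * scale)
    if idxs.size == 0:
        return []

    window_pts = max(3, int(round(fit_window_nm / s.step)))
    fits = []
    for idx in idxs:
        height, center, sigma = _refine_gaussian(s.wavelengths, s.intensities, int(idx), window_pts)
        if height > 0:
            fits.append(PeakFit(center=center, sigma=sigma, height=height))
    fits.sort(key=lambda p: (-p.height, p.center))
    return fits[:max_peaks]


def _slice_peak_center(grid: np.ndarray, values: np.ndarray, idx: int, width_nm: float) -> float:
    """Refined peak center of a 1-D EEM slice via a local Gaussian fit."""
    step = float(np.median(np.diff(grid)))
    window_pts = max(3, int(round(3.0 * width_nm / step)))
    _, center, _ = _refine_gaussian(grid, values, idx, window_pts)
    return center


def eem_peak_map(
    eem: EEMatrix,
    library: list[FluorophoreSpec],
    window_sigmas: float = 3.0,
) -> dict[str, tuple[float, float, float] | None]:
    """Locate each library fluorophore's peak on an EEM.

    For every entry, the search window is the fluorophore's nominal
    (ex_center +- window_sigmas * ex_width, em_center +- window_sigmas *
    em_width) box. The maximum inside the window must be a 2-D local maximum
    with positive intensity; its position is refined by separable 1-D
    Gaussian fits along the excitation and emission slices. Entries with no
    qualifying maximum map to ``None``.

    Returns
    -------
    dict mapping fluorophore name -> (excitation nm, emission nm, height)
    or None.
    """
    if not library:
        raise ValueError("fluorophore library must not be empty")

    out: dict[str, tuple[float, float, float] | None] = {}
    ex, em, ii = eem.ex_wavelengths, eem.em_wavelengths, eem.intensities
    for f in library:
        ex_mask = np.abs(ex - f.ex_center) <= window_sigmas * f.ex_width
        em_mask = np.abs(em - f.em_center) <= window_sigmas * f.em_width
        if not ex_mask.any() or not em_mask.any():
            out[f.name] = None
            continue
        ex_idx = np.flatnonzero(ex_mask)
        em_idx = np.flatnonzero(em_mask)
        sub = ii[np.ix_(ex_idx, em_idx)]
        if sub.max() <= 0:
            out[f.name] = None
            continue
        si, sj = np.unravel_index(int(np.argmax(sub)), sub.shape)
        i, j = int(ex_idx[si]), int(em_idx[sj])
        # require a genuine local maximum against neighbours in the full EEM
        neighbours = [
            ii[i - 1, j] if i > 0 else -np.inf,
            ii[i + 1, j] if i < ex.size - 1 else -np.inf,
            ii[i, j - 1] if j > 0 else -np.inf,
            ii[i, j + 1] if j < em.size - 1 else -np.inf,
        ]
        if ii[i, j] < max(neighbours):
            out[f.name] = None
            continue
        ex_peak = _slice_peak_center(ex, ii[:, j], i, f.ex_width)
        em_peak = _slice_peak_center(em, ii[i, :], j, f.em_width)
        out[f.name] = (ex_peak, em_peak, float(ii[i, j]))
    return out
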