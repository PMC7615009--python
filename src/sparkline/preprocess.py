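"""Baseline estimation, F/F0 normalisation and denoising.

The resting-fluorescence baseline F0 varies both along the scanned line
(uneven dye loading, cell edges) and slowly in time (bleaching, focus drift).
It is estimated per spatial pixel with an iterative robust temporal mean that
excludes bright (event) lines, smoothed along space, and modulated by a slowly
varying temporal drift profile.  Everything downstream works on F/F0 and on
the z-image (F/F0 - 1) / noise_sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import DetectionParams, LineScanImage

#: spatial smoothing of the per-pixel baseline, µm — kept below the scale of
#: sharp background bands, whose edges a heavier smooth would misfit,
#: leaving persistent F/F0 ridges that masquerade as events
BASELINE_SMOOTH_UM = 0.3
#: temporal smoothing of the drift profile, ms
DRIFT_SMOOTH_MS = 500.0
#: robust SD from the median absolute deviation of a Gaussian
MAD_TO_SD = 1.4826


@dataclass
class NormalizedImage:
    """F/F0 image plus the baseline map and robust noise scale."""

    values: np.ndarray  # F/F0, same axes as the source
    baseline: np.ndarray  # F0 map, counts
    noise_sigma: float  # robust SD of F/F0 in event-free pixels
    source: LineScanImage

    def __post_init__(self) -> None:
        if self.values.shape != self.baseline.shape:
            raise ValueError("values and baseline must share a shape")
        if float(self.baseline.min()) <= 0:
            raise ValueError("baseline must be strictly positive")
        if not self.noise_sigma > 0:
            raise ValueError("noise_sigma must be positive")

    @property
    def time_step(self) -> float:
        return self.source.time_step

    @property
    def pixel_size(self) -> float:
        return self.source.pixel_size

    @property
    def z(self) -> np.ndarray:
        """The z-image (F/F0 - 1) / noise_sigma (computed once, cached)."""
        cached = getattr(self, "_z", None)
        if cached is None:
            cached = (self.values - 1.0) / self.noise_sigma
            self._z = cached
        return cached


def estimate_baseline(
    image: LineScanImage, params: DetectionParams | None = None
) -> tuple[np.ndarray, float]:
    """Estimate the F0 baseline map and the noise scale.

    Per spatial pixel the temporal mean and SD are computed twice, excluding
    lines brighter than mean + ``baseline_exclusion_z``·SD after the first
    pass, so that release events do not inflate F0.  The per-pixel baseline is
    smoothed along space (1 µm Gaussian) and multiplied by a slow temporal
    drift profile (500 ms Gaussian of per-line medians, normalised to mean 1).

    Returns ``(baseline_map, noise_sigma)`` with ``noise_sigma`` in F/F0
    units, from the scaled median absolute deviation over included pixels.
    """
    if params is None:
        params = DetectionParams()
    pix = np.asarray(image.pixels, dtype=np.float64)
    n_t = pix.shape[0]

    include = np.ones(pix.shape, dtype=bool)
    for _ in range(2):
        counts = include.sum(axis=0)
        if np.any(counts == 0):
            raise ValueError("dead columns: no lines left to estimate baseline")
        mean = np.where(include, pix, 0.0).sum(axis=0) / counts
        var = np.where(include, (pix - mean[None, :]) ** 2, 0.0).sum(axis=0) / counts
        sd = np.sqrt(var)
        include = pix <= (mean + params.baseline_exclusion_z * sd)[None, :]

    counts = include.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("dead columns: no lines left to estimate baseline")
    col_baseline = np.where(include, pix, 0.0).sum(axis=0) / counts
    if np.any(col_baseline <= 0):
        raise ValueError("dead columns: zero robust baseline")

    sigma_px = BASELINE_SMOOTH_UM / image.pixel_size
    col_baseline = ndimage.gaussian_filter1d(col_baseline, sigma_px, mode="nearest")

    # slow multiplicative temporal drift from per-line medians of included px
    masked = np.where(include, pix / col_baseline[None, :], np.nan)
    drift = np.nanmedian(masked, axis=1)
    # lines fully excluded (e.g. a wave spanning the cell): interpolate
    bad = ~np.isfinite(drift)
    if bad.any():
        idx = np.arange(n_t)
        drift[bad] = np.interp(idx[bad], idx[~bad], drift[~bad])
    sigma_t = DRIFT_SMOOTH_MS / image.time_step
    drift = ndimage.gaussian_filter1d(drift, sigma_t, mode="nearest")
    drift /= drift.mean()

    baseline = drift[:, None] * col_baseline[None, :]

    resid = pix / baseline - 1.0
    dev = np.abs(resid[include] - np.median(resid[include]))
    noise_sigma = MAD_TO_SD * float(np.median(dev))
    if noise_sigma <= 0:
        # noiseless synthetic input: fall back to a tiny positive scale so the
        # z-image stays defined
        noise_sigma = 1e-6
    return baseline, noise_sigma


def normalize(image: LineScanImage, baseline: np.ndarray, noise_sigma: float) -> NormalizedImage:
    """Divide the image by its baseline map, elementwise."""
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.shape != image.pixels.shape:
        raise ValueError("baseline shape must match the image")
    values = np.asarray(image.pixels, dtype=np.float64) / baseline
    return NormalizedImage(values=values, baseline=baseline, noise_sigma=noise_sigma, source=image)


def _kernel_noise_factor(sigma_t_px: float, sigma_x_px: float) -> float:
    """sqrt of the sum of squared Gaussian kernel weights — the factor by
    which white-noise SD shrinks under the discrete filter."""
    factor = 1.0
    for s in (sigma_t_px, sigma_x_px):
        if s <= 0:
            continue
        r = max(1, int(4 * s + 0.5))
        x = np.arange(-r, r + 1, dtype=np.float64)
        k = np.exp(-0.5 * (x / s) ** 2)
        k /= k.sum()
        factor *= float(np.sqrt(np.sum(k**2)))
    return factor


def denoise(norm: NormalizedImage, params: DetectionParams) -> NormalizedImage:
    """Gaussian smoothing with physically specified widths.

    Sigmas are given in ms (time) and µm (space) and converted to pixels via
    the calibration.  ``noise_sigma`` is rescaled by the theoretical
    white-noise reduction factor of the discrete kernel, so the z-image keeps
    its scale.  Zero sigmas disable smoothing (identity).
    """
    sigma_t = params.denoise_sigma_time / norm.time_step
    sigma_x = params.denoise_sigma_space / norm.pixel_size
    if sigma_t <= 0 and sigma_x <= 0:
        return norm
    values = ndimage.gaussian_filter(
        norm.values, sigma=(max(sigma_t, 0.0), max(sigma_x, 0.0)), mode="nearest"
    )
    factor = _kernel_noise_factor(sigma_t, sigma_x)
    return NormalizedImage(
        values=values,
        baseline=norm.baseline,
        noise_sigma=norm.noise_sigma * factor,
        source=norm.source,
    )


def preprocess(image: LineScanImage, params: DetectionParams | None = None) -> NormalizedImage:
    """Baseline → normalise → denoise, the full step-1 chain."""
    if params is None:
        params = DetectionParams()
    baseline, noise_sigma = estimate_baseline(image, params)
    norm = normalize(image, baseline, noise_sigma)
    return denoise(norm, params)
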