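"""Pseudo-line scans from 2D time-lapse spark recordings.

Spinning-disk recordings of (typically curved) smooth muscle cells are
videos, not line scans.  A user-drawn polyline through the cell turns each
frame into one scan line: frames are denoised (Gaussian blur, 3x3 mean
smooth) and background-subtracted (rolling ball), then resampled along the
polyline at unit spacing with bilinear interpolation — frame index becomes
the time axis, arc length the space axis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

from .io_formats import LineScanImage

#: consecutive segments approaching each other closer than this (px) trigger
#: a double-back warning (a single spark must not be sampled twice)
DOUBLE_BACK_PX = 5.0


def preprocess_stack(
    stack: np.ndarray,
    blur_sigma: float = 1.0,
    rolling_ball_radius: int = 25,
) -> np.ndarray:
    """Per-frame Gaussian blur → 3x3 mean smooth → rolling-ball background
    subtraction."""
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be frames x rows x cols with >= 2 frames")
    if rolling_ball_radius >= min(stack.shape[1], stack.shape[2]):
        raise ValueError("rolling-ball radius must be below the frame size")
    out = np.empty_like(stack)
    for i, frame in enumerate(stack):
        if blur_sigma > 0:
            frame = ndimage.gaussian_filter(frame, blur_sigma, mode="nearest")
        frame = ndimage.uniform_filter(frame, size=3, mode="nearest")
        background = rolling_ball(frame, radius=rolling_ball_radius)
        out[i] = frame - background
    return out


def _sample_points(polyline: np.ndarray, spacing: float) -> np.ndarray:
    """Points at fixed arc-length spacing along a polyline, including the
    first vertex and the final vertex's arc length."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total <= 0:
        raise ValueError("polyline has zero length")
    s = np.arange(0.0, total, spacing)
    if total - s[-1] > 1e-9:
        s = np.append(s, total)
    rows = np.interp(s, cum, polyline[:, 0])
    cols = np.interp(s, cum, polyline[:, 1])
    return np.stack([rows, cols], axis=1)


def _warn_double_back(polyline: np.ndarray) -> None:
    for i in range(1, len(polyline) - 1):
        prev = polyline[i] - polyline[i - 1]
        nxt = polyline[i + 1] - polyline[i]
        # distance from the next vertex back to the previous segment
        a, b, c = polyline[i - 1], polyline[i], polyline[i + 1]
        ab = b - a
        denom = float(np.dot(ab, ab))
        t = float(np.clip(np.dot(c - a, ab) / denom, 0.0, 1.0)) if denom else 0.0
        dist = float(np.hypot(*(c - (a + t * ab))))
        turning_back = float(np.dot(prev, nxt)) < 0
        if turning_back and dist < DOUBLE_BACK_PX:
            warnings.warn(
                f"polyline doubles back within {DOUBLE_BACK_PX} px near vertex "
                f"{i}; a single event may be sampled twice",
                stacklevel=3,
            )


def reslice(
    stack: np.ndarray,
    polyline,
    spacing: float = 1.0,
    frame_interval_ms: float = 10.0,
    pixel_size_um: float = 1.0,
) -> LineScanImage:
    """Resample a stack along a polyline into a line scan.

    ``polyline`` is a list of (row, col) vertices inside the frame.  Output
    axis 0 is the frame index (time), axis 1 the arc-length position;
    off-grid samples are bilinearly interpolated.  Calibration:
    ``time_step = frame_interval_ms``, ``pixel_size = pixel_size_um ·
    spacing``.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("stack must be frames x rows x cols")
    polyline = np.asarray(polyline, dtype=np.float64)
    if polyline.ndim != 2 or polyline.shape[0] < 2 or polyline.shape[1] != 2:
        raise ValueError("polyline must be a list of >= 2 (row, col) vertices")
    n_rows, n_cols = stack.shape[1], stack.shape[2]
    if (
        polyline[:, 0].min() < 0
        or polyline[:, 1].min() < 0
        or polyline[:, 0].max() > n_rows - 1
        or polyline[:, 1].max() > n_cols - 1
    ):
        raise ValueError("polyline vertex outside the frame")
    _warn_double_back(polyline)

    pts = _sample_points(polyline, spacing)
    coords = np.stack([pts[:, 0], pts[:, 1]])  # (2, n_samples)
    lines = np.empty((stack.shape[0], pts.shape[0]))
    for i, frame in enumerate(stack):
        lines[i] = ndimage.map_coordinates(frame, coords, order=1, mode="nearest")
    lines = np.clip(lines, 0.0, None)
    return LineScanImage(
        pixels=lines,
        time_step=frame_interval_ms,
        pixel_size=pixel_size_um * spacing,
        bit_depth=16,
        source_path="pseudo-line-scan",
    )
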