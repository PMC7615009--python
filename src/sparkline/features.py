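"""Per-event measurements and recording-level statistics.

For each segmented event a fluorescence trace is extracted by averaging the
sub-image over space while ignoring pixels that belong to *other* events
(edges of which may reach into the window).  From the trace and the spatial
profile through the peak line come amplitude (peak ΔF/F0), FDHM/FWHM with
linear sub-sample interpolation of the half-maximum crossings, and the decay
time constant from a least-squares exponential fit.  Full duration and width
are the segmented object's bounding-box extents.

Also here: the recording summary (per-class counts, spark frequency per
100 µm per s, median + IQR per feature), the spark-latency density map, and
the post-wave refractoriness test (spark frequency in a 150 ms window after
each wave versus matched random control boxes, paired t test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .detect import (
    CLASS_LONG_SPARK,
    CLASS_MINIWAVE,
    CLASS_SPARK,
    CLASS_WAVE,
    EVENT_CLASSES,
    DetectionResult,
    ReleaseEvent,
)
from .io_formats import FEATURE_COLUMNS, LabelMask
from .preprocess import NormalizedImage

#: margin (ms) appended to the event window for traces and the decay fit
TRACE_PAD_MS = 20.0
#: spatial padding (µm) of the profile window around an event
PROFILE_PAD_UM = 2.0
#: decay constants above this are treated as fit failures downstream filters
#: may also exclude (e.g. tau > 120 ms as a mis-segmentation flag)
TAU_FAILURE_FACTOR = 10.0


@dataclass
class EventFeatures:
    """Measured properties of one release event (ms / µm / ΔF/F0 units)."""

    amplitude: float
    peak_f_f0: float
    full_width: float
    fwhm: float
    full_duration: float
    fdhm: float
    time_to_peak: float
    tau_decay: float | None
    peak_time: float
    peak_position: float
    degenerate: bool = False


@dataclass
class MeasuredEvent:
    """A detected event together with its measured features."""

    event: ReleaseEvent
    features: EventFeatures

    def row(self) -> dict:
        e, f = self.event, self.features
        return {
            "id": e.label,
            "class": e.event_class,
            "t_start_ms": e.bbox[0],
            "t_end_ms": e.bbox[1],
            "x_start_um": e.bbox[2],
            "x_end_um": e.bbox[3],
            "peak_time_ms": f.peak_time,
            "peak_position_um": f.peak_position,
            "amplitude": f.amplitude,
            "peak_f_f0": f.peak_f_f0,
            "full_width_um": f.full_width,
            "fwhm_um": f.fwhm,
            "full_duration_ms": f.full_duration,
            "fdhm_ms": f.fdhm,
            "time_to_peak_ms": f.time_to_peak,
            "tau_decay_ms": f.tau_decay if f.tau_decay is not None else np.nan,
            "score": e.score,
        }


def event_trace(
    norm: NormalizedImage,
    event: ReleaseEvent,
    all_events: LabelMask,
    pad_ms: float = TRACE_PAD_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially averaged F/F0 trace of one event.

    For every line in the event's time window (padded by ``pad_ms`` on both
    sides) the F/F0 values inside the event's spatial window are averaged,
    excluding pixels labelled as a *different* event.  Lines with no
    admissible pixel are NaN.

    Returns ``(line_indices, trace)``.
    """
    t0, t1, x0, x1 = event.bbox_px
    pad = int(round(pad_ms / norm.time_step))
    lo = max(0, t0 - pad)
    hi = min(norm.values.shape[0], t1 + pad)
    window = norm.values[lo:hi, x0:x1]
    labels = all_events.labels[lo:hi, x0:x1]
    admissible = (labels == 0) | (labels == event.label)
    counts = admissible.sum(axis=1)
    sums = np.where(admissible, window, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        trace = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return np.arange(lo, hi), trace


def _half_crossing_extent(
    y: np.ndarray, peak: int, level: float, step: float
) -> float:
    """Extent of the contiguous region around ``peak`` where ``y >= level``,
    with linear interpolation of the two boundary crossings.  NaN samples
    terminate the region.  Regions truncated by the array edge end at the
    edge (no extrapolation)."""
    n = len(y)
    ok = np.isfinite(y)

    left = peak
    while left - 1 >= 0 and ok[left - 1] and y[left - 1] >= level:
        left -= 1
    right = peak
    while right + 1 < n and ok[right + 1] and y[right + 1] >= level:
        right += 1

    start = float(left)
    if left - 1 >= 0 and ok[left - 1] and y[left - 1] < level:
        frac = (y[left] - level) / (y[left] - y[left - 1])
        start = left - frac
    end = float(right)
    if right + 1 < n and ok[right + 1] and y[right + 1] < level:
        frac = (y[right] - level) / (y[right] - y[right + 1])
        end = right + frac
    return (end - start) * step


def fit_decay_tau(
    trace: np.ndarray,
    peak_index: int,
    time_step: float,
    end_index: int | None = None,
) -> float | None:
    """Decay time constant from a least-squares fit of ``A·exp(-t/τ) + C``.

    The fit covers the post-peak trace up to ``end_index`` (the event end
    plus a margin).  Returns ``None`` when fewer than 4 post-peak samples are
    available, the trace does not decay, the fit does not converge, or the
    fitted τ falls outside ``(0, 10 × window]``.
    """
    if end_index is None:
        end_index = len(trace)
    y = np.asarray(trace[peak_index:end_index], dtype=np.float64)
    t = np.arange(len(y)) * time_step
    keep = np.isfinite(y)
    y, t = y[keep], t[keep]
    if len(y) < 4:
        return None
    window = float(t[-1]) if t[-1] > 0 else time_step
    if float(y.max() - y.min()) < 1e-9:
        return None  # constant trace: no decay to fit

    a0 = float(y[0] - y[-1])
    c0 = float(y[-1])
    tau0 = max(window / 3.0, time_step)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    import warnings

    for mult in (1.0, 0.3, 3.0, 0.1, 10.0):
        try:
            with warnings.catch_warnings():
                # degenerate covariance is routine on near-perfect fits
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    model,
                    t,
                    y,
                    p0=(a0 if a0 != 0 else 1e-3, tau0 * mult, c0),
                    maxfev=2000,
                )
        except RuntimeError:
            continue
        a, tau, _ = popt
        if a > 0 and 0 < tau <= TAU_FAILURE_FACTOR * window:
            return float(tau)
    return None


def measure_event(
    norm: NormalizedImage, event: ReleaseEvent, all_events: LabelMask
) -> EventFeatures:
    """Measure amplitude, widths, durations and decay tau of one event."""
    t0, t1, x0, x1 = event.bbox_px
    lines, trace = event_trace(norm, event, all_events)
    in_event = (lines >= t0) & (lines < t1) & np.isfinite(trace)
    if not in_event.any():
        # every line of the window is owned by other events
        raise ValueError(f"event {event.label}: no admissible trace samples")
    masked = np.where(in_event, trace, -np.inf)
    peak_i = int(np.argmax(masked))
    peak_f_f0 = float(trace[peak_i])
    amplitude = peak_f_f0 - 1.0
    peak_line = int(lines[peak_i])
    peak_time = peak_line * norm.time_step

    # temporal half-maximum duration
    level_t = 1.0 + amplitude / 2.0
    fdhm = _half_crossing_extent(trace, peak_i, level_t, norm.time_step)

    # spatial profile through the peak line, padded, other events excluded
    pad_px = int(round(PROFILE_PAD_UM / norm.pixel_size))
    lo = max(0, x0 - pad_px)
    hi = min(norm.values.shape[1], x1 + pad_px)
    row_vals = norm.values[peak_line, lo:hi]
    row_labels = all_events.labels[peak_line, lo:hi]
    admissible = (row_labels == 0) | (row_labels == event.label)
    profile = np.where(admissible, row_vals, np.nan)
    own = (np.arange(lo, hi) >= x0) & (np.arange(lo, hi) < x1) & np.isfinite(profile)
    if own.any():
        pk_x = int(np.argmax(np.where(own, profile, -np.inf)))
        level_x = 1.0 + (float(profile[pk_x]) - 1.0) / 2.0
        fwhm = _half_crossing_extent(profile, pk_x, level_x, norm.pixel_size)
        peak_position = (lo + pk_x) * norm.pixel_size
    else:
        fwhm = norm.pixel_size
        peak_position = event.peak_position_um

    full_duration = event.bbox[1] - event.bbox[0]
    full_width = event.bbox[3] - event.bbox[2]
    degenerate = event.area_px == 1
    fdhm = min(fdhm, full_duration)
    fwhm = min(fwhm, full_width)

    end_i = int(np.searchsorted(lines, t1 - 1, side="right"))
    margin = int(round(TRACE_PAD_MS / norm.time_step))
    tau = fit_decay_tau(
        trace, peak_i, norm.time_step, end_index=min(len(trace), end_i + margin)
    )

    return EventFeatures(
        amplitude=amplitude,
        peak_f_f0=peak_f_f0,
        full_width=full_width,
        fwhm=fwhm,
        full_duration=full_duration,
        fdhm=fdhm,
        time_to_peak=peak_time - event.bbox[0],
        tau_decay=tau,
        peak_time=peak_time,
        peak_position=peak_position,
        degenerate=degenerate,
    )


def measure_all(result: DetectionResult) -> list[MeasuredEvent]:
    """Measure every event of a detection result."""
    return [
        MeasuredEvent(ev, measure_event(result.norm, ev, result.mask))
        for ev in result.events
    ]


# ---------------------------------------------------------------------------
# Recording summary


@dataclass
class RecordingSummary:
    """One-recording statistics: per-class counts, spark frequency
    (per 100 µm per s) and median + IQR per feature."""

    counts: dict[str, int]
    spark_frequency: float
    duration_s: float
    scan_length_um: float
    feature_stats: dict[str, tuple[float, float, float]]  # median, q1, q3
    source: str = ""

    @property
    def n_events(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        row: dict = {"source": self.source}
        for cls in EVENT_CLASSES:
            row[f"n_{cls}"] = self.counts.get(cls, 0)
        row["n_events"] = self.n_events
        row["duration_s"] = self.duration_s
        row["scan_length_um"] = self.scan_length_um
        row["spark_frequency_per_100um_per_s"] = self.spark_frequency
        for name in FEATURE_COLUMNS:
            med, q1, q3 = self.feature_stats.get(name, (np.nan, np.nan, np.nan))
            row[f"{name}_median"] = med
            row[f"{name}_q1"] = q1
            row[f"{name}_q3"] = q3
        return pd.DataFrame([row])


def summarize(
    measured: list[MeasuredEvent],
    image,
    merge_long_sparks: bool = False,
    source: str = "",
) -> RecordingSummary:
    """Summarise a recording.

    ``spark_frequency = 100 · n_sparks / (scan_length_µm · duration_s)``,
    counting only spark-class events; with ``merge_long_sparks`` long sparks
    count as sparks.  Quartiles use linear interpolation; undefined feature
    values (e.g. failed tau fits) are ignored.  ``image`` only needs
    ``duration_ms`` and ``scan_length_um``.
    """
    counts = {cls: 0 for cls in EVENT_CLASSES}
    for m in measured:
        counts[m.event.event_class] += 1
    n_sparks = counts[CLASS_SPARK] + (counts[CLASS_LONG_SPARK] if merge_long_sparks else 0)
    duration_s = image.duration_ms / 1000.0
    scan_length = image.scan_length_um
    freq = 100.0 * n_sparks / (scan_length * duration_s)

    frame = pd.DataFrame([m.row() for m in measured]) if measured else pd.DataFrame()
    feature_stats = {}
    for name in FEATURE_COLUMNS:
        if len(frame) and frame[name].notna().any():
            vals = frame[name].dropna().to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            feature_stats[name] = (float(med), float(q1), float(q3))
        else:
            feature_stats[name] = (np.nan, np.nan, np.nan)
    return RecordingSummary(
        counts=counts,
        spark_frequency=freq,
        duration_s=duration_s,
        scan_length_um=scan_length,
        feature_stats=feature_stats,
        source=source,
    )


# ---------------------------------------------------------------------------
# Latency map and refractoriness


def latency_map(
    events: list[ReleaseEvent],
    image,
    spatial_radius: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Time since the preceding release event, per pixel.

    For pixel (t, x) the map holds ``t`` minus the end time of the latest
    event pixel at spatial positions within ``spatial_radius`` (µm) of ``x``
    and time ≤ t, clamped at 0 inside events.  Pixels with no preceding event
    get their own time coordinate and are flagged invalid in the companion
    mask.

    Returns ``(map_ms, valid)``.
    """
    n_t, n_x = image.n_lines, image.n_pixels
    dt = image.time_step
    mask = np.zeros((n_t, n_x), dtype=bool)
    for ev in events:
        mask[ev.pixels] = True
    r_px = int(round(spatial_radius / image.pixel_size))
    if r_px > 0:
        mask = ndimage.maximum_filter1d(mask.astype(np.uint8), 2 * r_px + 1, axis=1) > 0

    t_idx = np.arange(n_t)[:, None]
    last = np.maximum.accumulate(np.where(mask, t_idx, -1), axis=0)
    valid = last >= 0
    lat = np.where(valid, np.clip(t_idx - last - 1, 0, None), t_idx).astype(np.float64)
    return lat * dt, valid


#: scale factor: events per µm·ms → events per 100 µm per s
_FREQ_SCALE = 100.0 * 1000.0


def refractoriness_test(
    events: list[ReleaseEvent],
    image,
    window: float = 150.0,
    n_controls: int = 5,
    seed: int = 0,
    max_tries: int = 500,
) -> tuple[float, float, float]:
    """Post-wave spark frequency versus matched random control boxes.

    For every wave/miniwave a box spanning the event's spatial extent and
    ``[t_end, t_end + window)`` is placed; sparks whose peak falls inside are
    counted.  Matched controls are same-size boxes placed uniformly at random
    (seeded), rejected if they intersect any wave/miniwave or its following
    window.  The per-event (post, mean-of-controls) frequency pairs enter a
    paired t test (closed form; two-sided p from the t distribution).

    Returns ``(freq_post_wave, freq_control, p_value)`` with frequencies in
    sparks per 100 µm per s.
    """
    waves = [e for e in events if e.event_class in (CLASS_WAVE, CLASS_MINIWAVE)]
    if not waves:
        raise ValueError("refractoriness test requires at least one wave or miniwave")
    sparks = [e for e in events if e.event_class == CLASS_SPARK]
    spark_t = np.array([e.peak_time_ms for e in sparks])
    spark_x = np.array([e.peak_position_um for e in sparks])

    duration = image.duration_ms
    length = image.scan_length_um

    # forbidden rectangles: each wave's extent plus its following window
    forbidden = [
        (w.bbox[0], w.bbox[1] + window, w.bbox[2], w.bbox[3]) for w in waves
    ]

    def count(t0, t1, x0, x1):
        if len(spark_t) == 0:
            return 0
        return int(
            np.count_nonzero(
                (spark_t >= t0) & (spark_t < t1) & (spark_x >= x0) & (spark_x < x1)
            )
        )

    def intersects(t0, t1, x0, x1):
        return any(
            t0 < ft1 and ft0 < t1 and x0 < fx1 and fx0 < x1
            for ft0, ft1, fx0, fx1 in forbidden
        )

    # distinct stream key: control placement must never replay the draws of
    # a generator that was seeded with the same integer
    rng = np.random.default_rng([seed, 0x5EED])
    post_freqs, control_freqs = [], []
    for w in waves:
        x0, x1 = w.bbox[2], w.bbox[3]
        width = x1 - x0
        t0 = w.bbox[1]
        t1 = min(t0 + window, duration)
        area = max(t1 - t0, 1e-9) * width
        post_freqs.append(count(t0, t1, x0, x1) / area * _FREQ_SCALE)

        ctrls = []
        tries = 0
        while len(ctrls) < n_controls:
            tries += 1
            if tries > max_tries * n_controls:
                raise RuntimeError(
                    "could not place control boxes avoiding waves and their "
                    f"{window} ms follow-up windows"
                )
            ct0 = rng.uniform(0, max(duration - window, 1e-9))
            cx0 = rng.uniform(0, max(length - width, 1e-9))
            ct1, cx1 = ct0 + window, cx0 + width
            if intersects(ct0, ct1, cx0, cx1):
                continue
            ctrls.append(count(ct0, ct1, cx0, cx1) / (window * width) * _FREQ_SCALE)
        control_freqs.append(float(np.mean(ctrls)))

    post = np.asarray(post_freqs)
    ctrl = np.asarray(control_freqs)
    d = post - ctrl
    n = len(d)
    if n < 2:
        raise ValueError("paired test requires at least 2 waves")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        p = 1.0 if float(np.mean(d)) == 0.0 else 0.0
    else:
        t_stat = float(np.mean(d)) / (sd / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t_stat), df=n - 1))
    return float(np.mean(post)), float(np.mean(ctrl)), p
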