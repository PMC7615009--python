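"""Detection, scoring, classification and splitting of calcium release events.

Pipeline (on the normalised image):

1. threshold the z-image at a permissive ``candidate_z`` and take connected
   components — candidate events;
2. score each candidate by its brightness AND size with a saturating score in
   [0, 1]; candidates below ``detect_threshold`` are rejected as noise;
3. classify retained objects into spark / long spark / miniwave / wave from
   their half-maximum width and duration;
4. split spark-scale clusters into unitary events with a marker-controlled
   watershed (waves and miniwaves are never split, so large propagating
   events cannot be fragmented into pseudo-sparks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .io_formats import DetectionParams, LabelMask, LineScanImage
from .preprocess import NormalizedImage, preprocess

CLASS_SPARK = "spark"
CLASS_LONG_SPARK = "long_spark"
CLASS_MINIWAVE = "miniwave"
CLASS_WAVE = "wave"
EVENT_CLASSES = (CLASS_SPARK, CLASS_LONG_SPARK, CLASS_MINIWAVE, CLASS_WAVE)


@dataclass
class ReleaseEvent:
    """One segmented calcium release event.

    ``pixels`` holds the (time, space) index arrays of the event's pixel set;
    ``bbox`` is the tight physical bounding box (t_start, t_end, x_start,
    x_end) in ms/µm, half-open.
    """

    label: int
    event_class: str
    pixels: tuple[np.ndarray, np.ndarray]
    bbox: tuple[float, float, float, float]
    bbox_px: tuple[int, int, int, int]  # (t0, t1, x0, x1), half-open indices
    score: float
    peak_time_ms: float = float("nan")
    peak_position_um: float = float("nan")

    @property
    def area_px(self) -> int:
        return int(self.pixels[0].size)

    def pixel_index_set(self) -> set[tuple[int, int]]:
        return set(zip(self.pixels[0].tolist(), self.pixels[1].tolist()))


@dataclass
class DetectionResult:
    """Events plus the final label mask and the normalised image they came
    from.  Event labels run 1..K and match the mask."""

    events: list[ReleaseEvent]
    mask: LabelMask
    norm: NormalizedImage
    params: DetectionParams

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


def _skimage_connectivity(connectivity: int) -> int:
    return 1 if connectivity == 4 else 2


def detect_candidates(norm: NormalizedImage, params: DetectionParams) -> LabelMask:
    """Brightness-based candidate detection (deliberately permissive).

    Thresholds the z-image at ``candidate_z``, labels connected components and
    drops components smaller than ``min_event_area`` (µm·ms).
    """
    z = norm.z
    binary = z > params.candidate_z
    labels = cc_label(binary, connectivity=_skimage_connectivity(params.connectivity))
    px_area = norm.pixel_size * norm.time_step
    min_px = params.min_event_area / px_area
    if min_px > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_px)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    return LabelMask(labels.astype(np.int32)).relabel_sequential()


def score_object(
    pixels: tuple[np.ndarray, np.ndarray],
    norm: NormalizedImage,
    params: DetectionParams,
) -> float:
    """Combined size-and-brightness score in [0, 1].

    ``score = sqrt(s_b · s_a)`` with the brightness term
    ``s_b = z̄ / (z̄ + z_half)`` (z̄ = mean z over the object's brightest
    quartile of pixels) and the size term ``s_a = A / (A + A_half)``
    (A = area in µm·ms).  Monotone in both; saturates at 1.
    """
    tt, xx = pixels
    if tt.size == 0:
        raise ValueError("empty pixel set cannot be scored")
    zvals = norm.z[tt, xx]
    k = max(1, int(np.ceil(zvals.size / 4)))
    top = np.partition(zvals, zvals.size - k)[-k:]
    z_bar = max(float(top.mean()), 0.0)
    area = tt.size * norm.pixel_size * norm.time_step
    s_b = z_bar / (z_bar + params.score_z_half)
    s_a = area / (area + params.score_area_half)
    return float(np.sqrt(s_b * s_a))


def _half_max_extent(profile: np.ndarray, step: float) -> float:
    """Contiguous extent (physical units) of a profile around its maximum at
    half maximum.  The profile is the per-column/per-line max of the object's
    z-values (NaN outside).  Contiguity matters: a cluster of separate sparks
    dips below half max between peaks and must not measure as one wide event,
    whereas genuine propagating release is contiguous."""
    finite = np.isfinite(profile)
    if not finite.any():
        return 0.0
    vals = np.where(finite, profile, -np.inf)
    peak = int(np.argmax(vals))
    half = vals[peak] / 2.0
    left = peak
    while left - 1 >= 0 and vals[left - 1] >= half:
        left -= 1
    right = peak
    while right + 1 < len(vals) and vals[right + 1] >= half:
        right += 1
    return float(right - left + 1) * step


def classify_event(
    pixels: tuple[np.ndarray, np.ndarray],
    norm: NormalizedImage,
    params: DetectionParams,
) -> str:
    """Classify an object from its half-maximum width and duration.

    Width ≥ ``wave_min_width`` → wave; width in [``miniwave_min_width``,
    ``wave_min_width``) → miniwave; narrow but lasting ≥
    ``long_spark_min_duration`` → long spark; else spark.
    """
    tt, xx = pixels
    zvals = norm.z[tt, xx]
    # max-projection profiles over the object's own pixels
    spatial = np.full(int(xx.max()) + 1, -np.inf)
    np.maximum.at(spatial, xx, zvals)
    spatial[np.isneginf(spatial)] = np.nan
    temporal = np.full(int(tt.max()) + 1, -np.inf)
    np.maximum.at(temporal, tt, zvals)
    temporal[np.isneginf(temporal)] = np.nan

    width = _half_max_extent(spatial, norm.pixel_size)
    duration = _half_max_extent(temporal, norm.time_step)

    if width >= params.wave_min_width:
        return CLASS_WAVE
    if width >= params.miniwave_min_width:
        return CLASS_MINIWAVE
    if duration >= params.long_spark_min_duration:
        return CLASS_LONG_SPARK
    return CLASS_SPARK


def _split_markers(
    dff: np.ndarray,
    component: np.ndarray,
    norm: NormalizedImage,
    params: DetectionParams,
) -> list[tuple[int, int]]:
    """Local maxima of ΔF/F0 inside one component that survive the prominence
    (h-maxima) and anisotropic minimum-separation filters."""
    # adaptive prominence: bright spark pairs separate on a modest relative
    # dip, but the dip must always clear the (denoised) noise floor; the
    # configured value caps it
    peak_dff = float(dff[component].max())
    h = min(
        params.split_min_prominence,
        max(0.10 * peak_dff, 2.5 * norm.noise_sigma),
    )
    sub = np.where(component, dff, dff[component].min() - 1.0)
    peaks_mask = h_maxima(sub, h) & component
    if not peaks_mask.any():
        # degenerate plateau: fall back to the single global max
        tt, xx = np.nonzero(component)
        i = int(np.argmax(dff[tt, xx]))
        return [(int(tt[i]), int(xx[i]))]
    peak_labels = cc_label(peaks_mask, connectivity=2)
    candidates = []
    for lab in range(1, peak_labels.max() + 1):
        tt, xx = np.nonzero(peak_labels == lab)
        i = int(np.argmax(dff[tt, xx]))
        candidates.append((float(dff[tt[i], xx[i]]), int(tt[i]), int(xx[i])))
    candidates.sort(reverse=True)

    dx = norm.pixel_size / params.split_min_distance
    dt = norm.time_step / params.split_min_distance_time
    accepted: list[tuple[int, int]] = []
    for _, t, x in candidates:
        ok = all(
            ((t - t0) * dt) ** 2 + ((x - x0) * dx) ** 2 >= 1.0
            for t0, x0 in accepted
        )
        if ok:
            accepted.append((t, x))
    return accepted


def split_clusters(
    candidates: LabelMask, norm: NormalizedImage, params: DetectionParams
) -> LabelMask:
    """Split spark-scale clusters into unitary events.

    Within each spark/long-spark-scale component, prominent local maxima of
    ΔF/F0 separated by at least ``split_min_distance`` (µm) /
    ``split_min_distance_time`` (ms) in the elliptical metric become markers
    of a watershed on the inverted ΔF/F0 image.  Pixels are conserved: the
    children partition the parent.  Wave- and miniwave-class components are
    returned unchanged.
    """
    labels = candidates.labels
    dff = norm.values - 1.0
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    conn = _skimage_connectivity(params.connectivity)
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        component = labels[slc] == lab
        tt, xx = np.nonzero(component)
        cls = classify_event(
            (tt + slc[0].start, xx + slc[1].start), norm, params
        )
        sub_dff = dff[slc]
        markers_pts: list[tuple[int, int]]
        if cls in (CLASS_WAVE, CLASS_MINIWAVE):
            markers_pts = []
        else:
            markers_pts = _split_markers(sub_dff, component, norm, params)
        if len(markers_pts) <= 1:
            out[slc][component] = next_label
            next_label += 1
            continue
        markers = np.zeros(component.shape, dtype=np.int32)
        for i, (t, x) in enumerate(markers_pts, start=1):
            markers[t, x] = i
        ws = watershed(-sub_dff, markers=markers, mask=component, connectivity=conn)
        for i in range(1, len(markers_pts) + 1):
            child = ws == i
            if child.any():
                out[slc][child] = next_label
                next_label += 1
    return LabelMask(out).relabel_sequential()


def _event_from_pixels(
    label: int,
    pixels: tuple[np.ndarray, np.ndarray],
    norm: NormalizedImage,
    params: DetectionParams,
    score: float,
    event_class: str,
) -> ReleaseEvent:
    tt, xx = pixels
    t0, t1 = int(tt.min()), int(tt.max()) + 1
    x0, x1 = int(xx.min()), int(xx.max()) + 1
    i = int(np.argmax(norm.z[tt, xx]))
    return ReleaseEvent(
        label=label,
        event_class=event_class,
        pixels=pixels,
        bbox=(
            t0 * norm.time_step,
            t1 * norm.time_step,
            x0 * norm.pixel_size,
            x1 * norm.pixel_size,
        ),
        bbox_px=(t0, t1, x0, x1),
        score=score,
        peak_time_ms=float(tt[i]) * norm.time_step,
        peak_position_um=float(xx[i]) * norm.pixel_size,
    )


def detect_events(
    image: LineScanImage, params: DetectionParams | None = None
) -> DetectionResult:
    """Run the full detection pipeline on a calibrated line scan.

    Returns a :class:`DetectionResult` whose events carry final labels 1..K
    matching the returned mask.  The pipeline is deterministic: identical
    image and parameters give identical results.
    """
    if params is None:
        params = DetectionParams()
    norm = preprocess(image, params)
    return detect_events_normalized(norm, params)


def detect_events_normalized(
    norm: NormalizedImage, params: DetectionParams
) -> DetectionResult:
    """Detection pipeline steps 2-4 on an already-normalised image."""
    candidates = detect_candidates(norm, params)

    # score filter before splitting
    kept = np.zeros_like(candidates.labels)
    next_label = 1
    for lab, slc in enumerate(ndimage.find_objects(candidates.labels), start=1):
        if slc is None:
            continue
        comp = candidates.labels[slc] == lab
        tt, xx = np.nonzero(comp)
        pix = (tt + slc[0].start, xx + slc[1].start)
        if score_object(pix, norm, params) >= params.detect_threshold:
            kept[slc][comp] = next_label
            next_label += 1
    retained = LabelMask(kept.astype(np.int32))

    split = split_clusters(retained, norm, params)

    # re-score and re-classify the (possibly split) children
    events: list[ReleaseEvent] = []
    final = np.zeros_like(split.labels)
    next_label = 1
    for lab, slc in enumerate(ndimage.find_objects(split.labels), start=1):
        if slc is None:
            continue
        comp = split.labels[slc] == lab
        tt, xx = np.nonzero(comp)
        pix = (tt + slc[0].start, xx + slc[1].start)
        score = score_object(pix, norm, params)
        if score < params.detect_threshold:
            continue
        cls = classify_event(pix, norm, params)
        final[slc][comp] = next_label
        events.append(_event_from_pixels(next_label, pix, norm, params, score, cls))
        next_label += 1
    return DetectionResult(
        events=events, mask=LabelMask(final.astype(np.int32)), norm=norm, params=params
    )
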