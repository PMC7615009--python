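"""Synthetic line-scan generator with ground-truth masks.

Emulates the structure of real permeabilized-myocyte line scans: a background
with slow spatial variation (dark/bright bands and per-column gain jitter),
repetitive spark bands (a column where a similar spark repeats in time),
couplets of adjacent sparks, a large number of isolated sparks with a minimum
separation, and Gaussian noise.  Only spark-scale events are generated — no
waves — so benchmarks built on it measure spark detection specifically.

Spark shapes are parametric: a spatial Gaussian times a rise/decay
exponential in time.  ``template_library`` accepts user-supplied 2D template
stacks so that empirically recorded spark shapes can be dropped in instead.

Amplitudes are dialled so the dimmest sparks sit at or below the noise floor:
a detector (or human) comparison on these images therefore probes the false
negative rate, not just the easy bright events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import LabelMask, LineScanImage, write_linescan, write_mask


class PlacementError(RuntimeError):
    """Raised when the requested event counts cannot be placed under the
    separation constraints (counts are never silently reduced)."""


@dataclass
class SynthParams:
    """Generator settings; most values are randomised per image within these
    bounds.  Defaults mirror mouse ventricular line-scan geometry
    (2604 lines x 1024 px, 1.92 ms/line, 0.1 µm/px, 12-bit) and spark
    statistics of 30-100 sparks per image."""

    image_shape: tuple[int, int] = (2604, 1024)  # (lines, pixels)
    time_step: float = 1.92  # ms / line
    pixel_size: float = 0.1  # µm / px
    bit_depth: int = 12
    background_level_range: tuple[float, float] = (300.0, 800.0)  # counts
    n_bands_range: tuple[int, int] = (2, 6)
    band_brightness_shift_range: tuple[float, float] = (-80.0, 80.0)  # counts
    column_gain_jitter: float = 0.03  # gain ~ U(1-j, 1+j)
    n_repetitive_bands_range: tuple[int, int] = (0, 2)
    n_couplets_range: tuple[int, int] = (2, 6)
    n_sparks_range: tuple[int, int] = (30, 100)
    spark_amplitude_range: tuple[float, float] = (0.1, 1.0)  # ΔF/F0
    spark_width_range: tuple[float, float] = (0.5, 1.1)  # Gaussian σ, µm
    spark_duration_range: tuple[float, float] = (15.0, 40.0)  # decay τ, ms
    rise_tau_range: tuple[float, float] = (2.0, 6.0)  # ms
    couplet_distance_range: tuple[float, float] = (1.5, 3.0)  # µm
    couplet_time_scale: float = 10.0  # ms of temporal offset per µm
    min_spark_separation: tuple[float, float] = (2.0, 40.0)  # (µm, ms)
    noise_sd_range: tuple[float, float] = (15.0, 40.0)  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_repetitive_bands_range
        if not (0 <= lo <= hi <= 2):
            raise ValueError("n_repetitive_bands_range must lie within {0..2}")
        for name in (
            "background_level_range",
            "n_bands_range",
            "n_couplets_range",
            "n_sparks_range",
            "spark_amplitude_range",
            "spark_width_range",
            "spark_duration_range",
            "rise_tau_range",
            "couplet_distance_range",
            "noise_sd_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty")
        if self.spark_amplitude_range[0] <= 0:
            raise ValueError("spark amplitudes must be positive")

    def replace(self, **kwargs) -> "SynthParams":
        import dataclasses

        return dataclasses.replace(self, **kwargs)


@dataclass
class SparkPlacement:
    """Ground-truth record of one placed spark."""

    label: int
    kind: str  # isolated | couplet | repetitive
    peak_t_idx: int
    peak_x_idx: int
    amplitude: float  # ΔF/F0
    width_sigma: float  # µm
    decay_tau: float  # ms
    rise_tau: float  # ms


#: fraction of the peak below which the template is truncated to zero
TEMPLATE_TRUNCATION = 0.01


def spark_template(
    width_sigma: float,
    rise_tau: float,
    decay_tau: float,
    amplitude: float,
    time_step: float,
    pixel_size: float,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Separable parametric spark template in ΔF/F0 units.

    Spatial Gaussian(σ = ``width_sigma`` µm) times the temporal kernel
    ``(1 - exp(-t/rise_tau)) * exp(-t/decay_tau)``, normalised so the peak
    equals ``amplitude``; values below 1% of the peak are truncated to zero
    and the array is cropped to the non-zero support.

    Returns ``(template, (peak_t, peak_x))`` — the array (time x space) and
    the peak's index within it.
    """
    if min(width_sigma, rise_tau, decay_tau, amplitude) <= 0:
        raise ValueError("all template parameters must be positive")
    # analytic peak time of the rise/decay kernel
    t_peak = rise_tau * np.log(1.0 + decay_tau / rise_tau)
    # extend until the decay envelope is safely below truncation
    t_end = t_peak + decay_tau * np.log(1.0 / TEMPLATE_TRUNCATION) + 3 * decay_tau
    t = np.arange(0.0, t_end, time_step)
    g = (1.0 - np.exp(-t / rise_tau)) * np.exp(-t / decay_tau)
    g /= g.max()

    sigma_px = width_sigma / pixel_size
    half = int(np.ceil(sigma_px * np.sqrt(-2.0 * np.log(TEMPLATE_TRUNCATION)))) + 1
    x = np.arange(-half, half + 1, dtype=np.float64)
    s = np.exp(-0.5 * (x / sigma_px) ** 2)

    tmpl = amplitude * np.outer(g, s)
    tmpl[tmpl < TEMPLATE_TRUNCATION * amplitude] = 0.0
    # crop trailing rows / outer columns to the support; the leading t = 0
    # row (zero, by the rise term) is kept so the template starts dark
    rows = np.flatnonzero(tmpl.any(axis=1))
    cols = np.flatnonzero(tmpl.any(axis=0))
    tmpl = tmpl[: rows[-1] + 1, cols[0] : cols[-1] + 1]
    pk = np.unravel_index(int(np.argmax(tmpl)), tmpl.shape)
    return tmpl, (int(pk[0]), int(pk[1]))


def template_library(stack: np.ndarray | None = None):
    """Return a callable drawing spark templates.

    With ``stack=None`` the parametric shape of :func:`spark_template` is
    used.  A user-supplied ``stack`` (n x time x space, ΔF/F0 peak-normalised
    to 1) substitutes empirically recorded shapes: the callable then rescales
    a randomly picked member to the requested amplitude.
    """
    if stack is None:
        def draw(rng, p: SynthParams, amplitude: float):
            sigma = rng.uniform(*p.spark_width_range)
            decay = rng.uniform(*p.spark_duration_range)
            rise = rng.uniform(*p.rise_tau_range)
            tmpl, pk = spark_template(
                sigma, rise, decay, amplitude, p.time_step, p.pixel_size
            )
            return tmpl, pk, dict(width_sigma=sigma, decay_tau=decay, rise_tau=rise)

        return draw

    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("template stack must be n x time x space")

    def draw(rng, p: SynthParams, amplitude: float):
        tmpl = stack[rng.integers(len(stack))] * amplitude
        tmpl = tmpl.copy()
        tmpl[tmpl < TEMPLATE_TRUNCATION * amplitude] = 0.0
        pk = np.unravel_index(int(np.argmax(tmpl)), tmpl.shape)
        return tmpl, (int(pk[0]), int(pk[1])), dict(
            width_sigma=float("nan"), decay_tau=float("nan"), rise_tau=float("nan")
        )

    return draw


def _too_close(
    t_idx: int,
    x_idx: int,
    placed: list[SparkPlacement],
    p: SynthParams,
    skip: set[int] = frozenset(),
) -> bool:
    sep_x_px = p.min_spark_separation[0] / p.pixel_size
    sep_t_px = p.min_spark_separation[1] / p.time_step
    for q in placed:
        if q.label in skip:
            continue
        d = ((t_idx - q.peak_t_idx) / sep_t_px) ** 2 + (
            (x_idx - q.peak_x_idx) / sep_x_px
        ) ** 2
        if d < 1.0:
            return True
    return False


class _Canvas:
    """ΔF/F0 accumulation plus per-pixel ownership for the ground-truth mask
    (overlap pixels belong to the spark contributing the larger value)."""

    def __init__(self, shape):
        self.dff = np.zeros(shape, dtype=np.float64)
        self.labels = np.zeros(shape, dtype=np.int32)
        self.best = np.zeros(shape, dtype=np.float64)

    def add(self, tmpl: np.ndarray, t0: int, x0: int, label: int) -> None:
        sl = (slice(t0, t0 + tmpl.shape[0]), slice(x0, x0 + tmpl.shape[1]))
        self.dff[sl] += tmpl
        support = tmpl > 0
        win_best = self.best[sl]
        win_lab = self.labels[sl]
        take = support & (tmpl > win_best)
        win_best[take] = tmpl[take]
        win_lab[take] = label


def _place(
    rng, canvas: _Canvas, draw, p: SynthParams, amplitude: float, kind: str,
    placed: list[SparkPlacement],
    fixed: tuple[int, int] | None = None,
    skip_sep: set[int] = frozenset(),
    max_tries: int = 300,
) -> SparkPlacement:
    n_t, n_x = canvas.dff.shape
    tmpl, (pk_t, pk_x), info = draw(rng, p, amplitude)
    if tmpl.shape[0] >= n_t or tmpl.shape[1] >= n_x:
        raise PlacementError("spark template larger than the image")
    for _ in range(max_tries):
        if fixed is not None:
            t_pk, x_pk = fixed
        else:
            t_pk = int(rng.integers(pk_t, n_t - (tmpl.shape[0] - pk_t)))
            x_pk = int(rng.integers(pk_x, n_x - (tmpl.shape[1] - pk_x)))
        t0, x0 = t_pk - pk_t, x_pk - pk_x
        inside = (
            0 <= t0
            and 0 <= x0
            and t0 + tmpl.shape[0] <= n_t
            and x0 + tmpl.shape[1] <= n_x
        )
        if inside and not _too_close(t_pk, x_pk, placed, p, skip=skip_sep):
            label = len(placed) + 1
            canvas.add(tmpl, t0, x0, label)
            sp = SparkPlacement(
                label=label, kind=kind, peak_t_idx=t_pk, peak_x_idx=x_pk,
                amplitude=amplitude, **info,
            )
            placed.append(sp)
            return sp
        if fixed is not None:
            break
    raise PlacementError(
        f"could not place a {kind} spark after {max_tries} tries "
        f"(min_spark_separation={p.min_spark_separation})"
    )


def generate_image(
    params: SynthParams, seed: int | None = None, templates=None
) -> tuple[LineScanImage, LabelMask, list[SparkPlacement]]:
    """Generate one synthetic line scan, its ground-truth mask and the
    placement list.  Deterministic given the seed.

    Construction order: background (level + bands + column gain) →
    repetitive spark bands → couplets → isolated sparks → multiplicative
    combination ``background * (1 + ΣΔF/F0)`` → Gaussian noise → clipping to
    the bit depth.
    """
    p = params
    rng = np.random.default_rng(p.seed if seed is None else seed)
    n_t, n_x = p.image_shape
    draw = template_library(templates)

    # --- background
    level = rng.uniform(*p.background_level_range)
    background = np.full((n_t, n_x), level, dtype=np.float64)
    n_bands = int(rng.integers(p.n_bands_range[0], p.n_bands_range[1] + 1))
    x_idx = np.arange(n_x, dtype=np.float64)
    for _ in range(n_bands):
        shift = rng.uniform(*p.band_brightness_shift_range)
        center = rng.uniform(0, n_x)
        width = rng.uniform(0.03, 0.15) * n_x
        background += shift * np.exp(-0.5 * ((x_idx - center) / width) ** 2)[None, :]
    gain = rng.uniform(1 - p.column_gain_jitter, 1 + p.column_gain_jitter, size=n_x)
    background *= gain[None, :]
    background = np.clip(background, 1.0, None)

    canvas = _Canvas((n_t, n_x))
    placed: list[SparkPlacement] = []

    # --- repetitive spark bands: one column position, a rescaled reference
    # spark repeated (aperiodically) in time with varied intensity
    n_rep = int(
        rng.integers(p.n_repetitive_bands_range[0], p.n_repetitive_bands_range[1] + 1)
    )
    sep_t_lines = p.min_spark_separation[1] / p.time_step
    for _ in range(n_rep):
        base_amp = rng.uniform(*p.spark_amplitude_range)
        sigma = rng.uniform(*p.spark_width_range)
        decay = rng.uniform(*p.spark_duration_range)
        rise = rng.uniform(*p.rise_tau_range)
        tmpl0, _ = spark_template(
            sigma, rise, decay, 1.0, p.time_step, p.pixel_size
        )
        margin_x = int(np.ceil(tmpl0.shape[1] / 2)) + 1
        x_pk = int(rng.integers(margin_x, n_x - margin_x))
        t = float(rng.uniform(0, 3 * sep_t_lines))
        while True:
            t += float(rng.uniform(1.2 * sep_t_lines, 4.0 * sep_t_lines))
            t_pk = int(t)
            if t_pk >= n_t - tmpl0.shape[0]:
                break
            amp = base_amp * rng.uniform(0.7, 1.3)
            amp = float(np.clip(amp, *p.spark_amplitude_range))

            def draw_fixed(rng_, p_, amplitude, _s=sigma, _d=decay, _r=rise):
                tm, pk = spark_template(
                    _s, _r, _d, amplitude, p_.time_step, p_.pixel_size
                )
                return tm, pk, dict(width_sigma=_s, decay_tau=_d, rise_tau=_r)

            try:
                _place(
                    rng, canvas, draw_fixed, p, amp, "repetitive", placed,
                    fixed=(t_pk, x_pk),
                    skip_sep={q.label for q in placed
                              if q.kind == "repetitive" and q.peak_x_idx == x_pk},
                )
            except PlacementError:
                continue  # this repeat collides with a previous band; skip it

    # --- couplets: second member at a random angle and (tight) distance
    n_couplets = int(rng.integers(p.n_couplets_range[0], p.n_couplets_range[1] + 1))
    for _ in range(n_couplets):
        amp1 = rng.uniform(*p.spark_amplitude_range)
        first = _place(rng, canvas, draw, p, amp1, "couplet", placed)
        amp2 = rng.uniform(*p.spark_amplitude_range)
        dist = rng.uniform(*p.couplet_distance_range)  # µm
        for _ in range(100):
            theta = rng.uniform(0, 2 * np.pi)
            dx_px = dist * np.cos(theta) / p.pixel_size
            dt_px = dist * np.sin(theta) * p.couplet_time_scale / p.time_step
            t_pk = first.peak_t_idx + int(round(dt_px))
            x_pk = first.peak_x_idx + int(round(dx_px))
            try:
                _place(
                    rng, canvas, draw, p, amp2, "couplet", placed,
                    fixed=(t_pk, x_pk), skip_sep={first.label},
                )
                break
            except PlacementError:
                continue
        else:
            raise PlacementError("could not place the second couplet member")

    # --- isolated sparks
    n_sparks = int(rng.integers(p.n_sparks_range[0], p.n_sparks_range[1] + 1))
    for _ in range(n_sparks):
        amp = rng.uniform(*p.spark_amplitude_range)
        _place(rng, canvas, draw, p, amp, "isolated", placed)

    # --- combine, add noise, clip
    image = background * (1.0 + canvas.dff)
    noise_sd = rng.uniform(*p.noise_sd_range)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    vmax = 2**p.bit_depth - 1
    n_clipped = int(np.count_nonzero(image > vmax))
    image = np.clip(np.rint(image), 0, vmax).astype(np.uint16)

    ls = LineScanImage(
        pixels=image,
        time_step=p.time_step,
        pixel_size=p.pixel_size,
        bit_depth=p.bit_depth,
        source_path=f"synthetic(seed={p.seed if seed is None else seed})",
    )
    ls.clipped_fraction = n_clipped / image.size
    mask = LabelMask(canvas.labels)
    return ls, mask, placed


def generate_dataset(
    params: SynthParams, n_images: int, out_dir
) -> pd.DataFrame:
    """Write ``n_images`` image/mask pairs plus a manifest CSV.

    Per-image seeds are derived from ``params.seed``; regenerating from the
    manifest's seeds reproduces the files bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    child_seeds = derive_seeds(params.seed, n_images)
    rows = []
    for i, s in enumerate(child_seeds):
        image, mask, placed = generate_image(params, seed=int(s))
        img_path = out / f"synthetic_{i:03d}.tif"
        mask_path = out / f"synthetic_{i:03d}_mask.tif"
        write_linescan(image, img_path)
        write_mask(mask, mask_path)
        rows.append(
            {
                "image": img_path.name,
                "mask": mask_path.name,
                "seed": int(s),
                "n_sparks": len(placed),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-image seeds (below 2**31) from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# Event layouts (no pixel rendering) for recording-level statistics


@dataclass
class RecordingGeometry:
    """Calibrated extent of a recording without pixel data; enough for
    frequency, latency and refractoriness computations."""

    n_lines: int
    n_pixels: int
    time_step: float  # ms
    pixel_size: float  # µm

    @property
    def duration_ms(self) -> float:
        return self.n_lines * self.time_step

    @property
    def scan_length_um(self) -> float:
        return self.n_pixels * self.pixel_size


def generate_event_layout(
    n_waves: int = 20,
    spark_rate: float = 20.0,  # sparks per 100 µm per s
    suppress_ms: float = 0.0,
    seed: int = 0,
    n_lines: int = 26000,
    n_pixels: int = 1024,
    time_step: float = 1.92,
    pixel_size: float = 0.1,
    wave_width_um: float = 30.0,
    wave_duration_ms: float = 100.0,
    spark_extent: tuple[float, float] = (2.0, 30.0),  # (µm, ms)
    max_tries: int = 10_000,
):
    """Generate a wave + spark event layout without rendering pixels.

    Waves are placed without overlap of their post-wave windows; sparks
    follow a homogeneous Poisson process over the recording, excluded from
    the wave rectangles themselves and — when ``suppress_ms > 0`` — also
    from the ``suppress_ms`` window after each wave within the wave's
    spatial extent (release refractoriness).  With ``suppress_ms = 0`` the
    spark field is the uniform null.

    Returns ``(events, geometry)`` with :class:`ReleaseEvent` instances.
    """
    from .detect import CLASS_SPARK, CLASS_WAVE, ReleaseEvent

    rng = np.random.default_rng(seed)
    geom = RecordingGeometry(n_lines, n_pixels, time_step, pixel_size)
    duration, length = geom.duration_ms, geom.scan_length_um
    guard = max(suppress_ms, 200.0)

    def make_event(label, cls, t0, t1, x0, x1):
        ti = int(((t0 + t1) / 2) / time_step)
        xi = int(((x0 + x1) / 2) / pixel_size)
        return ReleaseEvent(
            label=label,
            event_class=cls,
            pixels=(np.array([ti]), np.array([xi])),
            bbox=(t0, t1, x0, x1),
            bbox_px=(
                int(t0 / time_step), max(int(t1 / time_step), int(t0 / time_step) + 1),
                int(x0 / pixel_size), max(int(x1 / pixel_size), int(x0 / pixel_size) + 1),
            ),
            score=1.0,
            peak_time_ms=(t0 + t1) / 2,
            peak_position_um=(x0 + x1) / 2,
        )

    events = []
    wave_rects: list[tuple[float, float, float, float]] = []
    tries = 0
    while len(wave_rects) < n_waves:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n_waves} non-overlapping waves"
            )
        t0 = rng.uniform(0, duration - wave_duration_ms - guard)
        x0 = rng.uniform(0, length - wave_width_um)
        rect = (t0, t0 + wave_duration_ms, x0, x0 + wave_width_um)
        padded = (rect[0], rect[1] + guard, rect[2], rect[3])
        if any(
            padded[0] < r[1] + guard and r[0] < padded[1]
            and padded[2] < r[3] and r[2] < padded[3]
            for r in wave_rects
        ):
            continue
        wave_rects.append(rect)
        events.append(make_event(len(events) + 1, CLASS_WAVE, *rect))

    n_sparks = rng.poisson(spark_rate * (length / 100.0) * (duration / 1000.0))
    w_um, d_ms = spark_extent
    placed = 0
    while placed < n_sparks:
        t = rng.uniform(0, duration - d_ms)
        x = rng.uniform(0, length - w_um)
        tc, xc = t + d_ms / 2, x + w_um / 2
        in_wave = any(r[0] <= tc < r[1] and r[2] <= xc < r[3] for r in wave_rects)
        suppressed = suppress_ms > 0 and any(
            r[1] <= tc < r[1] + suppress_ms and r[2] <= xc < r[3]
            for r in wave_rects
        )
        if in_wave or suppressed:
            placed += 1  # the event is swallowed/suppressed, not re-drawn
            continue
        events.append(make_event(len(events) + 1, CLASS_SPARK, t, t + d_ms, x, x + w_um))
        placed += 1
    return events, geom
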