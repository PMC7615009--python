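"""Seeded closed-loop benchmarks: generator → detector → matcher.

These drive the package's self-evaluation: detection accuracy on synthetic
ground truth at the two standard thresholds (0.45 sensitive / 0.6 less
sensitive), and the refractoriness statistic on wave/spark event layouts.
Benchmarks run on a 1024 x 512 px canvas (≈ 2 s x 51 µm at 1.92 ms/line,
0.1 µm/px) with 20-40 sparks per image — the full-frame geometry scaled to
half extent in both axes with spark density preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

from .detect import detect_events
from .evaluate import match_events
from .features import refractoriness_test
from .io_formats import DetectionParams
from .synth import SynthParams, derive_seeds, generate_event_layout, generate_image

SENSITIVE_THRESHOLD = 0.45
LESS_SENSITIVE_THRESHOLD = 0.6


def benchmark_synth_params(seed: int = 0, **overrides) -> SynthParams:
    """Benchmark-scale generator settings (reduced canvas, same density)."""
    base = dict(
        image_shape=(1024, 512),
        n_sparks_range=(20, 40),
        n_couplets_range=(2, 4),
        n_repetitive_bands_range=(0, 2),
        seed=seed,
    )
    base.update(overrides)
    return SynthParams(**base)


@dataclass
class DetectionBenchmark:
    tp: int
    fp: int
    fn: int
    n_images: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp)


def run_detection_benchmark(
    n_images: int,
    seed: int,
    params: DetectionParams | None = None,
    **synth_overrides,
) -> DetectionBenchmark:
    """Generate ``n_images`` seeded images, detect, and match against ground
    truth (Dice ≥ 0.15)."""
    if params is None:
        params = DetectionParams()
    tp = fp = fn = 0
    for s in derive_seeds(seed, n_images):
        sp = benchmark_synth_params(seed=int(s), **synth_overrides)
        image, mask, _ = generate_image(sp)
        result = detect_events(image, params)
        res = match_events(mask, result.mask)
        tp += res.tp
        fp += res.fp
        fn += res.fn
    return DetectionBenchmark(tp=tp, fp=fp, fn=fn, n_images=n_images)


def high_amplitude_benchmark(n_images: int = 10, seed: int = 0) -> DetectionBenchmark:
    """Images restricted to clearly visible sparks (ΔF/F0 ≥ 0.8)."""
    return run_detection_benchmark(
        n_images, seed, spark_amplitude_range=(0.8, 1.0)
    )


def threshold_ordering_benchmark(
    n_images: int = 30, seed: int = 0
) -> dict[float, DetectionBenchmark]:
    """Detection errors at the sensitive and less-sensitive thresholds on a
    shared image set (full amplitude range, dimmest sparks near-invisible)."""
    out = {}
    for th in (SENSITIVE_THRESHOLD, LESS_SENSITIVE_THRESHOLD):
        out[th] = run_detection_benchmark(
            n_images, seed, params=DetectionParams(detect_threshold=th)
        )
    return out


def refractoriness_benchmark(
    seed: int = 0, n_waves: int = 20, suppress_ms: float = 150.0
) -> tuple[float, float, float]:
    """Post-wave vs control spark frequency on a layout with true
    suppression; returns (freq_post, freq_control, p)."""
    events, geom = generate_event_layout(
        n_waves=n_waves, suppress_ms=suppress_ms, seed=seed
    )
    return refractoriness_test(events, geom, seed=seed)


def refractoriness_null_rate(n_runs: int = 100, seed: int = 0) -> float:
    """Fraction of null-layout runs in which the paired test is
    non-significant at the 5% level."""
    nonsig = 0
    for s in derive_seeds(seed, n_runs):
        events, geom = generate_event_layout(
            n_waves=20, suppress_ms=0.0, seed=int(s)
        )
        _, _, p = refractoriness_test(events, geom, seed=int(s))
        nonsig += p >= 0.05
    return nonsig / n_runs
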