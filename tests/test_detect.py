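"""Candidate detection, scoring, classification, splitting, orchestration."""

import numpy as np
import pytest

from sparkline import (
    DetectionParams,
    LineScanImage,
    classify_event,
    detect_candidates,
    detect_events,
    score_object,
    split_clusters,
    spark_template,
)
from sparkline.preprocess import NormalizedImage, preprocess


def make_norm(dff, noise_sigma=0.05, dt=1.0, dx=0.1):
    """NormalizedImage with a prescribed ΔF/F0 field (baseline = 100)."""
    dff = np.asarray(dff, dtype=np.float64)
    source = LineScanImage(100.0 * (1.0 + np.clip(dff, -0.99, None)),
                           time_step=dt, pixel_size=dx, bit_depth=16)
    return NormalizedImage(values=1.0 + dff, baseline=np.full(dff.shape, 100.0),
                           noise_sigma=noise_sigma, source=source)


def insert(canvas, tmpl, t0, x0):
    nt = min(tmpl.shape[0], canvas.shape[0] - t0)
    nx = min(tmpl.shape[1], canvas.shape[1] - x0)
    canvas[t0:t0 + nt, x0:x0 + nx] += tmpl[:nt, :nx]
    return canvas


class TestDetectCandidates:
    def test_single_bright_template_gives_one_candidate(self):
        dff = np.zeros((256, 128))
        tmpl, (pt, px) = spark_template(0.8, 4.0, 25.0, 1.0, 1.0, 0.1)
        insert(dff, tmpl, 60, 40)
        rng = np.random.default_rng(0)
        norm = make_norm(dff + rng.normal(0, 0.05, dff.shape))
        mask = detect_candidates(norm, DetectionParams())
        # the component containing the true peak exists and is unique there
        peak_label = mask.labels[60 + pt, 40 + px]
        assert peak_label > 0

    def test_candidate_pixels_grow_as_threshold_drops(self):
        rng = np.random.default_rng(1)
        norm = make_norm(rng.normal(0, 0.05, (128, 64)))
        lo = detect_candidates(norm, DetectionParams(candidate_z=1.5,
                                                     min_event_area=0.01))
        hi = detect_candidates(norm, DetectionParams(candidate_z=2.5,
                                                     min_event_area=0.01))
        assert np.all((hi.labels > 0) <= (lo.labels > 0))
        assert (lo.labels > 0).sum() >= (hi.labels > 0).sum()

    def test_min_area_filter_removes_specks(self):
        dff = np.zeros((64, 64))
        dff[10, 10] = 5.0  # single-pixel spike: area 0.1 µm·ms
        norm = make_norm(dff)
        mask = detect_candidates(norm, DetectionParams(min_event_area=1.0))
        assert mask.n_events == 0


class TestScoreObject:
    def _uniform_object(self, z_value, n_px):
        dff = np.zeros((256, 512))
        tt = np.repeat(np.arange(n_px // 32 + 1), 32)[:n_px]
        xx = np.tile(np.arange(32), n_px // 32 + 1)[:n_px]
        dff[tt, xx] = z_value * 0.05
        return (tt, xx), make_norm(dff)

    def test_half_saturation_point_scores_exactly_half(self):
        params = DetectionParams()
        # z = z_half on every pixel, area = area_half (300 px x 0.1 µm·ms)
        n_px = int(params.score_area_half / (1.0 * 0.1))
        pix, norm = self._uniform_object(params.score_z_half, n_px)
        assert score_object(pix, norm, params) == pytest.approx(0.5, abs=1e-9)

    def test_score_increases_with_area_at_fixed_brightness(self):
        params = DetectionParams()
        pix_small, norm = self._uniform_object(10.0, 160)
        pix_large, norm2 = self._uniform_object(10.0, 320)
        assert (score_object(pix_large, norm2, params)
                > score_object(pix_small, norm, params))

    def test_score_saturates_below_one(self):
        params = DetectionParams()
        pix, norm = self._uniform_object(1000.0, 6400)
        s = score_object(pix, norm, params)
        assert 0.9 < s < 1.0

    def test_empty_object_rejected(self):
        _, norm = self._uniform_object(1.0, 32)
        with pytest.raises(ValueError):
            score_object((np.array([], int), np.array([], int)), norm,
                         DetectionParams())


class TestClassifyEvent:
    def _rect_object(self, width_um, duration_ms, dt=1.0, dx=0.1):
        n_x = int(width_um / dx)
        n_t = int(duration_ms / dt)
        dff = np.zeros((max(n_t + 20, 64), max(n_x + 20, 64)))
        dff[10:10 + n_t, 10:10 + n_x] = 1.0
        tt, xx = np.nonzero(dff > 0)
        return (tt, xx), make_norm(dff, dt=dt, dx=dx)

    @pytest.mark.parametrize(
        "width_um,duration_ms,expected",
        [
            (2.0, 25.0, "spark"),
            (2.5, 300.0, "long_spark"),
            (12.0, 40.0, "miniwave"),
            (40.0, 40.0, "wave"),
        ],
    )
    def test_classes_from_width_and_duration(self, width_um, duration_ms, expected):
        pix, norm = self._rect_object(width_um, duration_ms)
        assert classify_event(pix, norm, DetectionParams()) == expected


class TestSplitClusters:
    def _two_template_norm(self, sep_um, sigma=0.9, amp=1.0):
        dff = np.zeros((256, 256))
        tmpl, (pt, px) = spark_template(sigma, 4.0, 25.0, amp, 1.0, 0.1)
        x_first = 80
        insert(dff, tmpl, 60, x_first)
        insert(dff, tmpl, 60, x_first + int(sep_um / 0.1))
        norm = make_norm(dff)
        peaks = ((60 + pt, x_first + px),
                 (60 + pt, x_first + int(sep_um / 0.1) + px))
        return norm, peaks

    def test_single_spark_unchanged(self):
        dff = np.zeros((128, 128))
        tmpl, _ = spark_template(0.8, 4.0, 25.0, 1.0, 1.0, 0.1)
        insert(dff, tmpl, 30, 50)
        norm = make_norm(dff)
        params = DetectionParams()
        candidates = detect_candidates(norm, params)
        assert candidates.n_events == 1
        out = split_clusters(candidates, norm, params)
        np.testing.assert_array_equal(out.labels > 0, candidates.labels > 0)
        assert out.n_events == 1

    def test_two_templates_4um_apart_split_into_two(self):
        norm, peaks = self._two_template_norm(4.0)
        params = DetectionParams()
        candidates = detect_candidates(norm, params)
        assert candidates.n_events == 1  # merged into one component
        out = split_clusters(candidates, norm, params)
        assert out.n_events == 2
        labels_at_peaks = {out.labels[p] for p in peaks}
        assert len(labels_at_peaks) == 2 and 0 not in labels_at_peaks

    def test_split_children_partition_parent(self):
        norm, _ = self._two_template_norm(4.0)
        params = DetectionParams()
        candidates = detect_candidates(norm, params)
        out = split_clusters(candidates, norm, params)
        np.testing.assert_array_equal(out.labels > 0, candidates.labels > 0)

    def test_below_min_distance_stays_one_event(self):
        norm, _ = self._two_template_norm(0.5)
        params = DetectionParams()
        candidates = detect_candidates(norm, params)
        assert candidates.n_events == 1
        out = split_clusters(candidates, norm, params)
        assert out.n_events == 1

    def test_wave_scale_objects_never_split(self):
        # two bright cores on a contiguous 30 µm wide band: wave, kept whole
        dff = np.zeros((128, 512))
        dff[40:80, 60:360] = 0.8
        dff[50:70, 100:140] += 0.8
        dff[50:70, 280:320] += 0.8
        norm = make_norm(dff)
        params = DetectionParams()
        candidates = detect_candidates(norm, params)
        assert candidates.n_events == 1
        out = split_clusters(candidates, norm, params)
        assert out.n_events == 1


class TestDetectEvents:
    def test_constant_image_has_no_events(self):
        img = LineScanImage(np.full((256, 64), 500.0), time_step=1.92,
                            pixel_size=0.1, bit_depth=12)
        assert len(detect_events(img)) == 0

    def test_pure_noise_has_no_events(self, flat_image_factory):
        img = flat_image_factory(noise_sd=25.0, shape=(512, 256), seed=42)
        assert len(detect_events(img)) == 0

    def test_every_event_scores_above_threshold(self, synth_image):
        image, _, _ = synth_image
        params = DetectionParams()
        result = detect_events(image, params)
        assert len(result) > 0
        for ev in result:
            assert ev.score >= params.detect_threshold

    def test_final_mask_partitions_into_events(self, synth_image):
        image, _, _ = synth_image
        result = detect_events(image)
        total = 0
        for ev in result:
            assert np.all(result.mask.labels[ev.pixels] == ev.label)
            total += ev.area_px
        assert total == int((result.mask.labels > 0).sum())

    def test_less_sensitive_threshold_finds_no_more_events(self, synth_image):
        image, _, _ = synth_image
        n_sensitive = len(detect_events(image, DetectionParams(detect_threshold=0.45)))
        n_strict = len(detect_events(image, DetectionParams(detect_threshold=0.6)))
        assert n_strict <= n_sensitive

    def test_deterministic(self, synth_image):
        image, _, _ = synth_image
        a = detect_events(image)
        b = detect_events(image)
        np.testing.assert_array_equal(a.mask.labels, b.mask.labels)
        assert [(e.label, e.event_class, e.score) for e in a] == [
            (e.label, e.event_class, e.score) for e in b
        ]

    def test_high_amplitude_sparks_all_recovered(self):
        from sparkline import SynthParams, generate_image, match_events

        p = SynthParams(image_shape=(512, 256), n_sparks_range=(10, 12),
                        spark_amplitude_range=(0.8, 1.0),
                        n_couplets_range=(0, 0), n_repetitive_bands_range=(0, 0),
                        seed=21)
        image, mask, placed = generate_image(p)
        result = detect_events(image)
        res = match_events(mask, result.mask)
        assert res.fn == 0
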