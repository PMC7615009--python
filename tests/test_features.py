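"""Event measurement, summaries, latency maps and the refractoriness test."""

import numpy as np
import pytest

from sparkline import (
    LabelMask,
    LineScanImage,
    ReleaseEvent,
    detect_events,
    event_trace,
    fit_decay_tau,
    latency_map,
    measure_all,
    measure_event,
    refractoriness_test,
    spark_template,
    summarize,
)
from sparkline.preprocess import NormalizedImage
from sparkline.synth import RecordingGeometry, generate_event_layout


def make_norm(values, dt=1.92, dx=0.1):
    values = np.asarray(values, dtype=np.float64)
    source = LineScanImage(100.0 * values, time_step=dt, pixel_size=dx,
                           bit_depth=16)
    return NormalizedImage(values=values, baseline=np.full(values.shape, 100.0),
                           noise_sigma=0.05, source=source)


def rect_event(label, t0, t1, x0, x1, dt=1.92, dx=0.1, cls="spark"):
    tt, xx = np.mgrid[t0:t1, x0:x1]
    return ReleaseEvent(
        label=label, event_class=cls, pixels=(tt.ravel(), xx.ravel()),
        bbox=(t0 * dt, t1 * dt, x0 * dx, x1 * dx), bbox_px=(t0, t1, x0, x1),
        score=1.0, peak_time_ms=(t0 + t1) / 2 * dt,
        peak_position_um=(x0 + x1) / 2 * dx,
    )


class TestEventTrace:
    def test_isolated_event_is_plain_spatial_mean(self):
        values = np.full((64, 32), 1.0)
        values[20:30, 10:20] = 2.0
        norm = make_norm(values)
        ev = rect_event(1, 20, 30, 10, 20)
        mask = np.zeros((64, 32), dtype=np.int32)
        mask[20:30, 10:20] = 1
        lines, trace = event_trace(norm, ev, LabelMask(mask), pad_ms=0.0)
        np.testing.assert_allclose(trace, values[20:30, 10:20].mean(axis=1))

    def test_neighbor_pixels_are_excluded(self):
        # own pixels at 2.0, neighbour's at 10.0 in the same window
        values = np.full((64, 32), 1.0)
        values[20:30, 10:15] = 2.0
        values[20:30, 15:20] = 10.0
        norm = make_norm(values)
        ev = rect_event(1, 20, 30, 10, 20)
        mask = np.zeros((64, 32), dtype=np.int32)
        mask[20:30, 10:15] = 1
        mask[20:30, 15:20] = 2  # a different event
        _, trace = event_trace(norm, ev, LabelMask(mask), pad_ms=0.0)
        np.testing.assert_allclose(trace, 2.0)

    def test_fully_occupied_line_is_undefined(self):
        values = np.full((64, 32), 1.0)
        norm = make_norm(values)
        ev = rect_event(1, 20, 30, 10, 20)
        mask = np.zeros((64, 32), dtype=np.int32)
        mask[20:30, 10:20] = 1
        mask[25, 10:20] = 2  # line 25 fully owned by the neighbour
        _, trace = event_trace(norm, ev, LabelMask(mask), pad_ms=0.0)
        assert np.isnan(trace[5])
        assert np.isfinite(trace[4])


class TestMeasureEvent:
    def test_amplitude_is_peak_minus_one(self):
        values = np.full((128, 64), 1.0)
        values[40:60, 20:40] = 1.0
        values[50, 20:40] = 2.6
        norm = make_norm(values)
        ev = rect_event(1, 40, 60, 20, 40)
        mask = np.zeros((128, 64), dtype=np.int32)
        mask[40:60, 20:40] = 1
        f = measure_event(norm, ev, LabelMask(mask))
        assert f.amplitude == pytest.approx(1.6)
        assert f.peak_f_f0 == pytest.approx(2.6)
        assert f.amplitude == pytest.approx(f.peak_f_f0 - 1.0, abs=1e-9)

    def test_fwhm_of_gaussian_profile(self):
        # spatial Gaussian with sigma 1 µm above baseline: FWHM = 2.355 µm
        dx, dt = 0.05, 1.0
        x = (np.arange(256) - 128) * dx
        profile = np.exp(-0.5 * (x / 1.0) ** 2)
        values = np.full((64, 256), 1.0)
        values[20:40] += profile[None, :]
        norm = make_norm(values, dt=dt, dx=dx)
        mask = (values > 1.01).astype(np.int32)
        ev_pixels = np.nonzero(mask)
        ev = rect_event(1, 20, 40, int(ev_pixels[1].min()),
                        int(ev_pixels[1].max()) + 1, dt=dt, dx=dx)
        f = measure_event(norm, ev, LabelMask(mask))
        assert f.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 1.0, rel=0.02)

    def test_fdhm_from_known_crossings(self):
        # trace rises at 12 ms and falls at 40 ms (half level): FDHM 28 ms
        dt = 2.0
        values = np.full((64, 16), 1.0)
        t = np.arange(64) * dt
        # triangle peaking at 1.0 (t = 26 ms), half level 0.5 at 12 and 40 ms
        tri = np.clip(np.minimum((t + 2.0) / 28.0, (54.0 - t) / 28.0), 0, None)
        values += tri[:, None]
        norm = make_norm(values, dt=dt)
        mask = (values > 1.0).astype(np.int32)
        tt = np.nonzero(mask.any(axis=1))[0]
        ev = rect_event(1, int(tt.min()), int(tt.max()) + 1, 0, 16, dt=dt)
        f = measure_event(norm, ev, LabelMask(mask))
        # half max 0.5 crossed at t = 12 and t = 40
        assert f.fdhm == pytest.approx(28.0, abs=dt)

    def test_half_widths_never_exceed_full_extents(self, synth_image):
        image, _, _ = synth_image
        result = detect_events(image)
        for m in measure_all(result):
            assert m.features.fwhm <= m.features.full_width + 1e-9
            assert m.features.fdhm <= m.features.full_duration + 1e-9


class TestFitDecayTau:
    @pytest.mark.parametrize("tau", [10.0, 20.0, 40.0, 80.0])
    def test_noiseless_exponential_recovered(self, tau):
        dt = 1.92
        t = np.arange(0, 6 * tau, dt)
        trace = 1.0 + 1.5 * np.exp(-t / tau)
        fitted = fit_decay_tau(trace, 0, dt)
        assert fitted == pytest.approx(tau, rel=0.02)

    def test_tau_30ms_within_half_ms(self):
        dt = 1.92
        t = np.arange(0, 200, dt)
        trace = 1.0 + 1.0 * np.exp(-t / 30.0)
        fitted = fit_decay_tau(trace, 0, dt)
        assert fitted == pytest.approx(30.0, abs=0.5)

    def test_constant_post_peak_trace_undefined(self):
        trace = np.full(50, 2.0)
        assert fit_decay_tau(trace, 0, 1.92) is None

    def test_too_few_samples_undefined(self):
        assert fit_decay_tau(np.array([2.0, 1.5, 1.2]), 0, 1.92) is None


class TestSummarize:
    @pytest.mark.parametrize(
        "n_sparks,length_um,duration_s,expected",
        [(10, 50.0, 5.0, 4.0), (0, 50.0, 5.0, 0.0), (1, 100.0, 1.0, 1.0)],
    )
    def test_spark_frequency_formula(self, n_sparks, length_um, duration_s,
                                     expected):
        geom = RecordingGeometry(
            n_lines=int(duration_s * 1000), n_pixels=int(length_um / 0.1),
            time_step=1.0, pixel_size=0.1,
        )

        class M:
            def __init__(self, i):
                self.event = rect_event(i, 0, 2, 0, 2, cls="spark")

            def row(self):
                from sparkline.io_formats import EVENT_COLUMNS

                r = {c: np.nan for c in EVENT_COLUMNS}
                r["class"] = "spark"
                return r

        summary = summarize([M(i) for i in range(n_sparks)], geom)
        assert summary.spark_frequency == pytest.approx(expected, abs=1e-9)

    def test_class_counts_sum_to_total(self, synth_image):
        image, _, _ = synth_image
        result = detect_events(image)
        measured = measure_all(result)
        summary = summarize(measured, image)
        assert summary.n_events == len(measured)

    def test_frequency_counts_only_spark_class(self):
        geom = RecordingGeometry(5000, 500, 1.0, 0.1)

        class M:
            def __init__(self, cls, i):
                self.event = rect_event(i, 0, 2, 0, 2, cls=cls)

            def row(self):
                from sparkline.io_formats import EVENT_COLUMNS

                r = {c: np.nan for c in EVENT_COLUMNS}
                r["class"] = self.event.event_class
                return r

        measured = [M("spark", 1), M("wave", 2), M("long_spark", 3)]
        s = summarize(measured, geom)
        assert s.spark_frequency == pytest.approx(100 * 1 / (50.0 * 5.0))
        merged = summarize(measured, geom, merge_long_sparks=True)
        assert merged.spark_frequency == pytest.approx(100 * 2 / (50.0 * 5.0))


class TestLatencyMap:
    def _geom(self):
        return RecordingGeometry(n_lines=400, n_pixels=64, time_step=1.0,
                                 pixel_size=0.1)

    def test_time_since_event_end(self):
        geom = self._geom()
        ev = rect_event(1, 50, 100, 20, 30, dt=1.0, dx=0.1)  # ends at 100 ms
        lat, valid = latency_map([ev], geom, spatial_radius=0.0)
        assert lat[250, 25] == pytest.approx(150.0)
        assert valid[250, 25]

    def test_pixels_before_any_event_get_own_time(self):
        geom = self._geom()
        ev = rect_event(1, 50, 100, 20, 30, dt=1.0, dx=0.1)
        lat, valid = latency_map([ev], geom, spatial_radius=0.0)
        assert not valid[20, 25]
        assert lat[20, 25] == pytest.approx(20.0)

    def test_zero_inside_events_and_non_negative(self):
        geom = self._geom()
        ev = rect_event(1, 50, 100, 20, 30, dt=1.0, dx=0.1)
        lat, valid = latency_map([ev], geom, spatial_radius=0.0)
        assert np.all(lat >= 0)
        assert np.all(lat[60:99, 22:28] == 0)


class TestRefractorinessTest:
    def test_suppressed_generator_is_significant(self):
        events, geom = generate_event_layout(n_waves=20, suppress_ms=150.0,
                                             seed=7)
        post, ctrl, p = refractoriness_test(events, geom, seed=7)
        assert post < ctrl
        assert p < 0.05

    def test_null_generator_usually_non_significant(self):
        nonsig = 0
        for seed in range(100):
            events, geom = generate_event_layout(n_waves=20, suppress_ms=0.0,
                                                 seed=seed)
            _, _, p = refractoriness_test(events, geom, seed=seed)
            nonsig += p >= 0.05
        assert nonsig >= 90

    def test_zero_waves_is_an_error(self):
        geom = RecordingGeometry(1000, 100, 1.0, 0.1)
        sparks = [rect_event(1, 10, 20, 10, 20, cls="spark")]
        with pytest.raises(ValueError):
            refractoriness_test(sparks, geom)

    def test_deterministic_given_seed(self):
        events, geom = generate_event_layout(n_waves=10, suppress_ms=0.0, seed=3)
        a = refractoriness_test(events, geom, seed=5)
        b = refractoriness_test(events, geom, seed=5)
        assert a == b
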