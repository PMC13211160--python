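"""Gravity detrend, Hilbert envelope, run detection and event criteria."""

import dataclasses

import numpy as np
import pytest

from drivehull import (
    DetectionConfig,
    DriveSegment,
    SegmentMismatchError,
    SeriesTooShortError,
    apply_event_criteria,
    compute_envelope,
    detect_active_periods,
    detrend_gravity,
)
from drivehull.drive_detection import moving_average


def fft_analytic_modulus(signal):
    """Independent frequency-domain analytic-signal envelope (test oracle)."""
    n = len(signal)
    spectrum = np.fft.fft(signal)
    weights = np.zeros(n)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[n // 2] = 1.0
        weights[1 : n // 2] = 2.0
    else:
        weights[1 : (n + 1) // 2] = 2.0
    return np.abs(np.fft.ifft(spectrum * weights))


RAW_ENVELOPE = DetectionConfig(envelope_smooth_window_s=1e-6)


class TestDetrendGravity:
    @pytest.mark.parametrize(
        "offset", [(0.0, 0.0, -1.0), (0.01, -0.02, -0.99)]
    )
    def test_constant_series_goes_to_zero(self, make_series, offset):
        series = make_series(np.tile(offset, (100, 1)))
        detrended, offsets = detrend_gravity(series)
        np.testing.assert_allclose(detrended.xyz, 0.0, atol=1e-12)
        np.testing.assert_allclose(offsets, offset)

    def test_bursty_signal_has_zero_median_after(self, make_series, rng):
        xyz = rng.normal(0, 0.05, (2000, 3)) + np.array([0.0, 0.0, -1.0])
        detrended, _ = detrend_gravity(make_series(xyz))
        np.testing.assert_allclose(np.median(detrended.xyz, axis=0), 0.0, atol=1e-12)


class TestComputeEnvelope:
    def test_pure_tone_recovers_amplitude(self, make_series):
        t = np.arange(600) / 10.0
        x = 0.2 * np.sin(2 * np.pi * 1.0 * t)
        series = make_series(np.column_stack([x, 0 * x, 0 * x]))
        env = compute_envelope(series, "longitudinal", DetectionConfig())
        interior = env.value[100:-100]
        assert np.all(np.abs(interior - 0.2) < 0.05 * 0.2)

    def test_zero_signal_zero_envelope(self, make_series):
        series = make_series(np.zeros((200, 3)))
        env = compute_envelope(series, "longitudinal")
        np.testing.assert_allclose(env.value, 0.0, atol=1e-15)

    def test_am_tone_matches_fft_oracle(self, make_series):
        t = np.arange(1200) / 10.0
        x = (0.1 + 0.05 * np.sin(2 * np.pi * 0.05 * t)) * np.sin(2 * np.pi * 1.5 * t)
        series = make_series(np.column_stack([x, 0 * x, 0 * x]))
        env = compute_envelope(series, "longitudinal", RAW_ENVELOPE)
        oracle = fft_analytic_modulus(x)
        np.testing.assert_allclose(env.value[50:-50], oracle[50:-50], atol=1e-6)

    def test_envelope_nonnegative_everywhere(self, make_series, rng):
        series = make_series(rng.normal(0, 0.1, (500, 3)))
        env = compute_envelope(series, "magnitude")
        assert np.all(env.value >= 0)

    def test_too_short_series_raises(self, make_series):
        series = make_series(np.zeros((10, 3)))  # 1 s < 5 s window
        with pytest.raises(SeriesTooShortError):
            compute_envelope(series, "longitudinal", DetectionConfig())

    def test_moving_average_preserves_constants(self):
        np.testing.assert_allclose(moving_average(np.full(100, 3.5), 11), 3.5)


def _env(values, rate=10.0):
    from drivehull import EnvelopeSeries

    return EnvelopeSeries(
        t=np.arange(len(values)) / rate, value=np.asarray(values, float),
        source_axis="longitudinal",
    )


class TestDetectActivePeriods:
    def test_all_zero_envelope_gives_no_segments(self):
        assert detect_active_periods(_env(np.zeros(5000))) == []

    def test_rectangular_burst_recovered_within_window(self):
        cfg = DetectionConfig()
        values = np.zeros(6000)
        values[2000:3200] = 0.1  # 120 s burst at 10 Hz
        segs = detect_active_periods(_env(values), cfg)
        assert len(segs) == 1
        assert abs(segs[0].start_s - 200.0) <= cfg.envelope_smooth_window_s
        assert abs(segs[0].end_s - 320.0) <= cfg.envelope_smooth_window_s

    def test_bursts_closer_than_merge_gap_are_merged(self):
        values = np.zeros(6000)
        values[1000:1900] = 0.1  # 90 s
        values[2100:3000] = 0.1  # 20 s gap < merge_gap 30 s
        segs = detect_active_periods(_env(values))
        assert len(segs) == 1

    def test_bursts_beyond_merge_gap_stay_separate(self):
        values = np.zeros(8000)
        values[1000:1900] = 0.1
        values[2400:3300] = 0.1  # 50 s gap > 30 s
        segs = detect_active_periods(_env(values))
        assert len(segs) == 2

    def test_short_runs_discarded(self):
        values = np.zeros(6000)
        values[1000:1300] = 0.1  # 30 s < min duration 60 s
        assert detect_active_periods(_env(values)) == []

    def test_segments_disjoint_and_sorted(self, rng):
        values = (rng.random(20000) < 0.3) * 0.1
        segs = detect_active_periods(_env(values))
        for a, b in zip(segs, segs[1:]):
            assert a.end_s < b.start_s


def _segment(start, end):
    return DriveSegment("P1", 0, start, end)


class TestExtractWristSegments:
    def test_retained_segment_sample_count(self, make_series, rng):
        from drivehull import extract_wrist_segments

        wrist = make_series(rng.normal(0, 0.1, (2000, 3)), device_role="wrist")
        seg = DriveSegment("P1", 0, 10.0, 130.0, retained=True)
        subs, kept = extract_wrist_segments(wrist, [seg])
        assert len(subs) == 1 and kept == [seg]
        assert abs(subs[0].n_samples - 1200) <= 1

    def test_non_retained_segments_skipped(self, make_series, rng):
        from drivehull import extract_wrist_segments

        wrist = make_series(rng.normal(0, 0.1, (2000, 3)), device_role="wrist")
        subs, kept = extract_wrist_segments(
            wrist, [DriveSegment("P1", 0, 10.0, 130.0, retained=False)]
        )
        assert subs == [] and kept == []

    def test_recording_ending_mid_segment_is_cropped(self, make_series, rng):
        from drivehull import extract_wrist_segments

        wrist = make_series(rng.normal(0, 0.1, (1000, 3)), device_role="wrist")
        seg = DriveSegment("P1", 0, 50.0, 200.0, retained=True)  # ends at 99.9 s
        subs, _ = extract_wrist_segments(wrist, [seg])
        assert subs[0].t[-1] == pytest.approx(99.9)


class TestApplyEventCriteria:
    def _series_with_pulse(self, make_series, axis, peak, n=1500):
        xyz = np.zeros((n, 3))
        xyz[700:730, axis] = peak * np.sin(np.pi * np.arange(30) / 30)
        return make_series(xyz)

    def test_longitudinal_accel_at_0p40_is_retained(self, make_series):
        series = self._series_with_pulse(make_series, 0, 0.40)
        (seg,) = apply_event_criteria(series, [_segment(10.0, 140.0)])
        assert seg.retained
        assert seg.peak_long_accel_g == pytest.approx(0.40, rel=0.01)

    def test_all_peaks_below_thresholds_not_retained(self, make_series):
        series = self._series_with_pulse(make_series, 0, 0.30)
        (seg,) = apply_event_criteria(series, [_segment(10.0, 140.0)])
        assert not seg.retained

    def test_scripted_braking_event_retained_with_peak(self, make_series):
        series = self._series_with_pulse(make_series, 0, -0.5)
        (seg,) = apply_event_criteria(series, [_segment(10.0, 140.0)])
        assert seg.retained
        assert seg.peak_long_decel_g == pytest.approx(0.5, rel=0.01)
        assert seg.peak_long_accel_g == pytest.approx(0.0, abs=1e-9)

    def test_lateral_event_retained(self, make_series):
        series = self._series_with_pulse(make_series, 1, -0.55)
        (seg,) = apply_event_criteria(series, [_segment(10.0, 140.0)])
        assert seg.retained
        assert seg.peak_lateral_abs_g == pytest.approx(0.55, rel=0.01)

    def test_boundaries_never_modified(self, make_series, rng):
        series = make_series(rng.normal(0, 0.2, (1500, 3)))
        segs = [_segment(10.0, 80.0), _segment(90.0, 149.0)]
        out = apply_event_criteria(series, segs)
        assert [(s.start_s, s.end_s) for s in out] == [
            (s.start_s, s.end_s) for s in segs
        ]

    def test_segment_outside_series_raises(self, make_series):
        series = make_series(np.zeros((100, 3)))
        with pytest.raises(SegmentMismatchError):
            apply_event_criteria(series, [_segment(50.0, 500.0)])

    def test_retain_all_active_keeps_subthreshold_segments(self, make_series):
        series = self._series_with_pulse(make_series, 0, 0.1)
        cfg = DetectionConfig(retain_all_active=True)
        (seg,) = apply_event_criteria(series, [_segment(10.0, 140.0)], cfg)
        assert seg.retained

    def test_raising_thresholds_never_increases_retained(self, make_series, rng):
        xyz = rng.normal(0, 0.25, (6000, 3))
        series = make_series(xyz)
        segs = [_segment(60.0 * i + 5, 60.0 * i + 55) for i in range(9)]
        counts = []
        for bump in (0.0, 0.1, 0.2, 0.4):
            cfg = DetectionConfig(
                long_accel_threshold_g=0.35 + bump,
                long_decel_threshold_g=0.45 + bump,
                lateral_threshold_g=0.5 + bump,
            )
            out = apply_event_criteria(series, segs, cfg)
            counts.append(sum(s.retained for s in out))
        assert counts == sorted(counts, reverse=True)
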