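"""Preprocessing-step tests: background subtraction, shared-trend removal,
division imputation, flooring, normalization and running-average detrending."""

import numpy as np
import pytest

from circanuc.preprocess import (
    detrend_running_average,
    floor_min_to_zero,
    impute_division_outliers,
    normalize_by_mean,
    remove_shared_linear_trend,
    run_pipeline,
    subtract_background,
)
from circanuc.synth import CellTrace, FrameSet


def make_trace(intensity, background=None, divisions=(), t=None):
    intensity = np.asarray(intensity, dtype=float)
    t = np.arange(intensity.size, dtype=float) if t is None else t
    return CellTrace("c0", "f0", "CH", t, intensity,
                     background=None if background is None else np.asarray(background, float),
                     division_indices=np.asarray(divisions, dtype=int))


class TestSubtractBackground:
    def test_constant_cancels(self):
        tr = make_trace([100.0] * 5, [100.0] * 5)
        assert np.all(subtract_background(tr, "mean").intensity == 0.0)

    def test_zero_background_is_identity(self):
        tr = make_trace([3.0, 4.0, 5.0], [0.0, 0.0, 0.0])
        out = subtract_background(tr, "per-timepoint")
        assert np.array_equal(out.intensity, tr.intensity)

    def test_per_timepoint_arithmetic(self):
        tr = make_trace([110, 120, 130], [10, 20, 30])
        assert np.array_equal(subtract_background(tr, "per-timepoint").intensity, [100, 100, 100])

    def test_missing_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            subtract_background(make_trace([1, 2, 3]))

    def test_input_unmodified(self):
        tr = make_trace([110, 120, 130], [10, 20, 30])
        subtract_background(tr)
        assert np.array_equal(tr.intensity, [110, 120, 130])


class TestSharedTrend:
    def test_zero_slope_unchanged(self, rng):
        traces = [make_trace(rng.normal(100, 1, 48)) for _ in range(4)]
        out = remove_shared_linear_trend(FrameSet("f0", traces))
        for before, after in zip(traces, out.traces):
            assert np.allclose(before.intensity, after.intensity, atol=1.0)

    def test_injected_slope_recovered_within_1pct(self, rng):
        t = np.arange(72.0)
        slope = 0.5
        levels = [50.0, 120.0, 300.0]
        traces = [make_trace(level + slope * t + rng.normal(0, 0.01, 72), t=t)
                  for level in levels]
        out = remove_shared_linear_trend(FrameSet("f0", traces))
        for level, tr in zip(levels, out.traces):
            resid_slope = np.polyfit(t, tr.intensity, 1)[0]
            assert abs(resid_slope) < 0.01 * slope
            assert np.mean(tr.intensity) == pytest.approx(level + slope * np.mean(t), rel=1e-3)

    def test_commutes_with_common_constant(self, rng):
        t = np.arange(48.0)
        base = [make_trace(10 + 0.3 * t + rng.normal(0, 0.1, 48), t=t) for _ in range(3)]
        shifted = [tr.replace(intensity=tr.intensity + 50.0) for tr in base]
        out_base = remove_shared_linear_trend(FrameSet("f0", base))
        out_shift = remove_shared_linear_trend(FrameSet("f0", shifted))
        for a, b in zip(out_base.traces, out_shift.traces):
            assert np.allclose(b.intensity - a.intensity, 50.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            remove_shared_linear_trend(FrameSet("f0", [make_trace([1.0, 2.0])]))


class TestImputeDivisions:
    def test_single_flag(self):
        out = impute_division_outliers(make_trace([1, 9, 3], divisions=[1]))
        assert np.array_equal(out.intensity, [1, 2, 3])

    def test_no_flags_identity(self):
        tr = make_trace([1, 9, 3])
        assert np.array_equal(impute_division_outliers(tr).intensity, tr.intensity)

    def test_adjacent_flags_share_neighbors(self):
        out = impute_division_outliers(make_trace([1, 9, 9, 3], divisions=[1, 2]))
        assert np.array_equal(out.intensity, [1, 2, 2, 3])

    def test_boundary_uses_single_neighbor(self):
        out = impute_division_outliers(make_trace([9, 2, 3], divisions=[0]))
        assert np.array_equal(out.intensity, [2, 2, 3])

    def test_all_flagged_rejected(self):
        with pytest.raises(ValueError, match="flagged"):
            impute_division_outliers(make_trace([1, 2], divisions=[0, 1]))


class TestFloorAndNormalize:
    def test_floor_examples(self):
        assert np.array_equal(floor_min_to_zero(make_trace([3, 5, 4])).intensity, [0, 2, 1])
        zeroed = make_trace([0, 2, 1])
        assert np.array_equal(floor_min_to_zero(zeroed).intensity, zeroed.intensity)

    def test_floor_is_idempotent(self, rng):
        tr = make_trace(rng.normal(10, 3, 30))
        once = floor_min_to_zero(tr)
        twice = floor_min_to_zero(once)
        assert once.intensity.min() == 0.0
        assert np.array_equal(once.intensity, twice.intensity)

    def test_normalize_examples(self, rng):
        assert np.allclose(normalize_by_mean(make_trace([2, 4])).intensity, [2 / 3, 4 / 3])
        tr = make_trace(rng.uniform(1, 10, 40))
        assert np.mean(normalize_by_mean(tr).intensity) == pytest.approx(1.0)
        scaled = tr.replace(intensity=tr.intensity * 7.5)
        assert np.allclose(normalize_by_mean(scaled).intensity, normalize_by_mean(tr).intensity)

    def test_normalize_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError, match="mean"):
            normalize_by_mean(make_trace([-1.0, 1.0, 0.0]))


class TestRunningAverage:
    def test_constant_maps_to_one(self):
        out = detrend_running_average(np.full(96, 7.3), dt=1.0)
        assert np.allclose(out, 1.0)

    def test_stationary_cosine_nearly_unchanged(self):
        t = np.arange(96.0)
        y = 1.0 + 0.1 * np.cos(2 * np.pi * t / 24.0)
        out = detrend_running_average(y, dt=1.0)
        core = slice(12, 84)
        assert np.allclose(out[core], y[core], atol=0.02)

    def test_decaying_baseline_amplitude_stationary(self):
        t = np.arange(96.0)
        y = np.exp(-t / 60.0) * (1.0 + 0.2 * np.cos(2 * np.pi * t / 24.0))
        out = detrend_running_average(y, dt=1.0)
        day_amp = [np.ptp(out[12 + 24 * d:36 + 24 * d]) for d in range(3)]
        assert max(day_amp) / min(day_amp) < 1.1

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            detrend_running_average(np.array([1.0, -1.0] + [1.0] * 60), dt=1.0)


def test_pipeline_preserves_time_grid(dki_frames):
    processed = run_pipeline(dki_frames)
    for before, after in zip(dki_frames, processed):
        if before.traces:
            for tr_b, tr_a in zip(before.traces, after.traces):
                assert np.array_equal(tr_b.time, tr_a.time)


def test_pipeline_output_normalized(dki_frames):
    processed = run_pipeline(dki_frames)
    for frame in processed:
        for tr in frame.traces:
            assert np.mean(tr.intensity) == pytest.approx(1.0)
            if tr.channel == "PER2":
                assert tr.intensity.min() >= 0.0
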