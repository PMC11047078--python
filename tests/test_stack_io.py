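import json

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

from scnwave import stack_io, synth
from scnwave.stack_io import FrameStack, TemperatureSchedule


def _stack_from_trace(trace, shape=(6, 6), dt=0.5):
    frames = np.tile(np.asarray(trace)[:, None, None], (1, *shape))
    return FrameStack(frames=frames, frame_interval_h=dt)


class TestFrameStack:
    def test_rejects_wrong_ndim(self):
        with pytest.raises(ValueError):
            FrameStack(frames=np.zeros((4, 4)), frame_interval_h=0.5)

    def test_rejects_single_frame(self):
        with pytest.raises(ValueError):
            FrameStack(frames=np.zeros((1, 4, 4)), frame_interval_h=0.5)

    def test_times_are_uniform(self):
        st_ = FrameStack(frames=np.zeros((5, 2, 2)), frame_interval_h=0.5, t0_h=1.0)
        assert np.allclose(st_.times_h, [1.0, 1.5, 2.0, 2.5, 3.0])


class TestTemperatureSchedule:
    def test_rejects_gap(self):
        with pytest.raises(ValueError):
            TemperatureSchedule([(0, 24, 37.0), (30, 48, 32.0)])

    def test_rejects_nonzero_start(self):
        with pytest.raises(ValueError):
            TemperatureSchedule([(5, 24, 37.0)])

    def test_epoch_lookup(self):
        sched = TemperatureSchedule([(0, 24, 37.0), (24, 48, 32.0)])
        assert sched.epoch_index_at(0.0) == 0
        assert sched.epoch_index_at(23.9) == 0
        assert sched.epoch_index_at(24.0) == 1
        assert sched.epoch_index_at(48.0) == 1


class TestMovingAverageDetrend:
    def test_constant_stack_maps_to_zero(self):
        st_ = _stack_from_trace(np.full(120, 7.0))
        out = stack_io.moving_average_detrend(st_, 24.5)
        assert np.allclose(out.frames, 0.0, atol=1e-12)

    def test_removes_linear_trend_under_cosine(self):
        # pure 24 h cosine plus a linear trend; the residual trend slope of
        # the detrended trace must be <1% of the input slope (least-squares
        # slope as the oracle)
        t = np.arange(240) * 0.5
        slope_in = 2.0
        trace = np.cos(2 * np.pi * t / 24.0) + slope_in * t
        out = stack_io.moving_average_detrend(_stack_from_trace(trace), 24.5)
        resid = out.frames[:, 0, 0]
        # interior only: the shrinking edge window keeps edge means local
        interior = slice(25, -25)
        slope_out = np.polyfit(t[interior], resid[interior], 1)[0]
        assert abs(slope_out) < 0.01 * slope_in

    def test_window_longer_than_recording_rejected(self):
        st_ = _stack_from_trace(np.zeros(48))  # 24 h recording
        with pytest.raises(ValueError):
            stack_io.moving_average_detrend(st_, 25.0)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(0)
        trace = rng.normal(size=120)
        base = stack_io.moving_average_detrend(_stack_from_trace(trace), 24.5)
        scaled = stack_io.moving_average_detrend(_stack_from_trace(a * trace + b), 24.5)
        assert np.allclose(scaled.frames, a * base.frames, atol=1e-8)


class TestCubicDetrend:
    def test_exact_cubic_maps_to_zero(self):
        t = np.linspace(0, 10, 50)
        trace = 1.0 - 2.0 * t + 0.3 * t**2 - 0.01 * t**3
        assert np.allclose(stack_io.cubic_detrend(trace), 0.0, atol=1e-9)

    def test_residual_mean_zero(self):
        rng = np.random.default_rng(1)
        out = stack_io.cubic_detrend(rng.normal(size=100))
        assert abs(out.mean()) < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            stack_io.cubic_detrend(np.arange(4.0))


class TestTileRois:
    def test_full_mask_tile_count(self):
        # brute-force: floor(64/3)^2 complete 3x3 tiles on a 64x64 grid
        st_ = FrameStack(frames=np.ones((4, 64, 64)), frame_interval_h=0.5)
        rois = stack_io.tile_rois(st_, np.ones((64, 64), bool))
        assert rois.n_roi == (64 // 3) ** 2 == 441

    def test_single_tile_mean_is_nine_pixel_mean(self):
        frames = np.arange(2 * 9 * 9, dtype=float).reshape(2, 9, 9)
        mask = np.zeros((9, 9), bool)
        mask[3:6, 3:6] = True
        rois = stack_io.tile_rois(FrameStack(frames=frames, frame_interval_h=1.0), mask)
        assert rois.n_roi == 1
        assert np.allclose(rois.series[0], frames[:, 3:6, 3:6].mean(axis=(1, 2)))
        assert tuple(rois.roi_centers[0]) == (4, 4)

    def test_empty_mask_rejected(self):
        st_ = FrameStack(frames=np.ones((3, 9, 9)), frame_interval_h=1.0)
        with pytest.raises(ValueError):
            stack_io.tile_rois(st_, np.zeros((9, 9), bool))

    def test_partial_tiles_dropped_by_retention(self):
        mask = np.zeros((9, 9), bool)
        mask[0:3, 0:3] = True
        mask[3, 3] = True  # 1/9 of the next tile
        st_ = FrameStack(frames=np.ones((3, 9, 9)), frame_interval_h=1.0)
        rois = stack_io.tile_rois(st_, mask, retention_frac=0.5)
        assert rois.n_roi == 1

    def test_retained_rois_are_disjoint_lattice_tiles(self, banded_rois):
        rois, _, _ = banded_rois
        centers = {tuple(c) for c in rois.roi_centers}
        assert len(centers) == rois.n_roi
        assert all((r - 1) % 3 == 0 and (c - 1) % 3 == 0 for r, c in centers)


class TestExtractMeanTrace:
    def test_uniform_frames(self):
        frames = np.stack([np.full((5, 5), v) for v in (1.0, 2.0, 3.0)])
        st_ = FrameStack(frames=frames, frame_interval_h=1.0)
        trace = stack_io.extract_mean_trace(st_, np.ones((5, 5), bool))
        assert np.allclose(trace, [1, 2, 3])

    def test_single_pixel_mask(self):
        rng = np.random.default_rng(0)
        frames = rng.random((4, 5, 5))
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        st_ = FrameStack(frames=frames, frame_interval_h=1.0)
        assert np.allclose(stack_io.extract_mean_trace(st_, mask), frames[:, 2, 3])

    def test_empty_mask_rejected(self):
        st_ = FrameStack(frames=np.ones((3, 5, 5)), frame_interval_h=1.0)
        with pytest.raises(ValueError):
            stack_io.extract_mean_trace(st_, np.zeros((5, 5), bool))


class TestNormalizeSeries:
    def test_minmax_zero_to_hundred(self):
        out = stack_io.normalize_series(np.array([0.0, 10.0]), mode="minmax")
        assert np.allclose(out.values, [0.0, 100.0])

    def test_zscore_moments(self):
        rng = np.random.default_rng(2)
        out = stack_io.normalize_series(rng.random((5, 100)))
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(out.values.std(axis=1), 1.0, atol=1e-9)

    def test_constant_row_flagged_not_raised(self):
        series = np.vstack([np.ones(10), np.arange(10.0)])
        out = stack_io.normalize_series(series)
        assert out.degenerate.tolist() == [True, False]
        assert np.allclose(out.values[0], 0.0)


class TestReadWriteRoundTrip:
    def test_write_then_read_within_quantization(self, tmp_path, noise_free_stack):
        stack, gt, params = noise_free_stack
        path = tmp_path / "stack.tif"
        synth.write_stack(stack, path, schedule=params.temperature_schedule, seed=1)
        loaded, sched = stack_io.read_stack(path)
        assert loaded.n_frames == stack.n_frames
        assert loaded.frame_interval_h == stack.frame_interval_h
        assert np.max(np.abs(loaded.frames - stack.frames)) <= 0.5  # uint16 rounding
        assert sched is not None and sched.total_span_h == params.duration_h

    def test_missing_interval_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "x.tif", np.zeros((3, 4, 4), np.uint16))
        (tmp_path / "x.json").write_text(json.dumps({"channel": "a"}))
        with pytest.raises(ValueError, match="frame_interval_h"):
            stack_io.read_stack(tmp_path / "x.tif")

    def test_sidecar_without_epochs_defers_failure(self, tmp_path):
        tifffile.imwrite(tmp_path / "x.tif", np.zeros((3, 4, 4), np.uint16))
        (tmp_path / "x.json").write_text(json.dumps({"frame_interval_h": 0.5}))
        stack, sched = stack_io.read_stack(tmp_path / "x.tif")
        assert sched is None  # schedule-dependent ops refuse later

    def test_heterogeneous_page_shapes_rejected(self, tmp_path):
        with tifffile.TiffWriter(tmp_path / "bad.tif") as tw:
            tw.write(np.zeros((4, 4), np.uint16))
            tw.write(np.zeros((5, 5), np.uint16))
        (tmp_path / "bad.json").write_text(json.dumps({"frame_interval_h": 0.5}))
        with pytest.raises(ValueError, match="page"):
            stack_io.read_stack(tmp_path / "bad.tif")

    def test_overflow_rejected_naming_frame(self, tmp_path):
        frames = np.ones((3, 4, 4))
        frames[1] = 1e6
        st_ = FrameStack(frames=frames, frame_interval_h=0.5)
        with pytest.raises(ValueError, match="frame 1"):
            synth.write_stack(st_, tmp_path / "over.tif")
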