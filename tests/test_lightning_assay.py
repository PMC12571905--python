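"""Lightning assay tests: thresholding, area counting, HES calling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hesquant import (GeneratorConfig, ImageStack, LightningParams,
                      analyze_roi, crop_window, detect_hes,
                      measure_area_series, normalize_series, render_dataset,
                      run_lightning, select_threshold)
from hesquant.io import CellROI
from hesquant.lightning_assay import NormalizedTrace
from conftest import make_shrink_event

PARAMS = LightningParams()


def _stack(data: np.ndarray, px: float = 0.2125,
           dt: float = 0.5) -> ImageStack:
    return ImageStack(data=np.asarray(data, dtype=float), pixel_size=px,
                      frame_interval=dt, channel="phase")


def _roi(cy: float, cx: float, cell_id: int = 1,
         frame_last: int = 0) -> CellROI:
    return CellROI(cell_id=cell_id, frame_first=0, frame_last=frame_last,
                   x_min=0, y_min=0, x_max=1, y_max=1,
                   centroid_x=cx, centroid_y=cy)


class TestCropWindow:
    def test_centred_crop_has_requested_size(self):
        stack = _stack(np.zeros((1, 1024, 1024)))
        crop = crop_window(stack, _roi(512, 512), PARAMS)
        assert crop.shape_yx == (400, 400)
        assert (crop.y_offset, crop.x_offset) == (312, 312)

    def test_border_centroid_clips_with_recorded_offset(self):
        stack = _stack(np.zeros((1, 1024, 1024)))
        crop = crop_window(stack, _roi(10, 10), PARAMS)
        assert crop.shape_yx == (400, 400)
        assert (crop.y_offset, crop.x_offset) == (0, 0)

    def test_reembedding_recovers_original_pixels(self):
        rng = np.random.default_rng(0)
        stack = _stack(rng.random((3, 600, 600)))
        crop = crop_window(stack, _roi(77, 501), PARAMS)
        rebuilt = np.zeros_like(stack.data)
        h, w = crop.shape_yx
        rebuilt[:, crop.y_offset:crop.y_offset + h,
                crop.x_offset:crop.x_offset + w] = crop.stack.data
        region = rebuilt != 0
        assert np.array_equal(rebuilt[region], stack.data[region])
        assert region.sum() == 3 * 400 * 400

    def test_centroid_outside_image_rejected(self):
        stack = _stack(np.zeros((1, 100, 100)))
        with pytest.raises(ValueError, match="outside"):
            crop_window(stack, _roi(500, 500), PARAMS)


class TestSelectThreshold:
    def test_two_value_histogram_matches_sorted_percentile_oracle(self):
        values = np.concatenate([np.zeros(9600), np.full(400, 100.0)])
        rng = np.random.default_rng(1)
        rng.shuffle(values)
        stack = _stack(values.reshape(10, 20, 50))
        thr = select_threshold(stack, slice(0, 10), PARAMS)
        # oracle: exhaustive sort + linear interpolation at rank q(n-1)
        s = np.sort(values)
        rank = 0.98 * (len(s) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        expected = s[lo] + (rank - lo) * (s[hi] - s[lo])
        assert thr == expected == 100.0

    def test_constant_baseline_is_degenerate_under_strict_greater(self):
        stack = _stack(np.full((12, 8, 8), 10.0))
        thr = select_threshold(stack, slice(0, 10), PARAMS)
        assert thr == 10.0
        area = measure_area_series(stack, thr, 1.0)
        assert np.all(area == 0.0)
        with pytest.raises(ValueError, match="baseline"):
            normalize_series(area, slice(0, 10), PARAMS)

    def test_identical_baselines_give_identical_thresholds(self):
        rng = np.random.default_rng(2)
        frames = rng.random((10, 16, 16))
        a = select_threshold(_stack(frames), slice(0, 10), PARAMS)
        b = select_threshold(_stack(frames.copy()), slice(0, 10), PARAMS)
        assert a == b


class TestMeasureArea:
    def test_known_pixel_count_matches_exhaustive_oracle(self):
        data = np.zeros((1, 64, 64))
        rng = np.random.default_rng(3)
        idx = rng.choice(64 * 64, size=1000, replace=False)
        data.reshape(1, -1)[0, idx] = 5.0
        area = measure_area_series(_stack(data), 1.0, 0.2125)
        # oracle: exhaustive count of suprathreshold pixels
        assert (data[0] > 1.0).sum() == 1000
        assert area[0] == pytest.approx(1000 * 0.04515625)
        assert area[0] == pytest.approx(45.15625)

    def test_all_below_threshold_gives_zero(self):
        area = measure_area_series(_stack(np.zeros((5, 8, 8))), 0.5, 1.0)
        assert np.all(area == 0.0)

    def test_frame_permutation_permutes_series(self):
        rng = np.random.default_rng(4)
        data = rng.random((6, 16, 16))
        perm = rng.permutation(6)
        a = measure_area_series(_stack(data), 0.5, 1.0)
        b = measure_area_series(_stack(data[perm]), 0.5, 1.0)
        assert np.array_equal(a[perm], b)

    def test_mask_restricts_counting(self):
        data = np.ones((2, 4, 4))
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        area = measure_area_series(_stack(data), 0.5, 1.0, mask=mask)
        assert np.all(area == 8.0)


class TestNormalize:
    def test_constant_series_normalizes_to_one(self):
        tr = normalize_series(np.full(30, 7.0), slice(0, 10), PARAMS)
        assert np.allclose(tr.values, 1.0)

    def test_simple_ratio(self):
        series = np.concatenate([np.full(10, 50.0), [75.0]])
        tr = normalize_series(series, slice(0, 10), PARAMS)
        assert tr.values[-1] == pytest.approx(1.5)

    def test_divisor_is_arithmetic_mean_of_baseline(self):
        baseline = np.array([48, 50, 52, 49, 51, 47, 53, 50, 48, 52],
                            dtype=float)
        series = np.concatenate([baseline, [100.0]])
        tr = normalize_series(series, slice(0, 10), PARAMS)
        assert tr.values[-1] == pytest.approx(100.0 / (baseline.sum() / 10))

    def test_baseline_window_mean_is_unity(self):
        rng = np.random.default_rng(5)
        series = rng.uniform(10, 20, 50)
        tr = normalize_series(series, slice(0, 10), PARAMS)
        assert abs(tr.values[:10].mean() - 1.0) < 1e-9


def _brute_force_hes(values, onset_level, relax_level, run, start, stop):
    """Independent exhaustive scan over all frames."""
    for i in range(start, stop - run + 1):
        if all(values[i + k] >= onset_level for k in range(run)):
            for j in range(i + 1, stop):
                if values[j] <= relax_level:
                    return i, j
            return i, None
    return None, None


class TestDetectHes:
    def test_flat_trace_not_called(self):
        tr = NormalizedTrace(values=np.ones(60), baseline_window=10,
                             frame_interval=0.5)
        res = detect_hes(tr, PARAMS)
        assert not res.called_hes and res.t_shrink_onset is None

    def test_boxcar_duration_and_peak_match_exhaustive_scan(self):
        values = np.ones(60)
        values[20:33] = 1.4          # 13 frames at 0.5 min/frame
        tr = NormalizedTrace(values=values, baseline_window=10,
                             frame_interval=0.5)
        res = detect_hes(tr, PARAMS)
        i, j = _brute_force_hes(values, 1.10, 1.05, 2, 10, 60)
        assert res.called_hes
        assert res.t_shrink_onset == pytest.approx(i * 0.5) \
            == pytest.approx(10.0)
        assert res.t_relaxation == pytest.approx(j * 0.5)
        assert res.shrink_duration == pytest.approx(6.5)
        assert res.peak_percent_change == pytest.approx(40.0)

    def test_never_relaxing_trace_truncates_at_extrusion(self):
        values = np.ones(60)
        values[20:] = 1.5
        tr = NormalizedTrace(values=values, baseline_window=10,
                             frame_interval=0.5)
        res = detect_hes(tr, PARAMS, t_extrusion=25.0)
        assert res.called_hes and res.truncated
        assert res.t_relaxation == pytest.approx(25.0)
        assert res.shrink_duration == pytest.approx(25.0 - 10.0)

    def test_onset_after_extrusion_not_called(self):
        values = np.ones(60)
        values[40:] = 1.5
        tr = NormalizedTrace(values=values, baseline_window=10,
                             frame_interval=0.5)
        res = detect_hes(tr, PARAMS, t_extrusion=15.0)
        assert not res.called_hes

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_detection_matches_exhaustive_scan_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        values = 1 + rng.normal(0, 0.08, 80)
        values[:10] = 1.0
        tr = NormalizedTrace(values=values, baseline_window=10,
                             frame_interval=0.5)
        res = detect_hes(tr, PARAMS)
        i, j = _brute_force_hes(values, 1.10, 1.05, 2, 10, 80)
        if i is None:
            assert not res.called_hes
        else:
            assert res.called_hes
            assert res.t_shrink_onset == pytest.approx(i * 0.5)
            if j is not None:
                assert res.t_relaxation == pytest.approx(j * 0.5)


class TestInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6), a=st.floats(0.1, 50.0),
           b=st.floats(-20.0, 100.0))
    def test_affine_intensity_rescale_leaves_assay_unchanged(self, seed, a, b):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0, 200, (30, 24, 24))
        s1, s2 = _stack(data), _stack(a * data + b)
        t1 = select_threshold(s1, slice(0, 10), PARAMS)
        t2 = select_threshold(s2, slice(0, 10), PARAMS)
        m1 = s1.data > t1
        m2 = s2.data > t2
        if np.array_equal(m1, m2):  # identical suprathreshold pixel sets
            a1 = measure_area_series(s1, t1, 1.0)
            a2 = measure_area_series(s2, t2, 1.0)
            n1 = normalize_series(a1, slice(0, 10), PARAMS)
            n2 = normalize_series(a2, slice(0, 10), PARAMS)
            assert np.allclose(n1.values, n2.values)
        else:
            # only float round-off at the threshold may differ
            assert (m1 ^ m2).sum() <= 2

    def test_peak_response_is_monotone_in_volume_loss(self, small_config,
                                                      small_geometry):
        peaks = []
        losses = np.linspace(5, 50, 11)
        for loss in losses:
            truth = [make_shrink_event(5, t_extrusion=60.0, loss=loss)]
            ds = render_dataset(small_config, small_geometry, truth,
                                channels=("phase",))
            _, results = run_lightning(ds)
            res = next(r for r in results if r.cell_id == 5)
            assert res.called_hes
            peaks.append(res.peak_percent_change)
        assert np.all(np.diff(peaks) > 0)


class TestRunLightning:
    def test_empty_roi_list_gives_empty_results(self, small_config,
                                                small_geometry):
        ds = render_dataset(small_config, small_geometry, [],
                            channels=("phase",))
        df, results = run_lightning(stack=ds.channels["phase"], rois=[],
                                    territory_map=ds.territory_map)
        assert len(df) == 0 and results == []

    def test_noiseless_calls_match_ground_truth(self, noiseless_event_field):
        ds = noiseless_event_field
        df, results = run_lightning(ds)
        truth = {ev.cell_id: ev for ev in ds.truth}
        for r in results:
            ev = truth.get(r.cell_id)
            assert r.called_hes == (ev is not None and ev.has_shrink)
            if ev is not None and ev.has_shrink:
                assert abs(r.t_shrink_onset - ev.t_shrink_onset) \
                    <= ds.config.frame_interval + 1e-9

    def test_batched_driver_equals_per_roi_composition(self,
                                                       noiseless_event_field):
        ds = noiseless_event_field
        _, batched = run_lightning(ds)
        for roi in ds.rois:
            mask = ds.territory_map == roi.cell_id
            ref = analyze_roi(ds.channels["phase"], roi, PARAMS,
                              territory_mask=mask)
            got = next(r for r in batched if r.cell_id == roi.cell_id)
            assert got.threshold_value == pytest.approx(ref.threshold_value)
            assert np.array_equal(got.area_series, ref.area_series)
            assert got.called_hes == ref.called_hes
            assert got.t_shrink_onset == ref.t_shrink_onset
            assert got.t_relaxation == ref.t_relaxation

    def test_onset_recovery_within_one_frame_on_noiseless_fields(self):
        hits = total = 0
        for seed in range(3):
            cfg = GeneratorConfig(seed=100 + seed, noise_model="none",
                                  extrusion_rate=60.0)
            from hesquant import build_monolayer, sample_events
            geom = build_monolayer(cfg)
            truth = sample_events(cfg, geom.rois)
            if not any(ev.has_shrink for ev in truth):
                continue
            ds = render_dataset(cfg, geom, truth, channels=("phase",))
            _, results = run_lightning(ds)
            by_cell = {r.cell_id: r for r in results}
            for ev in truth:
                if ev.has_shrink:
                    total += 1
                    r = by_cell[ev.cell_id]
                    if r.called_hes and abs(r.t_shrink_onset
                                            - ev.t_shrink_onset) \
                            <= cfg.frame_interval + 1e-9:
                        hits += 1
        assert total >= 5
        assert hits / total >= 0.99
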