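"""Generator tests: geometry, event sampling, rendering, round-trip."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hesquant import (GeneratorConfig, build_monolayer, generate_dataset,
                      read_dataset, render_dataset, write_dataset)
from hesquant.io import CellROI
from hesquant.synthetic_scene import (GroundTruthEvent, _frame_at,
                                      expected_shrink_incidence,
                                      sample_events, truth_to_frame)
from conftest import make_shrink_event


def _fake_rois(n: int) -> list[CellROI]:
    return [CellROI(cell_id=i + 1, frame_first=0, frame_last=299,
                    x_min=0, y_min=0, x_max=10, y_max=10,
                    centroid_x=5.0, centroid_y=5.0) for i in range(n)]


class TestMonolayer:
    def test_partition_covers_every_pixel(self):
        cfg = GeneratorConfig(n_cells=4, image_size=(64, 64), seed=1,
                              n_frames=100)
        geom = build_monolayer(cfg)
        areas = [(geom.label_map == c).sum() for c in range(1, 5)]
        junction = (geom.label_map == 0).sum()
        assert sum(areas) + junction == 64 * 64
        # territories partition the full field with no junction gap
        assert np.array_equal(np.unique(geom.territory_map),
                              np.arange(1, 5))

    def test_same_seed_identical_label_maps(self):
        cfg = GeneratorConfig(n_cells=4, image_size=(64, 64), seed=1,
                              n_frames=100)
        a, b = build_monolayer(cfg), build_monolayer(cfg)
        assert np.array_equal(a.label_map, b.label_map)

    def test_area_dispersion_against_pixel_count_oracle(self):
        cfg = GeneratorConfig(n_cells=200, image_size=(512, 512), seed=7,
                              n_frames=100)
        geom = build_monolayer(cfg)
        # oracle: exhaustive pixel counting of the territory map
        areas = np.array([(geom.territory_map == c).sum()
                          for c in range(1, 201)])
        assert areas.sum() == 512 * 512
        assert areas.std() / areas.mean() < 0.5

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="50 px"):
            GeneratorConfig(n_cells=100, image_size=(32, 32))


class TestSampleEvents:
    def test_zero_rates_give_empty_event_list(self):
        cfg = GeneratorConfig(seed=2, extrusion_rate=0.0, division_rate=0.0,
                              p_shrink_no_extrude=0.0)
        events = sample_events(cfg, _fake_rois(200))
        assert events == []

    def test_zero_extrusion_rate_gives_no_extrusions(self):
        cfg = GeneratorConfig(seed=2, extrusion_rate=0.0)
        events = sample_events(cfg, _fake_rois(500))
        assert all(ev.t_extrusion is None for ev in events)

    def test_has_shrink_fraction_within_binomial_bound(self):
        # oracle: binomial tail bound at p = 0.7 over >= 10,000 LCE draws
        cfg = GeneratorConfig(seed=3, extrusion_rate=240.0,
                              apoptotic_fraction=0.0, division_rate=0.0,
                              p_shrink_no_extrude=0.0)
        rois = _fake_rois(18000)
        events = sample_events(cfg, rois)
        lce = [ev for ev in events if ev.event_class == "LCE"]
        assert len(lce) >= 10000
        frac = np.mean([ev.has_shrink for ev in lce])
        se = np.sqrt(0.7 * 0.3 / len(lce))
        assert abs(frac - 0.7) < 3 * se

    def test_zero_jitter_reproduces_na_to_depol_lag_exactly(self):
        cfg = GeneratorConfig(seed=4, jitter_frac=0.0, extrusion_rate=150.0,
                              shrink_duration_sd=0.0)
        events = sample_events(cfg, _fake_rois(2000))
        chained = [ev for ev in events if ev.t_na_entry is not None]
        assert len(chained) > 20
        for ev in chained:
            assert ev.t_depol - ev.t_na_entry == pytest.approx(2.4, abs=1e-9)
            assert ev.t_shrink_onset - ev.t_depol == pytest.approx(5.0,
                                                                   abs=1e-9)

    def test_movie_too_short_raises_with_minimum_span(self):
        cfg = GeneratorConfig(seed=5, n_frames=40)
        with pytest.raises(ValueError, match="at least"):
            sample_events(cfg, _fake_rois(500))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6),
           rate=st.floats(5.0, 200.0),
           jitter=st.floats(0.0, 0.4),
           apo=st.floats(0.0, 1.0))
    def test_event_time_ordering_invariant(self, seed, rate, jitter, apo):
        cfg = GeneratorConfig(seed=seed, extrusion_rate=rate,
                              jitter_frac=jitter, apoptotic_fraction=apo)
        events = sample_events(cfg, _fake_rois(300))
        for ev in events:
            chain = [ev.t_atp_decline, ev.t_na_entry, ev.t_depol,
                     ev.t_shrink_onset]
            present = [t for t in chain if t is not None]
            assert all(a < b for a, b in zip(present, present[1:]))
            if ev.t_relaxation is not None:
                assert ev.t_shrink_onset < ev.t_relaxation
                if ev.t_extrusion is not None:
                    assert ev.t_relaxation <= ev.t_extrusion
            for t in present + [ev.t_relaxation, ev.t_extrusion,
                                ev.t_division]:
                if t is not None:
                    assert 0 <= t <= cfg.movie_end

    def test_volume_loss_moments_match_configuration(self):
        cfg = GeneratorConfig(seed=6, extrusion_rate=200.0,
                              apoptotic_fraction=0.0, division_rate=0.0,
                              p_shrink_no_extrude=0.0)
        events = sample_events(cfg, _fake_rois(12000))
        losses = np.array([ev.true_vol_loss for ev in events
                           if ev.has_shrink])
        assert len(losses) >= 1000
        se_mean = cfg.vol_loss_extrude_sd / np.sqrt(len(losses))
        assert abs(losses.mean() - cfg.vol_loss_extrude_mean) < 3 * se_mean
        # sd of the sd estimate ~ sd / sqrt(2 n)
        assert abs(losses.std(ddof=1) - cfg.vol_loss_extrude_sd) \
            < 3 * cfg.vol_loss_extrude_sd / np.sqrt(2 * len(losses))

    def test_expected_incidence_ratio_is_the_multiplier(self):
        cfg = GeneratorConfig()
        ratio = expected_shrink_incidence(cfg, "contractility_inhibited") \
            / expected_shrink_incidence(cfg, "control")
        assert ratio == pytest.approx(23.0, rel=1e-6)


class TestRendering:
    def test_noiseless_eventless_frames_are_identical(self, small_config,
                                                      small_geometry):
        ds = render_dataset(small_config, small_geometry, [],
                            channels=("phase", "dibac"))
        for stack in ds.channels.values():
            assert np.array_equal(stack.data, np.broadcast_to(
                stack.data[0], stack.data.shape))

    def test_seed_reproducibility_with_noise(self):
        cfg = GeneratorConfig(seed=11, n_cells=10, image_size=(128, 128),
                              n_frames=120)
        a = generate_dataset(cfg, channels=("phase",))
        b = generate_dataset(cfg, channels=("phase",))
        assert np.array_equal(a.channels["phase"].data,
                              b.channels["phase"].data)

    def test_channel_rendering_independent_of_subset(self, small_config,
                                                     small_geometry):
        truth = [make_shrink_event(3, t_extrusion=60.0)]
        both = render_dataset(small_config, small_geometry, truth,
                              channels=("phase", "dibac"))
        only = render_dataset(small_config, small_geometry, truth,
                              channels=("dibac",))
        assert np.array_equal(both.channels["dibac"].data,
                              only.channels["dibac"].data)

    def test_gap_area_strictly_increases_to_maximum(self, small_config,
                                                    small_geometry):
        truth = [make_shrink_event(5, t_extrusion=60.0, loss=25.0)]
        ds = render_dataset(small_config, small_geometry, truth,
                            channels=("phase",))
        ev = truth[0]
        dt = small_config.frame_interval
        f_on = _frame_at(ev.t_shrink_onset, dt)
        data = ds.channels["phase"].data
        thr = np.percentile(data[:10], 98)
        mask = ds.territory_map == 5
        # oracle: exhaustive per-frame pixel counting
        counts = [(data[f][mask] > thr).sum()
                  for f in range(f_on - 1, f_on + 4)]
        assert counts[0] < counts[1] < counts[2] < counts[3]
        f_rel = _frame_at(ev.t_relaxation, dt)
        assert counts[3] == max((data[f][mask] > thr).sum()
                                for f in range(f_on, f_rel))

    def test_dibac_step_located_at_depolarization(self, noiseless_event_field):
        ds = noiseless_event_field
        ev = ds.truth[0]
        mask = ds.territory_map == ev.cell_id
        trace = ds.channels["dibac"].data[:, mask].mean(axis=1)
        dt = ds.config.frame_interval
        f_dep = _frame_at(ev.t_depol, dt)
        assert trace[f_dep - 1] == pytest.approx(trace[0])
        assert trace[f_dep] > 1.3 * trace[0]

    def test_volume_reporter_tracks_true_volume(self, noiseless_event_field):
        ds = noiseless_event_field
        ev = ds.truth[0]   # extruding shrinker, loss 22%
        mask = ds.territory_map == ev.cell_id
        integrated = ds.channels["volume_reporter"].data[:, mask].sum(axis=1)
        rel = integrated / integrated[0]
        dt = ds.config.frame_interval
        f_ext = _frame_at(ev.t_extrusion, dt)
        t = np.arange(len(rel)) * dt
        t_trough = ev.t_shrink_onset + 0.45 * (ev.t_relaxation
                                               - ev.t_shrink_onset)
        expected = np.interp(t, [0, ev.t_shrink_onset, t_trough, f_ext * dt],
                             [1, 1, 0.78, 0.78])
        assert np.all(np.abs(rel[:f_ext] - expected[:f_ext]) < 0.01)

    def test_missing_chain_time_rejected_for_trace_channel(self, small_config,
                                                           small_geometry):
        ev = GroundTruthEvent(cell_id=2, event_class="none", has_shrink=True,
                              t_shrink_onset=40.0, t_relaxation=46.0,
                              true_vol_loss=10.0)
        with pytest.raises(ValueError, match="dibac"):
            render_dataset(small_config, small_geometry, [ev],
                           channels=("dibac",))


class TestRoundTrip:
    def test_write_read_round_trip(self, tmp_path, small_config,
                                   small_geometry):
        truth = [make_shrink_event(3, t_extrusion=60.0),
                 GroundTruthEvent(cell_id=9, event_class="division",
                                  t_division=30.0)]
        ds = render_dataset(small_config, small_geometry, truth,
                            channels=("phase", "calcein"))
        write_dataset(ds, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        for name in ds.channels:
            assert np.array_equal(ds.channels[name].data,
                                  back.channels[name].data)
            assert back.channels[name].pixel_size == pytest.approx(
                ds.config.pixel_size)
        assert truth_to_frame(back.truth).equals(truth_to_frame(ds.truth))
        assert back.config == ds.config
        assert [dataclasses.astuple(r) for r in back.rois] \
            == [dataclasses.astuple(r) for r in ds.rois]

    def test_empty_truth_round_trips(self, tmp_path, small_config,
                                     small_geometry):
        ds = render_dataset(small_config, small_geometry, [],
                            channels=("phase",))
        write_dataset(ds, tmp_path / "empty")
        back = read_dataset(tmp_path / "empty")
        assert back.truth == []
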