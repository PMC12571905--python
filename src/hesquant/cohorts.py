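"""End-to-end cohort pipelines over synthetic multi-field experiments.

A synthetic "experiment" is a set of independently seeded fields of view
(each a small confluent monolayer movie), mirroring multi-position
acquisition.  These drivers generate fields until the requested number of
events has accumulated, run the measurement pipeline on each field, and
pool per-cell calls into cohort-level estimates:

* :func:`run_lce_cohort` — live-cell extrusions: HES incidence, detected
  shrink durations, depolarization→shrink and Na⁺→depolarization lags, and
  reporter-based percent volume loss of extruding shrinkers.
* :func:`run_apoptotic_cohort` — apoptotic extrusions (event type fixed to
  apoptotic so the rare shrink fraction is estimated from a usefully sized
  cohort; the shrink-given-apoptotic model itself stays at its default).
* :func:`run_stay_shrink_cohort` — cells that shrink but remain in the
  layer (background shrink probability raised to reach the requested count;
  the volume-loss model and noise stay at their defaults).
* :func:`run_condition_pair` — control vs contractility-inhibited cohorts
  and the shrink-incidence fold-change.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .event_statistics import fold_change, summarize
from .lightning_assay import LightningParams, run_lightning
from .synthetic_scene import (GeneratorConfig, SyntheticDataset,
                              build_monolayer, render_dataset,
                              sample_events)
from .trace_kinetics import detect_onset, extract_trace_masked, normalize_trace
from .volumetrics import percent_shrink, smooth_series

__all__ = ["default_config", "field_seeds", "generate_field",
           "run_lce_cohort", "run_apoptotic_cohort",
           "run_stay_shrink_cohort", "run_condition_pair"]

ONSET_DELTA = 0.10
ONSET_CONSECUTIVE = 2


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions for one field of view."""
    return GeneratorConfig(seed=seed, **overrides)


def field_seeds(base_seed: int, stream: int, n: int) -> list[int]:
    """Deterministic per-field seeds derived from one experiment seed."""
    ss = np.random.SeedSequence([int(base_seed), int(stream)])
    return [int(s % (2 ** 31 - 1)) for s in ss.generate_state(n)]


def generate_field(seed: int, channels: Sequence[str] = ("phase",),
                   condition: str = "control",
                   **overrides) -> SyntheticDataset:
    config = default_config(seed=seed, **overrides)
    geom = build_monolayer(config)
    truth = sample_events(config, geom.rois, condition=condition)
    return render_dataset(config, geom, truth, channels=channels,
                          condition=condition)


def _trace_window(roi, n_frames: int, params: LightningParams
                  ) -> tuple[int, int]:
    """Frame window used for per-cell trace analysis (same as lightning)."""
    if roi.frame_last < n_frames - 1:
        start = max(0, roi.frame_last - params.pre_extrusion_frames
                    - params.baseline_window)
        return start, roi.frame_last
    return 0, n_frames


def _global_table(tables: list[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(tables, ignore_index=True) if tables \
        else pd.DataFrame(columns=["cell_id", "called_hes", "event_class"])


def _field_cell_table(dataset: SyntheticDataset, results_df: pd.DataFrame,
                      offset: int) -> pd.DataFrame:
    labels = {ev.cell_id: ev.event_class for ev in dataset.truth}
    table = results_df[["cell_id", "called_hes"]].copy()
    table["event_class"] = table["cell_id"].map(labels).fillna("none")
    table["cell_id"] = table["cell_id"] + offset
    return table


def run_lce_cohort(base_seed: int, min_lce: int = 210,
                   min_kinetic: int = 60, min_volume: int = 110,
                   max_fields: int = 1200,
                   params: LightningParams | None = None) -> dict:
    """Accumulate live-cell extrusions across fields and measure them.

    Returns pooled per-cell calls plus per-event measurements: detected
    shrink durations (min), paired depolarization→shrink-onset and
    Na⁺-entry→depolarization lags (min), and reporter percent volume loss
    for extruding shrinkers.
    """
    params = params or LightningParams()
    seeds = field_seeds(base_seed, 101, max_fields)
    tables, durations, volumes = [], [], []
    lags_depol_shrink, lags_na_depol = [], []
    n_lce = n_shrink_lce = 0
    n_fields = 0
    for i, seed in enumerate(seeds):
        need_kinetic = len(lags_depol_shrink) < min_kinetic
        need_volume = len(volumes) < min_volume
        channels = ["phase"]
        if need_kinetic:
            channels += ["dibac", "corona"]
        if need_volume:
            channels.append("volume_reporter")
        ds = generate_field(seed, channels=channels)
        results_df, results = run_lightning(ds, params=params)
        tables.append(_field_cell_table(ds, results_df, offset=i * 1000))
        by_cell = {r.cell_id: r for r in results}
        rois = {r.cell_id: r for r in ds.rois}
        dt = ds.config.frame_interval
        for ev in ds.truth:
            if ev.event_class != "LCE":
                continue
            n_lce += 1
            res = by_cell[ev.cell_id]
            if ev.has_shrink:
                n_shrink_lce += 1
                if res.called_hes and res.shrink_duration is not None:
                    durations.append(res.shrink_duration)
                roi = rois[ev.cell_id]
                start, stop = _trace_window(roi, ds.config.n_frames, params)
                mask = ds.territory_map == ev.cell_id
                if need_kinetic and res.called_hes \
                        and res.t_shrink_onset is not None:
                    onsets = {}
                    for ch in ("dibac", "corona"):
                        raw = extract_trace_masked(ds.channels[ch], mask)
                        trace = normalize_trace(
                            raw[start:stop],
                            baseline_window=params.baseline_window,
                            frame_interval=dt, frame_offset=start)
                        call = detect_onset(trace, "up", delta=ONSET_DELTA,
                                            min_consecutive=ONSET_CONSECUTIVE,
                                            channel=ch, cell_id=ev.cell_id)
                        onsets[ch] = call.t_onset
                    if onsets["dibac"] is not None:
                        lags_depol_shrink.append(
                            res.t_shrink_onset - onsets["dibac"])
                        if onsets["corona"] is not None:
                            lags_na_depol.append(
                                onsets["dibac"] - onsets["corona"])
                if need_volume:
                    raw = extract_trace_masked(
                        ds.channels["volume_reporter"], mask)
                    trace = normalize_trace(
                        smooth_series(raw[start:stop]),
                        baseline_window=params.baseline_window,
                        frame_interval=dt, frame_offset=start)
                    volumes.append(percent_shrink(
                        trace, slice(params.baseline_window, stop - start)))
        n_fields = i + 1
        if (n_lce >= min_lce and len(lags_depol_shrink) >= min_kinetic
                and len(volumes) >= min_volume):
            break
    table = _global_table(tables)
    summary = summarize(table, condition="control", seed=base_seed)
    return {
        "summary": summary,
        "cell_table": table,
        "n_fields": n_fields,
        "n_lce": n_lce,
        "n_shrink_lce": n_shrink_lce,
        "hes_fraction_lce": summary.hes_fraction_lce,
        "durations": np.asarray(durations),
        "mean_shrink_duration": float(np.mean(durations)) if durations
            else np.nan,
        "lags_depol_to_shrink": np.asarray(lags_depol_shrink),
        "lags_na_to_depol": np.asarray(lags_na_depol),
        "volume_losses": np.asarray(volumes),
    }


def run_lce_experiment(seeds: Sequence[int], min_lce_total: int = 210,
                       min_kinetic_total: int = 60,
                       min_volume_total: int = 110,
                       params: LightningParams | None = None) -> dict:
    """Pool :func:`run_lce_cohort` batches over several experiment seeds."""
    n = max(len(seeds), 1)
    batches = [run_lce_cohort(
        s, min_lce=-(-min_lce_total // n),
        min_kinetic=-(-min_kinetic_total // n),
        min_volume=-(-min_volume_total // n), params=params) for s in seeds]
    table = pd.concat(
        [b["cell_table"].assign(cell_id=lambda d, k=i: d["cell_id"]
                                + k * 10 ** 7)
         for i, b in enumerate(batches)], ignore_index=True)
    summary = summarize(table, condition="control", seed=int(seeds[0]))
    durations = np.concatenate([b["durations"] for b in batches])
    lags_ds = np.concatenate([b["lags_depol_to_shrink"] for b in batches])
    lags_nd = np.concatenate([b["lags_na_to_depol"] for b in batches])
    volumes = np.concatenate([b["volume_losses"] for b in batches])
    return {
        "summary": summary,
        "n_fields": sum(b["n_fields"] for b in batches),
        "n_lce": sum(b["n_lce"] for b in batches),
        "n_shrink_lce": sum(b["n_shrink_lce"] for b in batches),
        "hes_fraction_lce": summary.hes_fraction_lce,
        "durations": durations,
        "mean_shrink_duration": float(durations.mean()) if len(durations)
            else np.nan,
        "lags_depol_to_shrink": lags_ds,
        "lags_na_to_depol": lags_nd,
        "volume_losses": volumes,
    }


def run_apoptotic_cohort(base_seed: int, min_apoptotic: int = 310,
                         max_fields: int = 1500,
                         params: LightningParams | None = None) -> dict:
    """Shrink fraction among apoptotic extrusions.

    The generator is run with all extrusions apoptotic so the rare shrink
    fraction (default model: 3%) is estimated from the requested number of
    events; every other parameter keeps its default.
    """
    params = params or LightningParams()
    seeds = field_seeds(base_seed, 202, max_fields)
    tables = []
    n_apo = 0
    n_fields = 0
    for i, seed in enumerate(seeds):
        ds = generate_field(seed, channels=("phase",),
                            apoptotic_fraction=1.0)
        results_df, _ = run_lightning(ds, params=params)
        tables.append(_field_cell_table(ds, results_df, offset=i * 1000))
        n_apo += sum(ev.event_class == "apoptotic_extrusion"
                     for ev in ds.truth)
        n_fields = i + 1
        if n_apo >= min_apoptotic:
            break
    table = _global_table(tables)
    summary = summarize(table, condition="all_apoptotic", seed=base_seed)
    return {"summary": summary, "cell_table": table, "n_fields": n_fields,
            "n_apoptotic": n_apo,
            "hes_fraction_apoptotic": summary.hes_fraction_apoptotic}


def run_stay_shrink_cohort(base_seed: int, min_cells: int = 110,
                           max_fields: int = 400,
                           background_shrink_prob: float = 0.15,
                           params: LightningParams | None = None) -> dict:
    """Percent volume loss of cells that shrink but stay in the layer.

    The background (non-extruding) shrink probability is raised so the
    cohort reaches the requested size; the volume-loss distribution and
    noise stay at their defaults.
    """
    params = params or LightningParams()
    seeds = field_seeds(base_seed, 303, max_fields)
    volumes = []
    n_fields = 0
    for i, seed in enumerate(seeds):
        ds = generate_field(seed, channels=("volume_reporter",),
                            p_shrink_no_extrude=background_shrink_prob)
        for ev in ds.truth:
            if ev.event_class != "none" or not ev.has_shrink:
                continue
            mask = ds.territory_map == ev.cell_id
            raw = extract_trace_masked(ds.channels["volume_reporter"], mask)
            trace = normalize_trace(
                smooth_series(raw), baseline_window=params.baseline_window,
                frame_interval=ds.config.frame_interval)
            volumes.append(percent_shrink(
                trace, slice(params.baseline_window, len(raw))))
        n_fields = i + 1
        if len(volumes) >= min_cells:
            break
    return {"volume_losses": np.asarray(volumes), "n_fields": n_fields,
            "n_cells": len(volumes)}


def run_condition_pair(base_seed: int, n_fields_baseline: int = 500,
                       n_fields_treated: int = 170, n_boot: int = 2000,
                       treated_condition: str = "contractility_inhibited",
                       params: LightningParams | None = None) -> dict:
    """Control vs condition cohorts and the shrink-incidence fold-change."""
    params = params or LightningParams()

    def build(condition: str, stream: int, n_fields: int) -> pd.DataFrame:
        tables = []
        for i, seed in enumerate(field_seeds(base_seed, stream, n_fields)):
            ds = generate_field(seed, channels=("phase",), condition=condition)
            results_df, _ = run_lightning(ds, params=params)
            tables.append(_field_cell_table(ds, results_df, offset=i * 1000))
        return _global_table(tables)

    control_table = build("control", 404, n_fields_baseline)
    treated_table = build(treated_condition, 505, n_fields_treated)
    control = summarize(control_table, condition="control",
                        seed=base_seed, n_boot=n_boot)
    treated = summarize(treated_table, condition=treated_condition,
                        seed=base_seed + 1, n_boot=n_boot)
    fc = fold_change(control, treated, statistic="shrink_incidence",
                     seed=base_seed + 2, n_boot=n_boot)
    return {"control": control, "treated": treated, "fold_change": fc}
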