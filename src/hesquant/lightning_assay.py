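"""The lightning assay: junctional-brightness thresholding and HES calling.

Transient cell shrinkage shows up in phase-contrast movies as a burst of
bright junctional signal ("lightning") around the cell.  The assay fixes one
intensity threshold from pre-event frames (a percentile of the pooled
baseline pixel histogram), counts suprathreshold area per frame, normalizes
the area series to a 10-frame baseline, and calls a homeostatic early
shrinkage (HES) event when the normalized area rises by ``onset_delta``
(default 10%) for ``min_consecutive`` frames; relaxation is the return to
within ``relax_delta`` (default 5%) of baseline.

Thresholding is strict-greater, so a constant image yields zero area, and no
morphological filtering is applied.  The same scalar threshold is reused for
every frame of a video.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CellROI, ImageStack
from .synthetic_scene import SyntheticDataset

__all__ = ["LightningParams", "LightningResult", "NormalizedTrace",
           "CropWindow", "crop_window", "select_threshold",
           "measure_area_series", "normalize_series", "detect_hes",
           "analyze_roi", "run_lightning", "results_to_frame"]


@dataclass
class LightningParams:
    """Tunable parameters of the lightning assay.

    ``threshold_percentile``, ``onset_delta`` and ``relax_delta`` automate
    the threshold and event criteria that are otherwise set by eye; they are
    exposed so a user can reproduce a manual setting.
    ``pre_extrusion_frames`` bounds the event search span before a known
    extrusion (the assay crops "before, during and briefly after" the event
    rather than scanning the whole movie).
    """

    baseline_window: int = 10          # frames averaged to define baseline = 1
    threshold_percentile: float = 98.0  # percentile of pooled baseline pixels
    onset_delta: float = 0.10          # fractional rise defining shrink onset
    min_consecutive: int = 2           # frames the rise must be sustained
    relax_delta: float = 0.05          # fractional level defining relaxation
    window_px: int = 400               # side of the analysis crop, px
    pre_extrusion_frames: int = 50     # search-span length before extrusion

    def __post_init__(self) -> None:
        if self.baseline_window < 2:
            raise ValueError("baseline_window must be >= 2")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold_percentile must be in (0, 100)")
        if not self.onset_delta > self.relax_delta > 0:
            raise ValueError("need onset_delta > relax_delta > 0")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")


@dataclass
class NormalizedTrace:
    """A per-cell series divided by its pre-event baseline-window mean.

    ``values[0]`` corresponds to absolute movie frame ``frame_offset``; the
    baseline occupies ``values[:baseline_window]``.
    """

    values: np.ndarray
    baseline_window: int
    frame_interval: float
    frame_offset: int = 0

    def time(self, index: int) -> float:
        return (self.frame_offset + index) * self.frame_interval


@dataclass
class LightningResult:
    """Lightning-assay output for one cell."""

    cell_id: int
    threshold_value: float
    area_series: np.ndarray            # µm² per analyzed frame
    normalized_series: np.ndarray
    frame_offset: int
    peak_percent_change: float
    t_shrink_onset: float | None       # minutes
    t_relaxation: float | None
    t_extrusion: float | None
    shrink_duration: float | None
    called_hes: bool
    truncated: bool = False            # relaxation never reached in the span
    degenerate: bool = False           # zero/constant baseline


RESULT_COLUMNS = ["cell_id", "threshold_value", "peak_percent_change",
                  "t_shrink_onset_min", "t_relaxation_min", "t_extrusion_min",
                  "shrink_duration_min", "called_hes"]


def results_to_frame(results: Sequence[LightningResult]) -> pd.DataFrame:
    rows = [{"cell_id": r.cell_id, "threshold_value": r.threshold_value,
             "peak_percent_change": r.peak_percent_change,
             "t_shrink_onset_min": r.t_shrink_onset,
             "t_relaxation_min": r.t_relaxation,
             "t_extrusion_min": r.t_extrusion,
             "shrink_duration_min": r.shrink_duration,
             "called_hes": r.called_hes} for r in results]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@dataclass
class CropWindow:
    """A window crop with its offset recorded for exact re-embedding."""

    stack: ImageStack
    y_offset: int
    x_offset: int

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.stack.shape_yx


def crop_window(stack: ImageStack, roi: CellROI,
                params: LightningParams) -> CropWindow:
    """Crop a ``window_px``-square region centred on the ROI centroid.

    Clipped at image borders; the actual offset is recorded so the crop can
    be re-embedded losslessly.
    """
    h, w = stack.shape_yx
    cy, cx = roi.centroid_y, roi.centroid_x
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError(f"ROI {roi.cell_id} centroid ({cy:.1f}, {cx:.1f}) "
                         f"outside a {h}x{w} image")
    half = params.window_px // 2
    y0 = max(0, int(round(cy)) - half)
    x0 = max(0, int(round(cx)) - half)
    y1 = min(h, y0 + params.window_px)
    x1 = min(w, x0 + params.window_px)
    y0 = max(0, min(y0, y1 - params.window_px)) if y1 - params.window_px > 0 else 0
    x0 = max(0, min(x0, x1 - params.window_px)) if x1 - params.window_px > 0 else 0
    data = stack.data[..., y0:y1, x0:x1]
    return CropWindow(
        stack=ImageStack(data=data, pixel_size=stack.pixel_size,
                         frame_interval=stack.frame_interval,
                         z_step=stack.z_step, channel=stack.channel),
        y_offset=y0, x_offset=x0)


def select_threshold(crop: ImageStack | np.ndarray, baseline_frames: slice,
                     params: LightningParams) -> float:
    """Pick one scalar threshold from the pooled baseline pixel histogram.

    The threshold is the ``threshold_percentile``-th percentile of all pixel
    intensities in the baseline frames and is reused for every frame.
    """
    data = crop.data if isinstance(crop, ImageStack) else np.asarray(crop)
    pool = data[baseline_frames]
    n_frames = pool.shape[0]
    if n_frames < params.baseline_window:
        raise ValueError(f"baseline range has {n_frames} frames; "
                         f"need >= {params.baseline_window}")
    return float(np.percentile(pool, params.threshold_percentile))


def measure_area_series(crop: ImageStack | np.ndarray, threshold: float,
                        pixel_size: float,
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Suprathreshold area per frame in µm² (strict greater-than rule).

    ``mask`` optionally restricts counting to a pixel subset (e.g. the
    analyzed cell's territory); by default the whole crop is counted.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = crop.data if isinstance(crop, ImageStack) else np.asarray(crop)
    above = data > threshold
    if mask is not None:
        if mask.shape != data.shape[-2:]:
            raise ValueError("mask shape does not match crop")
        counts = above[..., mask].sum(axis=-1)
    else:
        counts = above.reshape(above.shape[0], -1).sum(axis=1)
    return counts.astype(float) * pixel_size ** 2


def normalize_series(series: np.ndarray, baseline_frames: slice,
                     params: LightningParams, frame_interval: float = 1.0,
                     frame_offset: int = 0) -> NormalizedTrace:
    """Divide a series by the mean of its baseline window."""
    series = np.asarray(series, dtype=float)
    baseline = series[baseline_frames]
    if len(baseline) < params.baseline_window:
        raise ValueError("baseline window shorter than configured")
    mean = baseline.mean()
    if mean <= 0:
        raise ValueError("baseline mean is non-positive (degenerate "
                         "threshold: no suprathreshold baseline area)")
    return NormalizedTrace(values=series / mean,
                           baseline_window=params.baseline_window,
                           frame_interval=frame_interval,
                           frame_offset=frame_offset)


def _first_run_at_or_above(values: np.ndarray, level: float,
                           start: int, stop: int, run: int) -> int | None:
    """Index of the first run of ``run`` consecutive values >= level."""
    ok = values >= level
    count = 0
    for i in range(start, stop):
        count = count + 1 if ok[i] else 0
        if count >= run:
            return i - run + 1
    return None


def detect_hes(trace: NormalizedTrace, params: LightningParams,
               t_extrusion: float | None = None) -> LightningResult:
    """Call shrink onset / relaxation on a normalized area trace.

    Onset is the first run of ``min_consecutive`` frames at or above
    ``1 + onset_delta`` within the search span (after the baseline window,
    before the extrusion when its time is known); relaxation is the first
    later frame at or below ``1 + relax_delta`` (truncated at the extrusion
    and flagged when never reached).
    """
    v = trace.values
    n = len(v)
    if n <= trace.baseline_window + params.min_consecutive:
        raise ValueError("trace too short for onset detection")
    start = trace.baseline_window
    stop = n
    if t_extrusion is not None:
        f_ext_rel = int(np.ceil(t_extrusion / trace.frame_interval - 1e-9)) \
            - trace.frame_offset
        stop = min(stop, max(start, f_ext_rel))
    onset_idx = _first_run_at_or_above(v, 1 + params.onset_delta,
                                       start, stop, params.min_consecutive)
    t_on = t_rel = duration = None
    truncated = False
    if onset_idx is None:
        peak = (v[start:stop].max() - 1) * 100 if stop > start else 0.0
        called = False
        peak_span = None
    else:
        called = True
        t_on = trace.time(onset_idx)
        relax_idx = None
        for i in range(onset_idx + 1, stop):
            if v[i] <= 1 + params.relax_delta:
                relax_idx = i
                break
        if relax_idx is None:
            truncated = True
            t_rel = t_extrusion if t_extrusion is not None \
                else trace.time(stop - 1)
            relax_idx = stop - 1
        else:
            t_rel = trace.time(relax_idx)
        duration = t_rel - t_on
        peak = (v[onset_idx:relax_idx + 1].max() - 1) * 100
    return LightningResult(
        cell_id=-1, threshold_value=np.nan,
        area_series=np.empty(0), normalized_series=v,
        frame_offset=trace.frame_offset,
        peak_percent_change=float(peak),
        t_shrink_onset=t_on, t_relaxation=t_rel, t_extrusion=t_extrusion,
        shrink_duration=duration, called_hes=called, truncated=truncated)


# ---------------------------------------------------------------------------
# per-ROI composition and batch driver
# ---------------------------------------------------------------------------

def _analysis_frames(roi: CellROI, n_frames: int,
                     params: LightningParams) -> tuple[int, int, float | None]:
    """(window start, window stop, t_extrusion) for one ROI.

    Extruding cells (``frame_last`` before the movie end) are analyzed over
    the ``pre_extrusion_frames`` preceding the extrusion plus the baseline
    window; cells that stay are analyzed over the whole movie.
    """
    if roi.frame_last < n_frames - 1:
        f_ext = roi.frame_last
        start = max(0, f_ext - params.pre_extrusion_frames
                    - params.baseline_window)
        return start, f_ext, None  # t_ext filled by caller in minutes
    return 0, n_frames, None


def analyze_roi(stack: ImageStack, roi: CellROI, params: LightningParams,
                territory_mask: np.ndarray | None = None) -> LightningResult:
    """Compose the elementary operations for one cell.

    This is the reference (per-ROI) path; :func:`run_lightning` produces
    identical results with a batched implementation.
    """
    crop = crop_window(stack, roi, params)
    start, stop, _ = _analysis_frames(roi, stack.n_frames, params)
    is_extruder = roi.frame_last < stack.n_frames - 1
    t_ext = roi.frame_last * stack.frame_interval if is_extruder else None
    baseline = slice(start, start + params.baseline_window)
    threshold = select_threshold(crop.stack, baseline, params)
    mask = None
    if territory_mask is not None:
        h, w = crop.shape_yx
        mask = territory_mask[crop.y_offset:crop.y_offset + h,
                              crop.x_offset:crop.x_offset + w]
    window = ImageStack(data=crop.stack.data[start:stop],
                        pixel_size=stack.pixel_size,
                        frame_interval=stack.frame_interval,
                        channel=stack.channel)
    try:
        area = measure_area_series(window, threshold, stack.pixel_size, mask)
        trace = normalize_series(area, slice(0, params.baseline_window),
                                 params, frame_interval=stack.frame_interval,
                                 frame_offset=start)
        result = detect_hes(trace, params, t_extrusion=t_ext)
    except ValueError:
        # degenerate baseline or a trace too short for onset detection
        return LightningResult(cell_id=roi.cell_id, threshold_value=threshold,
                               area_series=np.empty(0),
                               normalized_series=np.empty(0),
                               frame_offset=start, peak_percent_change=0.0,
                               t_shrink_onset=None, t_relaxation=None,
                               t_extrusion=t_ext, shrink_duration=None,
                               called_hes=False, degenerate=True)
    result.cell_id = roi.cell_id
    result.threshold_value = threshold
    result.area_series = area
    return result


def run_lightning(dataset: SyntheticDataset | None = None,
                  stack: ImageStack | None = None,
                  rois: Sequence[CellROI] | None = None,
                  territory_map: np.ndarray | None = None,
                  params: LightningParams | None = None,
                  use_territory_mask: bool = True,
                  out_csv: str | Path | None = None
                  ) -> tuple[pd.DataFrame, list[LightningResult]]:
    """Run the lightning assay for every ROI of a movie.

    Accepts either a :class:`SyntheticDataset` (phase channel + territory
    map) or an explicit stack / ROI list.  When a territory map is available
    the suprathreshold area is counted inside each cell's own territory,
    which keeps neighbouring events from contaminating the cell's series;
    without one, the whole crop is counted.  Cells sharing a crop and
    baseline are processed in one pass (threshold and per-frame label
    counts), which is exactly equivalent to the per-ROI composition.
    """
    params = params or LightningParams()
    if dataset is not None:
        if "phase" not in dataset.channels:
            raise ValueError("dataset has no phase channel")
        stack = dataset.channels["phase"]
        rois = dataset.rois
        territory_map = dataset.territory_map
    if stack is None or rois is None:
        raise ValueError("need a dataset or an explicit stack and ROI list")
    if not use_territory_mask:
        territory_map = None

    n_frames = stack.n_frames
    dt = stack.frame_interval
    px = stack.pixel_size
    results: list[LightningResult] = []

    full_field = params.window_px >= max(stack.shape_yx)
    stayers = [r for r in rois if r.frame_last >= n_frames - 1]
    extruders = [r for r in rois if r.frame_last < n_frames - 1]

    if full_field and territory_map is not None and stayers:
        # shared crop + shared baseline -> one threshold, one counting pass
        baseline = slice(0, params.baseline_window)
        threshold = select_threshold(stack, baseline, params)
        above = stack.data > threshold
        n_labels = int(territory_map.max()) + 1
        flat_labels = territory_map.ravel()
        counts = np.empty((n_frames, n_labels))
        for f in range(n_frames):
            counts[f] = np.bincount(flat_labels[above[f].ravel()],
                                    minlength=n_labels)
        areas = counts * px ** 2
        for roi in stayers:
            series = areas[:, roi.cell_id]
            try:
                trace = normalize_series(series, baseline, params,
                                         frame_interval=dt, frame_offset=0)
            except ValueError:
                results.append(LightningResult(
                    cell_id=roi.cell_id, threshold_value=threshold,
                    area_series=series, normalized_series=np.empty(0),
                    frame_offset=0, peak_percent_change=0.0,
                    t_shrink_onset=None, t_relaxation=None, t_extrusion=None,
                    shrink_duration=None, called_hes=False, degenerate=True))
                continue
            res = detect_hes(trace, params, t_extrusion=None)
            res.cell_id = roi.cell_id
            res.threshold_value = threshold
            res.area_series = series
            results.append(res)
    else:
        extruders = list(rois)
        stayers = []

    for roi in extruders:
        mask = None
        if territory_map is not None:
            mask = territory_map == roi.cell_id
        results.append(analyze_roi(stack, roi, params,
                                   territory_mask=mask))

    results.sort(key=lambda r: r.cell_id)
    df = results_to_frame(results)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df, results
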