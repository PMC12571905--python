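"""Per-cell fluorescence traces, onset detection and cross-channel lags.

Traces are per-frame mean intensities over a cell's ROI, normalized to a
pre-event baseline window (default 10 frames).  Directional onsets (e.g. the
DiBAC₄(3) rise at depolarization, the CoroNa rise at Na⁺ entry, the ATP
reporter decline) are the first sustained excursion beyond ±``delta`` of
baseline.  Lags between channels are averaged over cells with both onsets;
cells missing either onset are counted, not imputed.  Because the two dyes
could not be filmed together in the original experiments, both the paired
(same-cell) and the cohort-difference lag are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import CellROI, ImageStack
from .lightning_assay import NormalizedTrace

__all__ = ["OnsetCall", "LagEstimate", "extract_trace",
           "extract_trace_masked", "normalize_trace", "detect_onset",
           "estimate_lag", "normalize_to_precrowding"]


@dataclass
class OnsetCall:
    """A directional onset in one channel of one cell."""

    cell_id: int
    channel: str
    direction: str                  # "up" | "down"
    t_onset: float | None           # minutes, absent if no onset
    effect_size: float              # peak |normalized - 1| over the search span


@dataclass
class LagEstimate:
    """Lag between onsets in two channels (later minus earlier)."""

    channel_pair: tuple[str, str]
    per_cell_lags: np.ndarray       # minutes, one per cell with both onsets
    mean_lag: float
    sd_lag: float
    n_cells: int
    n_missing_a: int
    n_missing_b: int
    cohort_difference: float        # mean(t_b) - mean(t_a) over all onsets


def extract_trace(stack: ImageStack, roi: CellROI) -> np.ndarray:
    """Per-frame mean pixel intensity inside the ROI bounding box."""
    if roi.height <= 0 or roi.width <= 0:
        raise ValueError(f"ROI {roi.cell_id} is empty")
    h, w = stack.shape_yx
    if roi.y_min >= h or roi.x_min >= w or roi.y_max <= 0 or roi.x_max <= 0:
        raise ValueError(f"ROI {roi.cell_id} lies outside the image")
    box = stack.data[..., roi.y_min:roi.y_max, roi.x_min:roi.x_max]
    return box.reshape(stack.n_frames, -1).mean(axis=1)


def extract_trace_masked(stack: ImageStack, mask: np.ndarray) -> np.ndarray:
    """Per-frame mean intensity over an explicit pixel mask.

    Restricting to the cell's own territory removes the bounding-box
    dilution by neighbouring cells, which matters when absolute effect sizes
    (volume loss, step amplitudes) are read off the trace.
    """
    if not mask.any():
        raise ValueError("empty mask")
    return stack.data[..., mask].mean(axis=-1)


def normalize_trace(series: np.ndarray, baseline_window: int = 10,
                    frame_interval: float = 1.0,
                    frame_offset: int = 0) -> NormalizedTrace:
    """Divide a raw trace by the mean of its leading baseline window."""
    series = np.asarray(series, dtype=float)
    if len(series) < baseline_window + 1:
        raise ValueError("trace shorter than the baseline window")
    mean = series[:baseline_window].mean()
    if mean <= 0:
        raise ValueError("non-positive baseline mean")
    return NormalizedTrace(values=series / mean,
                           baseline_window=baseline_window,
                           frame_interval=frame_interval,
                           frame_offset=frame_offset)


def detect_onset(trace: NormalizedTrace, direction: str, delta: float = 0.10,
                 min_consecutive: int = 2, channel: str = "",
                 cell_id: int = -1,
                 exclude_frames: Iterable[int] = ()) -> OnsetCall:
    """First sustained excursion beyond ±delta of baseline.

    ``direction="up"`` looks for ``min_consecutive`` frames at or above
    ``1 + delta``; ``"down"`` for frames at or below ``1 - delta``.  Frames
    listed in ``exclude_frames`` (e.g. medium changes that refresh the dye)
    break any run crossing them.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    v = trace.values
    n = len(v)
    if n <= trace.baseline_window + min_consecutive:
        raise ValueError("trace too short for onset detection")
    if direction == "up":
        ok = v >= 1 + delta
        effect = float(np.max(v[trace.baseline_window:] - 1, initial=0.0))
    else:
        ok = v <= 1 - delta
        effect = float(np.max(1 - v[trace.baseline_window:], initial=0.0))
    excluded = set(int(f) - trace.frame_offset for f in exclude_frames)
    count = 0
    onset = None
    for i in range(trace.baseline_window, n):
        count = count + 1 if (ok[i] and i not in excluded) else 0
        if count >= min_consecutive:
            onset = i - min_consecutive + 1
            break
    return OnsetCall(cell_id=cell_id, channel=channel, direction=direction,
                     t_onset=None if onset is None else trace.time(onset),
                     effect_size=max(effect, 0.0))


def estimate_lag(calls_a: Sequence[OnsetCall],
                 calls_b: Sequence[OnsetCall]) -> LagEstimate:
    """Mean per-cell lag ``t_onset(b) - t_onset(a)`` over matched cells."""
    a_by_cell = {c.cell_id: c for c in calls_a}
    b_by_cell = {c.cell_id: c for c in calls_b}
    shared = sorted(set(a_by_cell) & set(b_by_cell))
    if not shared:
        raise ValueError("no overlapping cells between the two call sets")
    lags = []
    n_missing_a = sum(1 for c in calls_a if c.t_onset is None)
    n_missing_b = sum(1 for c in calls_b if c.t_onset is None)
    for cid in shared:
        ta, tb = a_by_cell[cid].t_onset, b_by_cell[cid].t_onset
        if ta is not None and tb is not None:
            lags.append(tb - ta)
    if not lags:
        raise ValueError("no cell has onsets in both channels")
    lags = np.asarray(lags)
    t_a = [c.t_onset for c in calls_a if c.t_onset is not None]
    t_b = [c.t_onset for c in calls_b if c.t_onset is not None]
    channel_a = calls_a[0].channel if calls_a else "a"
    channel_b = calls_b[0].channel if calls_b else "b"
    return LagEstimate(channel_pair=(channel_a, channel_b),
                       per_cell_lags=lags,
                       mean_lag=float(lags.mean()),
                       sd_lag=float(lags.std(ddof=1)) if len(lags) > 1 else 0.0,
                       n_cells=len(lags),
                       n_missing_a=n_missing_a, n_missing_b=n_missing_b,
                       cohort_difference=float(np.mean(t_b) - np.mean(t_a)))


def normalize_to_precrowding(series: np.ndarray, reference_frame: int,
                             frame_interval: float = 1.0) -> NormalizedTrace:
    """Normalize to a single pre-crowding reference measurement.

    Unlike baseline-window normalization, crowding experiments divide by one
    reference value taken before the crowding challenge.
    """
    series = np.asarray(series, dtype=float)
    if not 0 <= reference_frame < len(series):
        raise ValueError("reference frame outside the trace")
    ref = series[reference_frame]
    if ref <= 0:
        raise ValueError("non-positive reference value")
    return NormalizedTrace(values=series / ref, baseline_window=1,
                           frame_interval=frame_interval, frame_offset=0)
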