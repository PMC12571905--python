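"""Synthetic epithelial time-lapse generator with ground-truth event tables.

The generator stands in for raw monolayer microscopy: it builds a confluent
polygonal monolayer (Voronoi tessellation of blue-noise seed points with a
1-2 px phase-bright junction skeleton), samples extrusion / shrinkage /
division events with the temporal structure the analysis assumes, and renders
multi-channel movies:

``phase``
    Phase-contrast-like image: textured interiors, bright junction skeleton
    with a decaying halo.  A shrinking cell vacates a gap band inside its own
    territory whose width follows ``r_eq * (1 - (1 - loss)**(1/3))`` — the
    neighbours' bright junctions widen into the vacated footprint — so the
    suprathreshold junctional area rises in proportion to the volume lost.
    Extruding cells flash bright and vanish; dividing cells show a one-frame
    sub-threshold mitotic brightening and a sub-threshold cleavage furrow.
``volume_reporter`` / ``calcein``
    Fluorescence intensity scales linearly with instantaneous relative cell
    volume (the Calcein signal is quenched as cells lose water).
``dibac``
    Membrane-potential dye; steps up at depolarization onset.
``corona``
    Na⁺ indicator; steps up at Na⁺ entry and stays high only for extruders.
``atp``
    ATP reporter; declines linearly from the ATP-decline onset.

The event chain per shrinking cell is
``ATP decline → Na⁺ entry → depolarization → shrink onset → relaxation →
extrusion`` with configurable mean lags and truncated-Gaussian jitter
(sd = ``jitter_frac`` × mean, truncated at zero), which keeps the ordering
invariant valid by construction.

Noise is shot noise plus Gaussian read noise.  The default ``"gaussian"``
mode draws a single Gaussian deviate per pixel with
``sd = sqrt(I / photon_scale + read_noise_sd**2)`` (the large-count limit of
the Poisson model); ``"poisson"`` samples photon counts exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .io import CellROI, ImageStack, read_rois, read_stack, write_rois, write_stack

__all__ = [
    "GeneratorConfig", "ConditionSpec", "GroundTruthEvent", "MonolayerGeometry",
    "SyntheticDataset", "build_monolayer", "sample_events", "render_dataset",
    "generate_dataset", "write_dataset", "read_dataset",
    "expected_shrink_incidence", "render_volume_zstack",
    "simulate_island_phase_movie", "TRUTH_COLUMNS", "truth_to_frame",
]

FLUOR_CHANNELS = ("volume_reporter", "calcein", "dibac", "corona", "atp")
ALL_CHANNELS = ("phase",) + FLUOR_CHANNELS

# ---------------------------------------------------------------------------
# renderer calibration constants (intensity units are arbitrary camera counts)
# ---------------------------------------------------------------------------
PHASE_INTERIOR = 100.0          # mean interior level
PHASE_SPECKLE_SIGMA = 0.08      # log-sd of static interior texture
PHASE_JUNCTION = 200.0          # junction skeleton core level
PHASE_JUNCTION_JITTER = 0.15    # static +- fractional jitter on core pixels
PHASE_HALO_AMP = 70.0           # halo amplitude next to the skeleton
PHASE_HALO_SIGMA = 1.8          # halo decay length, px
PHASE_GAP_LEVEL = 320.0         # brightness of the vacated gap band
PHASE_FLASH_LEVEL = 340.0       # extrusion flash
PHASE_MITOTIC_BOOST = 40.0      # one-frame mitotic brightening (sub-threshold)
PHASE_FURROW_LEVEL = 160.0      # cleavage furrow line (sub-threshold)
FLUOR_BG = 5.0
FLUOR_LEVEL = 150.0
DIBAC_STEP = 0.40               # fractional rise at depolarization
CORONA_STEP = 0.35              # fractional rise at Na+ entry
CORONA_DECAY_TAU = 5.0          # min; Na+ decay for cells that do not extrude
ATP_DROP = 0.30                 # fractional ATP decline by chain end
GONE_FACTOR = 0.03              # fluorescence left after the cell extrudes

# analysis-window bookkeeping: the chain must fit between the 10-frame trace
# baseline and the extrusion, see sample_events
MAX_CHAIN_SPAN = 24.0           # min, ATP decline -> extrusion
T_EXT_MIN = 31.0                # min, earliest allowed extrusion
T_STAY_ONSET_MIN = 22.0         # min, earliest shrink onset without extrusion


@dataclass
class ConditionSpec:
    """Scalar modifiers a named experimental condition applies.

    ``shrink_multiplier`` scales the per-cell probability of undergoing any
    shrink event relative to the control condition; ``extrusion_factor``
    scales the extrusion rate (contractility inhibitors block extrusion while
    increasing shrinkage, so the contractility-inhibited condition pairs a
    23x shrink multiplier with a zero extrusion factor).
    """

    shrink_multiplier: float = 1.0
    extrusion_factor: float = 1.0


DEFAULT_CONDITIONS: dict[str, ConditionSpec] = {
    "control": ConditionSpec(1.0, 1.0),
    "contractility_inhibited": ConditionSpec(23.0, 0.0),
    "hypertonic": ConditionSpec(8.0, 2.0),
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic monolayer experiment.

    Defaults encode the measured event structure: ~70% of live-cell
    extrusions are preceded by homeostatic early shrinkage lasting ~6.5 min,
    shrinkage is rare (~3%) before apoptotic extrusion, extruders lose
    20 ± 3% of their volume while non-extruding shrinkers lose 11 ± 2.5%,
    depolarization leads the shrink onset by ~5 min and Na⁺ entry leads
    depolarization by 2.4 min.  The ATP-decline lead and all purely optical
    amplitudes are generator choices (documented in the methods note).
    """

    n_cells: int = 38
    frame_interval: float = 0.5           # min/frame
    n_frames: int = 300                   # 2.5 h movie
    pixel_size: float = 0.2125            # µm/px (400 px = 85 µm window)
    image_size: tuple[int, int] = (256, 256)
    seed: int = 0
    p_hes_given_lce: float = 0.70
    p_shrink_given_apoptotic: float = 0.03
    p_shrink_no_extrude: float = 8.0 / 750.0
    shrink_duration_mean: float = 6.5     # min
    shrink_duration_sd: float = 1.5       # min
    relax_to_extrusion_mean: float = 1.5  # min
    vol_loss_extrude_mean: float = 20.0   # percent
    vol_loss_extrude_sd: float = 3.0
    vol_loss_stay_mean: float = 11.0
    vol_loss_stay_sd: float = 2.5
    lag_na_to_depol: float = 2.4          # min
    lag_depol_to_shrink: float = 5.0      # min
    lag_atp_to_na: float = 3.0            # min (not printed; generator choice)
    jitter_frac: float = 0.20             # lag sd as a fraction of the mean
    extrusion_rate: float = 18.0          # events per 1,000 cells per hour
    apoptotic_fraction: float = 0.25      # fraction of extrusions
    division_rate: float = 8.0            # events per 1,000 cells per hour
    condition_multipliers: dict[str, float] = field(
        default_factory=lambda: {name: spec.shrink_multiplier
                                 for name, spec in DEFAULT_CONDITIONS.items()})
    condition_extrusion_factors: dict[str, float] = field(
        default_factory=lambda: {name: spec.extrusion_factor
                                 for name, spec in DEFAULT_CONDITIONS.items()})
    phase_photon_scale: float = 20000.0   # photons per intensity unit
    fluor_photon_scale: float = 2.0
    read_noise_sd: float = 0.1            # intensity units
    noise_model: str = "gaussian"         # "gaussian" | "poisson" | "none"

    def __post_init__(self) -> None:
        probs = [self.p_hes_given_lce, self.p_shrink_given_apoptotic,
                 self.p_shrink_no_extrude, self.apoptotic_fraction]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        durations = [self.frame_interval, self.shrink_duration_mean,
                     self.relax_to_extrusion_mean, self.lag_na_to_depol,
                     self.lag_depol_to_shrink, self.lag_atp_to_na]
        if any(d <= 0 for d in durations):
            raise ValueError("durations and lags must be positive")
        if self.shrink_duration_sd < 0 or self.vol_loss_extrude_sd < 0 \
                or self.vol_loss_stay_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.vol_loss_extrude_mean <= self.vol_loss_stay_mean:
            raise ValueError("extruder volume loss must exceed "
                             "non-extruder volume loss")
        if self.extrusion_rate < 0 or self.division_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_cells < 4:
            raise ValueError("need at least 4 cells")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        h, w = self.image_size
        if h * w / self.n_cells < 50:
            raise ValueError("image too small: mean cell area < 50 px")

    @property
    def movie_end(self) -> float:
        """Time of the last frame, minutes."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def hours(self) -> float:
        return self.movie_end / 60.0

    def condition(self, name: str) -> ConditionSpec:
        if name not in self.condition_multipliers:
            raise KeyError(f"unknown condition {name!r}")
        return ConditionSpec(
            self.condition_multipliers[name],
            self.condition_extrusion_factors.get(name, 1.0))


@dataclass
class GroundTruthEvent:
    """True event times (minutes) and magnitudes for one cell.

    Absent times are ``None``.  When all chain times are present they obey
    ``t_atp_decline < t_na_entry < t_depol < t_shrink_onset < t_extrusion``
    and ``t_relaxation`` lies in ``(t_shrink_onset, t_extrusion]``.
    """

    cell_id: int
    event_class: str                     # LCE | apoptotic_extrusion | division | none
    has_shrink: bool = False
    t_atp_decline: float | None = None
    t_na_entry: float | None = None
    t_depol: float | None = None
    t_shrink_onset: float | None = None
    t_relaxation: float | None = None
    t_extrusion: float | None = None
    t_division: float | None = None
    true_vol_loss: float | None = None   # percent

    def __post_init__(self) -> None:
        if self.event_class not in ("LCE", "apoptotic_extrusion",
                                    "division", "none"):
            raise ValueError(f"bad event class {self.event_class!r}")
        chain = [self.t_atp_decline, self.t_na_entry, self.t_depol,
                 self.t_shrink_onset]
        present = [t for t in chain if t is not None]
        if any(a >= b for a, b in zip(present, present[1:])):
            raise ValueError("event chain times out of order")
        if self.t_shrink_onset is not None and self.t_relaxation is not None:
            if not self.t_shrink_onset < self.t_relaxation:
                raise ValueError("relaxation must follow shrink onset")
            if self.t_extrusion is not None \
                    and self.t_relaxation > self.t_extrusion:
                raise ValueError("relaxation must not follow extrusion")
        if self.t_extrusion is not None and self.t_shrink_onset is not None \
                and not self.t_shrink_onset < self.t_extrusion:
            raise ValueError("shrink onset must precede extrusion")
        if self.true_vol_loss is not None and self.true_vol_loss < 0:
            raise ValueError("volume loss must be non-negative")

    @property
    def extrudes(self) -> bool:
        return self.event_class in ("LCE", "apoptotic_extrusion")


TRUTH_COLUMNS = ["cell_id", "event_class", "has_shrink", "t_atp_decline",
                 "t_na_entry", "t_depol", "t_shrink_onset", "t_relaxation",
                 "t_extrusion", "t_division", "true_vol_loss"]


def truth_to_frame(truth: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    rows = [{c: getattr(ev, c) for c in TRUTH_COLUMNS} for ev in truth]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def truth_from_frame(df: pd.DataFrame) -> list[GroundTruthEvent]:
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for c in TRUTH_COLUMNS:
            v = row[c]
            if c == "cell_id":
                v = int(v)
            elif c == "event_class":
                v = str(v)
            elif c == "has_shrink":
                v = bool(v)
            else:
                v = None if pd.isna(v) else float(v)
            kwargs[c] = v
        out.append(GroundTruthEvent(**kwargs))
    return out


# ---------------------------------------------------------------------------
# monolayer geometry
# ---------------------------------------------------------------------------

@dataclass
class MonolayerGeometry:
    """Voronoi monolayer: full partition, junction skeleton and ROIs.

    ``territory_map`` assigns every pixel to exactly one cell (labels 1..n);
    ``label_map`` is the same partition with the 1-2 px junction skeleton
    carved out as label 0.
    """

    territory_map: np.ndarray
    label_map: np.ndarray
    junction_mask: np.ndarray
    seeds_yx: np.ndarray
    rois: list[CellROI]

    @property
    def n_cells(self) -> int:
        return int(self.territory_map.max())

    def cell_mask(self, cell_id: int) -> np.ndarray:
        return self.territory_map == cell_id


def _blue_noise_points(rng: np.random.Generator, n: int,
                       shape: tuple[int, int]) -> np.ndarray:
    """Dart-throwing blue-noise sampling: n points with a minimum spacing."""
    h, w = shape
    r_min = 0.55 * np.sqrt(h * w / n)
    for attempt in range(8):
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < n and tries < 4000 * n:
            p = rng.uniform((1.0, 1.0), (h - 1.0, w - 1.0))
            if all(np.hypot(*(p - q)) >= r_min for q in pts):
                pts.append(p)
            tries += 1
        if len(pts) == n:
            arr = np.asarray(pts)
            if len(np.unique(arr.round(6), axis=0)) == n:
                return arr
        r_min *= 0.85  # relax spacing and retry with perturbed sampling
    raise RuntimeError("could not place monolayer seed points; "
                       "degenerate geometry after bounded retries")


def build_monolayer(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> MonolayerGeometry:
    """Tessellate the field into ``n_cells`` polygonal cells.

    Deterministic for a fixed config seed.  Every pixel belongs to exactly
    one cell territory; the junction skeleton (1-2 px, label 0 in
    ``label_map``) runs along territory boundaries.
    """
    rng = rng or np.random.default_rng([config.seed, 0])
    h, w = config.image_size
    pts = _blue_noise_points(rng, config.n_cells, (h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    _, idx = cKDTree(pts).query(grid)
    territory = (idx.reshape(h, w) + 1).astype(np.int32)
    junction = find_boundaries(territory, mode="thick")
    label_map = np.where(junction, 0, territory).astype(np.int32)
    rois = []
    for cid in range(1, config.n_cells + 1):
        mask = territory == cid
        ys, xs = np.nonzero(mask)
        rois.append(CellROI(
            cell_id=cid, frame_first=0, frame_last=config.n_frames - 1,
            x_min=int(xs.min()), y_min=int(ys.min()),
            x_max=int(xs.max()) + 1, y_max=int(ys.max()) + 1,
            centroid_x=float(xs.mean()), centroid_y=float(ys.mean())))
    return MonolayerGeometry(territory_map=territory, label_map=label_map,
                             junction_mask=junction, seeds_yx=pts, rois=rois)


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0) -> float:
    """One truncated-Gaussian draw (rejection; falls back to the bound)."""
    if sd == 0:
        return max(mean, low)
    for _ in range(200):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    return max(low + sd * 1e-3, low * 1.001)


def expected_shrink_incidence(config: GeneratorConfig,
                              condition: str = "control") -> float:
    """Analytic per-cell probability of any shrink event under a condition."""
    spec = config.condition(condition)
    p_ext0 = config.extrusion_rate * config.hours / 1000.0
    linked0 = p_ext0 * ((1 - config.apoptotic_fraction) * config.p_hes_given_lce
                        + config.apoptotic_fraction
                        * config.p_shrink_given_apoptotic)
    p_control = linked0 + config.p_shrink_no_extrude
    linked_c = spec.extrusion_factor * linked0
    q_bg = np.clip(spec.shrink_multiplier * p_control - linked_c, 0.0, 0.98)
    return float(linked_c + q_bg)


def _background_shrink_prob(config: GeneratorConfig, condition: str) -> float:
    spec = config.condition(condition)
    p_ext0 = config.extrusion_rate * config.hours / 1000.0
    linked0 = p_ext0 * ((1 - config.apoptotic_fraction) * config.p_hes_given_lce
                        + config.apoptotic_fraction
                        * config.p_shrink_given_apoptotic)
    p_control = linked0 + config.p_shrink_no_extrude
    linked_c = spec.extrusion_factor * linked0
    return float(np.clip(spec.shrink_multiplier * p_control - linked_c,
                         0.0, 0.98))


def _sample_chain(rng: np.random.Generator, config: GeneratorConfig
                  ) -> dict[str, float]:
    """Draw one jittered shrink/extrusion chain (spans, not absolute times).

    Chains whose full ATP→extrusion span exceeds ``MAX_CHAIN_SPAN`` are
    resampled so the 10-frame trace baseline always precedes the chain.
    """
    j = config.jitter_frac
    for _ in range(100):
        dur = _truncated_normal(rng, config.shrink_duration_mean,
                                config.shrink_duration_sd,
                                low=max(2 * config.frame_interval, 1.0))
        post = _truncated_normal(rng, config.relax_to_extrusion_mean,
                                 j * config.relax_to_extrusion_mean, low=0.5)
        lag_d = _truncated_normal(rng, config.lag_depol_to_shrink,
                                  j * config.lag_depol_to_shrink, low=0.5)
        lag_n = _truncated_normal(rng, config.lag_na_to_depol,
                                  j * config.lag_na_to_depol, low=0.3)
        lag_a = _truncated_normal(rng, config.lag_atp_to_na,
                                  j * config.lag_atp_to_na, low=0.5)
        if dur + post + lag_d + lag_n + lag_a <= MAX_CHAIN_SPAN:
            return {"dur": dur, "post": post, "lag_depol": lag_d,
                    "lag_na": lag_n, "lag_atp": lag_a}
    raise RuntimeError("could not draw a chain within the movie span")


def _vol_loss(rng: np.random.Generator, config: GeneratorConfig,
              extruder: bool) -> float:
    if extruder:
        return _truncated_normal(rng, config.vol_loss_extrude_mean,
                                 config.vol_loss_extrude_sd, low=3.0)
    return _truncated_normal(rng, config.vol_loss_stay_mean,
                             config.vol_loss_stay_sd, low=3.0)


def sample_events(config: GeneratorConfig, rois: Sequence[CellROI],
                  condition: str = "control",
                  rng: np.random.Generator | None = None
                  ) -> list[GroundTruthEvent]:
    """Sample ground-truth events for every cell.

    Extrusions occur at ``extrusion_rate`` (scaled by the condition's
    extrusion factor); live-cell extrusions shrink with probability
    ``p_hes_given_lce`` and apoptotic ones with ``p_shrink_given_apoptotic``.
    Cells may instead shrink without extruding (probability set by the
    condition's shrink multiplier) or divide.  Event times are chained by the
    configured lags plus truncated-Gaussian jitter; events that cannot fit in
    the movie span raise an error naming the minimum span.
    """
    rng = rng or np.random.default_rng([config.seed, 1])
    spec = config.condition(condition)
    p_ext = config.extrusion_rate * config.hours / 1000.0 * spec.extrusion_factor
    q_bg = _background_shrink_prob(config, condition)
    p_div = config.division_rate * config.hours / 1000.0
    if p_ext + q_bg + p_div > 1.0:
        raise ValueError("event probabilities exceed 1; lower the rates")

    end = config.movie_end
    t_ext_max = end - max(2 * config.frame_interval, 1.5)
    min_span = T_EXT_MIN + max(2 * config.frame_interval, 1.5)
    if t_ext_max <= T_EXT_MIN and (p_ext > 0):
        raise ValueError(
            f"movie too short for the event chain: needs at least "
            f"{min_span:.1f} min, got {end:.1f} min")

    events: list[GroundTruthEvent] = []
    for roi in rois:
        u = rng.random()
        if u < p_ext:
            apoptotic = rng.random() < config.apoptotic_fraction
            klass = "apoptotic_extrusion" if apoptotic else "LCE"
            p_shrink = (config.p_shrink_given_apoptotic if apoptotic
                        else config.p_hes_given_lce)
            shrink = rng.random() < p_shrink
            t_ext = rng.uniform(T_EXT_MIN, t_ext_max)
            if shrink:
                ch = _sample_chain(rng, config)
                t_rel = t_ext - ch["post"]
                t_on = t_rel - ch["dur"]
                t_dep = t_on - ch["lag_depol"]
                t_na = t_dep - ch["lag_na"]
                t_atp = t_na - ch["lag_atp"]
                events.append(GroundTruthEvent(
                    cell_id=roi.cell_id, event_class=klass, has_shrink=True,
                    t_atp_decline=t_atp, t_na_entry=t_na, t_depol=t_dep,
                    t_shrink_onset=t_on, t_relaxation=t_rel, t_extrusion=t_ext,
                    true_vol_loss=_vol_loss(rng, config, extruder=True)))
            else:
                events.append(GroundTruthEvent(
                    cell_id=roi.cell_id, event_class=klass, has_shrink=False,
                    t_extrusion=t_ext))
        elif u < p_ext + q_bg:
            # shrink without extrusion
            ch = _sample_chain(rng, config)
            t_on_max = end - ch["dur"] - 12.0
            if t_on_max <= T_STAY_ONSET_MIN:
                raise ValueError(
                    f"movie too short for a non-extruding shrink event: needs "
                    f"at least {T_STAY_ONSET_MIN + ch['dur'] + 12.0:.1f} min, "
                    f"got {end:.1f} min")
            t_on = rng.uniform(T_STAY_ONSET_MIN, t_on_max)
            t_rel = t_on + ch["dur"]
            t_dep = t_on - ch["lag_depol"]
            t_na = t_dep - ch["lag_na"]
            t_atp = t_na - ch["lag_atp"]
            events.append(GroundTruthEvent(
                cell_id=roi.cell_id, event_class="none", has_shrink=True,
                t_atp_decline=t_atp, t_na_entry=t_na, t_depol=t_dep,
                t_shrink_onset=t_on, t_relaxation=t_rel,
                true_vol_loss=_vol_loss(rng, config, extruder=False)))
        elif u < p_ext + q_bg + p_div:
            if end < 30.0:
                raise ValueError("movie too short for a division event: "
                                 f"needs at least 30.0 min, got {end:.1f}")
            events.append(GroundTruthEvent(
                cell_id=roi.cell_id, event_class="division",
                t_division=rng.uniform(15.0, end - 10.0)))
    return events


def apply_events_to_rois(rois: Sequence[CellROI],
                         truth: Sequence[GroundTruthEvent],
                         config: GeneratorConfig) -> list[CellROI]:
    """Set ``frame_last`` of extruding cells to the observed extrusion frame."""
    by_cell = {ev.cell_id: ev for ev in truth}
    out = []
    for roi in rois:
        roi = dataclasses.replace(roi)
        ev = by_cell.get(roi.cell_id)
        if ev is not None and ev.t_extrusion is not None:
            roi.frame_last = int(np.ceil(ev.t_extrusion
                                         / config.frame_interval - 1e-9))
        out.append(roi)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Rendered channels plus geometry and ground truth for one field."""

    config: GeneratorConfig
    condition: str
    channels: dict[str, ImageStack]
    rois: list[CellROI]
    truth: list[GroundTruthEvent]
    territory_map: np.ndarray
    label_map: np.ndarray

    def __post_init__(self) -> None:
        shapes = {ch: s.data.shape[0] for ch, s in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels disagree on frame count: {shapes}")
        roi_ids = {r.cell_id for r in self.rois}
        for ev in self.truth:
            if ev.cell_id not in roi_ids:
                raise ValueError(f"truth references unknown cell {ev.cell_id}")

    @property
    def n_cells(self) -> int:
        return len(self.rois)


def _frame_at(t: float, dt: float) -> int:
    return int(np.ceil(t / dt - 1e-9))


def _apply_noise(rng: np.random.Generator, clean: np.ndarray,
                 photon_scale: float, read_sd: float, model: str) -> np.ndarray:
    if model == "none":
        return clean
    if model == "poisson":
        out = rng.poisson(np.maximum(clean, 0) * photon_scale
                          ).astype(np.float32) / photon_scale
        if read_sd > 0:
            out += rng.normal(0.0, read_sd, size=clean.shape).astype(np.float32)
        return np.maximum(out, 0.0)
    # shot + read noise in one Gaussian draw; in-place f32 to keep the
    # per-frame cost dominated by the RNG, not temporaries
    sigma = clean * np.float32(1.0 / photon_scale)
    sigma += np.float32(read_sd ** 2)
    np.sqrt(sigma, out=sigma)
    noise = rng.standard_normal(clean.shape, dtype=np.float32)
    noise *= sigma
    noise += clean
    return np.maximum(noise, 0.0, out=noise)


def _gap_profile(frame: int, f_on: int, f_rel: int) -> float:
    """Fractional gap opening: fast strictly-increasing rise, plateau, close."""
    if frame < f_on or frame >= f_rel:
        return 0.0
    if frame == f_on:
        return 0.7
    if frame == f_on + 1:
        return 0.9
    return 1.0


def _render_phase(config: GeneratorConfig, geom: MonolayerGeometry,
                  truth: Sequence[GroundTruthEvent],
                  rng_static: np.random.Generator,
                  rng_noise: np.random.Generator) -> np.ndarray:
    h, w = config.image_size
    dt = config.frame_interval
    junction = geom.junction_mask
    # static textures
    speckle = np.exp(rng_static.normal(0.0, PHASE_SPECKLE_SIGMA,
                                       size=(h, w))).astype(np.float32)
    core_jitter = rng_static.uniform(1 - PHASE_JUNCTION_JITTER,
                                     1 + PHASE_JUNCTION_JITTER,
                                     size=(h, w)).astype(np.float32)
    halo_jitter = rng_static.uniform(0.75, 1.25, size=(h, w)).astype(np.float32)
    depth_dither = rng_static.uniform(0.0, 0.5, size=(h, w)).astype(np.float32)

    d_junction = ndimage.distance_transform_edt(~junction)
    halo = (PHASE_HALO_AMP
            * np.exp(-d_junction ** 2 / (2 * PHASE_HALO_SIGMA ** 2))
            * halo_jitter).astype(np.float32)
    base = np.where(junction, PHASE_JUNCTION * core_jitter,
                    PHASE_INTERIOR * speckle + halo).astype(np.float32)

    stack = np.empty((config.n_frames, h, w), dtype=np.float32)
    stack[:] = base

    sealed = np.float32(PHASE_INTERIOR)
    for ev in truth:
        mask = geom.territory_map == ev.cell_id
        ys, xs = np.nonzero(mask)
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        m = mask[sl]
        if ev.has_shrink:
            # inward distance from the cell's own boundary, with a static
            # sub-pixel dither so the gap area responds smoothly to width
            d_in = ndimage.distance_transform_edt(m) + depth_dither[sl]
            loss = ev.true_vol_loss / 100.0
            r_eq = np.sqrt(m.sum() / np.pi)
            f_on = _frame_at(ev.t_shrink_onset, dt)
            f_rel = _frame_at(ev.t_relaxation, dt)
            gap_level = np.float32(
                PHASE_GAP_LEVEL * (0.95 + 0.1 * float(rng_static.random())))
            for f in range(f_on, min(f_rel, config.n_frames)):
                p = _gap_profile(f, f_on, f_rel)
                width = r_eq * (1.0 - (1.0 - loss * p) ** (1.0 / 3.0))
                band = m & (d_in < 1.5 + width)
                stack[f][sl][band] = gap_level
        if ev.t_extrusion is not None:
            f_ext = _frame_at(ev.t_extrusion, dt)
            for f in range(f_ext, min(f_ext + 2, config.n_frames)):
                stack[f][sl][m] = PHASE_FLASH_LEVEL
            if f_ext + 2 < config.n_frames:
                stack[f_ext + 2:, sl[0], sl[1]][:, m] = sealed
        if ev.event_class == "division":
            f_div = _frame_at(ev.t_division, dt)
            if f_div < config.n_frames:
                frame = stack[f_div]
                frame[sl][m] = np.minimum(
                    frame[sl][m] + PHASE_MITOTIC_BOOST, PHASE_FURROW_LEVEL + 20)
            # cleavage furrow: a sub-threshold line through the centroid
            cy, cx = ys.mean(), xs.mean()
            theta = float(rng_static.uniform(0, np.pi))
            t_axis = np.arange(-max(h, w), max(h, w), 0.5)
            fy = np.round(cy + t_axis * np.sin(theta)).astype(int)
            fx = np.round(cx + t_axis * np.cos(theta)).astype(int)
            ok = (fy >= 0) & (fy < h) & (fx >= 0) & (fx < w)
            fy, fx = fy[ok], fx[ok]
            inside = mask[fy, fx]
            fy, fx = fy[inside], fx[inside]
            if f_div + 1 < config.n_frames and len(fy):
                stack[f_div + 1:, fy, fx] = PHASE_FURROW_LEVEL
    return _apply_noise(rng_noise, stack, config.phase_photon_scale,
                        config.read_noise_sd, config.noise_model)


def _volume_factor(times: np.ndarray, ev: GroundTruthEvent,
                   extruder: bool) -> np.ndarray:
    """Relative cell volume over time for a shrinking cell.

    Declines linearly from the shrink onset, holds a trough plateau, and
    either stays low until extrusion or recovers over ~10 min for cells that
    remain in the layer.
    """
    loss = ev.true_vol_loss / 100.0
    t_on, t_rel = ev.t_shrink_onset, ev.t_relaxation
    t_trough = t_on + 0.45 * (t_rel - t_on)
    if extruder:
        xp = [times[0], t_on, t_trough, times[-1]]
        fp = [1.0, 1.0, 1.0 - loss, 1.0 - loss]
    else:
        xp = [times[0], t_on, t_trough, t_rel, t_rel + 10.0, times[-1]]
        fp = [1.0, 1.0, 1.0 - loss, 1.0 - loss, 1.0, 1.0]
    xp = np.maximum.accumulate(np.asarray(xp, dtype=float))
    return np.interp(times, xp, fp)


def _channel_factors(config: GeneratorConfig, channel: str,
                     truth: Sequence[GroundTruthEvent]) -> np.ndarray:
    """Per-frame intensity factor for each cell, shape (T, n_cells + 1)."""
    T = config.n_frames
    times = np.arange(T) * config.frame_interval
    F = np.ones((T, config.n_cells + 1), dtype=np.float32)
    F[:, 0] = 1.0  # junction/background column scales FLUOR_BG
    for ev in truth:
        col = ev.cell_id
        fac = np.ones(T)
        if ev.has_shrink and channel in ("volume_reporter", "calcein"):
            fac = _volume_factor(times, ev, extruder=ev.extrudes)
        elif ev.has_shrink and channel == "dibac":
            fac = 1.0 + DIBAC_STEP * (times >= ev.t_depol)
        elif ev.has_shrink and channel == "corona":
            step = CORONA_STEP * (times >= ev.t_na_entry).astype(float)
            if not ev.extrudes:
                after = times >= ev.t_relaxation
                step[after] *= np.exp(-(times[after] - ev.t_relaxation)
                                      / CORONA_DECAY_TAU)
            fac = 1.0 + step
        elif ev.has_shrink and channel == "atp":
            t_end = ev.t_extrusion if ev.extrudes else ev.t_relaxation
            ramp = np.clip((times - ev.t_atp_decline)
                           / max(t_end - ev.t_atp_decline, 1e-6), 0.0, 1.0)
            fac = 1.0 - ATP_DROP * ramp
        if ev.t_extrusion is not None:
            f_ext = _frame_at(ev.t_extrusion, config.frame_interval)
            fac = fac.copy()
            fac[min(f_ext + 2, T):] = GONE_FACTOR
        F[:, col] = fac
    return F


def _render_fluorescence(config: GeneratorConfig, geom: MonolayerGeometry,
                         truth: Sequence[GroundTruthEvent], channel: str,
                         rng_static: np.random.Generator,
                         rng_noise: np.random.Generator) -> np.ndarray:
    levels = np.empty(config.n_cells + 1, dtype=np.float32)
    levels[0] = FLUOR_BG
    levels[1:] = FLUOR_LEVEL * rng_static.uniform(0.8, 1.2,
                                                  size=config.n_cells)
    factors = _channel_factors(config, channel, truth)
    per_frame = (levels[None, :] * factors).astype(np.float32)
    stack = per_frame[:, geom.label_map]  # (T, H, W); junction px -> column 0
    return _apply_noise(rng_noise, stack, config.fluor_photon_scale,
                        config.read_noise_sd, config.noise_model)


def render_dataset(config: GeneratorConfig,
                   geometry: MonolayerGeometry,
                   truth: Sequence[GroundTruthEvent],
                   channels: Sequence[str] = ("phase",),
                   condition: str = "control") -> SyntheticDataset:
    """Render the requested channels; fully reproducible per config seed.

    Each channel's pixel stream is seeded independently of which other
    channels are requested, so rendering a subset leaves the rest unchanged.
    """
    for ch in channels:
        if ch not in ALL_CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
        if ch in ("dibac", "corona", "atp", "volume_reporter", "calcein"):
            needed = {"dibac": "t_depol", "corona": "t_na_entry",
                      "atp": "t_atp_decline",
                      "volume_reporter": "t_shrink_onset",
                      "calcein": "t_shrink_onset"}[ch]
            for ev in truth:
                if ev.has_shrink and getattr(ev, needed) is None:
                    raise ValueError(
                        f"channel {ch!r} requested but event for cell "
                        f"{ev.cell_id} lacks {needed}")
    out: dict[str, ImageStack] = {}
    for ch in channels:
        ci = ALL_CHANNELS.index(ch)
        rng_static = np.random.default_rng([config.seed, 2, ci])
        rng_noise = np.random.default_rng([config.seed, 3, ci])
        if ch == "phase":
            data = _render_phase(config, geometry, truth, rng_static, rng_noise)
        else:
            data = _render_fluorescence(config, geometry, truth, ch,
                                        rng_static, rng_noise)
        out[ch] = ImageStack(data=data, pixel_size=config.pixel_size,
                             frame_interval=config.frame_interval, channel=ch)
    rois = apply_events_to_rois(geometry.rois, truth, config)
    return SyntheticDataset(config=config, condition=condition, channels=out,
                            rois=rois, truth=list(truth),
                            territory_map=geometry.territory_map,
                            label_map=geometry.label_map)


def generate_dataset(config: GeneratorConfig,
                     channels: Sequence[str] = ("phase",),
                     condition: str = "control") -> SyntheticDataset:
    """Build the monolayer, sample events and render in one call."""
    geom = build_monolayer(config)
    truth = sample_events(config, geom.rois, condition=condition)
    return render_dataset(config, geom, truth, channels=channels,
                          condition=condition)


# ---------------------------------------------------------------------------
# dataset round-trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write one OME-TIFF per channel plus rois.csv, truth.csv and config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, stack in dataset.channels.items():
        write_stack(directory / f"{name}.ome.tif", stack)
    tifffile.imwrite(directory / "territory_map.tif",
                     dataset.territory_map.astype(np.uint16))
    tifffile.imwrite(directory / "label_map.tif",
                     dataset.label_map.astype(np.uint16))
    write_rois(directory / "rois.csv", dataset.rois)
    truth_to_frame(dataset.truth).to_csv(directory / "truth.csv", index=False)
    cfg = dataclasses.asdict(dataset.config)
    cfg["image_size"] = list(cfg["image_size"])
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump({"condition": dataset.condition, "config": cfg}, fh)
    return directory


def read_dataset(directory: str | Path) -> SyntheticDataset:
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        doc = yaml.safe_load(fh)
    cfg_dict = doc["config"]
    cfg_dict["image_size"] = tuple(cfg_dict["image_size"])
    config = GeneratorConfig(**cfg_dict)
    channels = {}
    for path in sorted(directory.glob("*.ome.tif")):
        name = path.name.replace(".ome.tif", "")
        channels[name] = read_stack(path, channel=name)
    territory = tifffile.imread(directory / "territory_map.tif").astype(np.int32)
    label_map = tifffile.imread(directory / "label_map.tif").astype(np.int32)
    rois = read_rois(directory / "rois.csv")
    truth = truth_from_frame(pd.read_csv(directory / "truth.csv"))
    return SyntheticDataset(config=config, condition=doc["condition"],
                            channels=channels, rois=rois, truth=truth,
                            territory_map=territory, label_map=label_map)


# ---------------------------------------------------------------------------
# auxiliary synthetic objects for the volumetric and QPI pipelines
# ---------------------------------------------------------------------------

def render_volume_zstack(volume_factors: Sequence[float],
                         radius_px: int = 12, n_z: int = 30,
                         base_height_um: float = 8.0,
                         pixel_size: float = 0.2125, z_step: float = 0.4,
                         intensity: float = 1000.0, background: float = 50.0,
                         noise_sd: float = 0.0, seed: int = 0
                         ) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Render a columnar cell as a shrinking cylinder in a TZYX stack.

    Returns the stack, the (Y, X) footprint mask and the exact ground-truth
    volume per frame in µm³ (voxel count × voxel volume, so an exhaustive
    voxel-counting oracle can reproduce it bit-exactly in the noiseless
    case).
    """
    rng = np.random.default_rng(seed)
    side = 2 * radius_px + 5
    yy, xx = np.mgrid[0:side, 0:side]
    disk = (yy - side // 2) ** 2 + (xx - side // 2) ** 2 <= radius_px ** 2
    voxel_vol = pixel_size * pixel_size * z_step
    T = len(volume_factors)
    stack = np.full((T, n_z, side, side), background, dtype=np.float32)
    true_volumes = np.empty(T)
    for t, v in enumerate(volume_factors):
        n_filled = max(1, int(round(base_height_um * v / z_step)))
        n_filled = min(n_filled, n_z)
        stack[t, :n_filled][:, disk] = intensity
        true_volumes[t] = disk.sum() * n_filled * voxel_vol
    if noise_sd > 0:
        stack = stack + rng.normal(0, noise_sd, stack.shape).astype(np.float32)
    return (ImageStack(data=stack, pixel_size=pixel_size, frame_interval=1.0,
                       z_step=z_step, channel="volume_reporter"),
            disk, true_volumes)


def simulate_island_phase_movie(n_cells: int = 12, n_frames: int = 40,
                                frame_interval: float = 4.0,
                                pixel_size: float = 0.5,
                                image_size: tuple[int, int] = (160, 160),
                                divider_fraction: float = 0.4,
                                growth_rate: float = 0.10,
                                base_phase: float = 0.6,
                                background_drift: float = 0.05,
                                noise_sd: float = 0.01, seed: int = 0):
    """Simulate a quantitative-phase movie of a small cell island.

    Cells marked as pre-division grow in dry mass (phase scales up at
    ``growth_rate`` per hour); pre-extrusion cells hold constant mass.  The
    field outside the island is empty space whose per-frame additive offset
    drifts, which the background-correction step must remove.  Returns the
    phase stack (radians), the per-cell label map, the empty-space mask and
    a DataFrame with each cell's true class.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    cy, cx = h / 2, w / 2
    island_r = min(h, w) * 0.30
    angles = np.linspace(0, 2 * np.pi, n_cells, endpoint=False)
    radii = island_r * np.sqrt(rng.uniform(0.05, 0.9, n_cells))
    pts = np.column_stack([cy + radii * np.sin(angles),
                           cx + radii * np.cos(angles)])
    yy, xx = np.mgrid[0:h, 0:w]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= island_r ** 2
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    _, idx = cKDTree(pts).query(grid)
    labels = np.where(inside, idx.reshape(h, w) + 1, 0).astype(np.int32)
    empty_mask = ~inside

    is_divider = rng.random(n_cells) < divider_fraction
    levels = base_phase * rng.uniform(0.8, 1.2, n_cells)
    hours = np.arange(n_frames) * frame_interval / 60.0
    stack = np.empty((n_frames, h, w), dtype=np.float32)
    for t in range(n_frames):
        lut = np.empty(n_cells + 1, dtype=np.float32)
        lut[0] = 0.0
        growth = np.where(is_divider, 1.0 + growth_rate * hours[t], 1.0)
        lut[1:] = levels * growth
        frame = lut[labels]
        frame += background_drift * np.sin(2 * np.pi * t / max(n_frames, 1))
        stack[t] = frame
    if noise_sd > 0:
        stack = stack + rng.normal(0, noise_sd, stack.shape).astype(np.float32)
    classes = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "true_class": np.where(is_divider, "increasing", "flat"),
    })
    return (ImageStack(data=stack, pixel_size=pixel_size,
                       frame_interval=frame_interval, channel="qpi"),
            labels, empty_mask, classes)
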