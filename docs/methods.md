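# Methods

## Scientific setting

Epithelial monolayers eliminate live cells by extrusion to keep cell density
homeostatic. Before most live-cell extrusions (LCE) the doomed cell undergoes
a brief volume loss — homeostatic early shrinkage (HES) — visible in
phase-contrast movies as a transient brightening of the junctional region
around the cell. The shrinkage is driven by an ionic chain: ATP decline →
retained Na⁺ entry → membrane depolarization → K⁺/Cl⁻ efflux and water loss →
shrinkage → extrusion. `hesquant` implements the measurement side of this
biology: the lightning assay that detects and times HES, volumetric readouts
of the shrinkage magnitude, fluorescence-trace kinetics for the ionic chain,
QPI dry-mass trajectories, and cohort statistics — plus a synthetic
time-lapse generator that encodes the event structure so the whole pipeline
can be validated by parameter recovery.

## Synthetic scene generator

One *field* is a confluent monolayer movie: a Voronoi tessellation of
blue-noise (dart-throwing) seed points, a 1–2 px phase-bright junction
skeleton along territory boundaries, textured cell interiors, and a halo
decaying away from the skeleton. A synthetic *experiment* is a set of
independently seeded fields, mirroring multi-position acquisition.

Default study conditions (per field): 38 cells on a 256×256 px grid at
0.2125 µm/px (≈10 µm cells), 300 frames at 0.5 min/frame (2.5 h). Event
model defaults:

| parameter | default | origin |
|---|---|---|
| P(HES before LCE) | 0.70 | reported incidence (~70%) |
| P(shrink before apoptotic extrusion) | 0.03 | reported (~3%) |
| shrink duration | 6.5 ± 1.5 min | reported ~6.5 min; spread is a generator choice |
| volume loss, extruders | 20 ± 3 % | reported |
| volume loss, non-extruders | 11 ± 2.5 % | reported |
| depolarization → shrink onset | 5.0 min | reported ~5 min |
| Na⁺ entry → depolarization | 2.4 min | reported |
| ATP decline → Na⁺ entry | 3.0 min | not quantified in the source; generator choice |
| extrusion rate | 18 per 1,000 cells/h | a crowded-monolayer turnover rate, chosen so a field of view contains events at a workable density |
| apoptotic fraction of extrusions | 0.25 | within the reported 20–30% steady-state range |
| shrink-without-extrusion probability | 8/750 ≈ 1.07% | reported count (8 of 750 cells); the accompanying "<0.03%" figure is arithmetically inconsistent with it and both are surfaced, never reconciled |
| relaxation → extrusion | 1.5 ± 0.3 min | generator choice; brightening "lasts ~6.5 min before extrusion" |
| contractility-inhibited condition | shrink ×23, extrusion ×0 | reported 23× shrink increase; Y-27632/blebbistatin block extrusion |
| hypertonic condition | shrink ×8, extrusion ×2 | illustrative defaults; no single fold value is reported |

Event times are chained backwards from the extrusion with truncated-Gaussian
jitter (sd = 20% of each mean lag, truncated at zero), which makes the
ordering invariant hold by construction. Chains whose ATP→extrusion span
exceeds 24 min are redrawn so a 10-frame baseline window always fits before
the chain inside a 30-min analysis window; this truncates <1% of joint draws
and shifts per-link means by <0.01 min. Events that cannot fit in the movie
raise an error naming the minimum span.

Condition multipliers act on the per-cell probability of *any* shrink event
relative to control, with a separate extrusion factor (contractility
inhibitors increase shrinkage while blocking extrusion, so the two must be
decoupled; a multiplier on shrink incidence alone would exceed probability
1 at ×23 under any usable extrusion rate).

### Rendering model

*Phase.* Interiors carry a static log-normal speckle texture; the junction
skeleton is bright with a static ±15% jitter and a Gaussian halo (σ = 1.8 px)
into the interiors. A shrinking cell opens a bright *gap band* inside its own
territory: the band width follows the isotropic-shrinkage law
`w(t) = r_eq · (1 − (1 − loss·p(t))^{1/3})`, where `p(t)` rises 0→0.7→0.9→1
over the first frames after onset (strictly increasing to its maximum),
holds, and closes at relaxation. Rendering the gap inside the shrinking
cell's own footprint matches the physics — the retracting cell vacates its
territory and the neighbours' bright junctions widen into the gap — and makes
per-cell area measurements leak-free. Extruding cells flash bright for two
frames at the extrusion and are then replaced by a sealed interior. Dividing
cells show a one-frame mitotic brightening and a cleavage-furrow line, both
kept below the lightning threshold: mitoses are excluded by eye in manual
scoring, and the event caller has no mitosis-rejection logic, so the
generator keeps division optics out of the shrink detector's band. That is a
known simplification: on real data, bright mitotic rounding would need
masking before the assay.

*Fluorescence.* Per-cell levels are uniform with ±20% static heterogeneity.
Volume reporter and Calcein scale linearly with instantaneous relative
volume (decline from onset to a trough plateau at `1 − loss`; extruders hold
the trough until extrusion, stayers recover over ~10 min). DiBAC steps up
+40% at depolarization; CoroNa steps up +35% at Na⁺ entry and decays
(τ = 5 min) after relaxation only in cells that stay; the ATP reporter
declines linearly by 30% from the ATP-decline onset to the chain end.

*Noise.* Shot noise plus Gaussian read noise. The default `"gaussian"` mode
draws one deviate per pixel with `sd = sqrt(I/photon_scale + read_sd²)` —
the large-count limit of the Poisson model, indistinguishable at the default
counts and ~15× faster than exact Poisson sampling, which remains available
via `noise_model="poisson"`. Defaults (`photon_scale` 20,000 for phase, 2
for fluorescence, `read_sd` 0.1) put the per-cell baseline
suprathreshold-area CV near 1% (tail cells up to ~7%), calibrated so the 10%
onset criterion has a false-onset rate below 0.05% per cell per movie —
essential because a per-cell false rate of even 0.2% would visibly inflate
the 3% apoptotic shrink fraction and deflate the 23× incidence ratio whose
control denominator is ~3% of cells. Fluorescence ROI-mean traces have
<0.2% CV because averaging over ~1,700 px suppresses pixel noise; that is
the physically expected regime for ROI means.

### What the generator does *not* emulate

No cell migration or neighbour rearrangement, no photorealistic
phase-contrast optics (halo/shade-off artefacts), no 3-D tissue geometry, no
daughter-cell relabelling after division, no mechanistic ion-flux dynamics —
conditions are scalar multipliers on event probabilities. Passing recovery
tests therefore demonstrates that the measurement pipeline is correct and
unbiased *given* the assumed optical signatures; it does not validate the
segmentation-free reading of real phase movies.

## Lightning assay

The original assay sets an intensity threshold by eye from pre-event frames;
here the threshold is automated as the 98th percentile of the pooled pixel
histogram of the 10 baseline frames, reused for all frames (strict-greater
rule, so a constant image yields zero area; no morphological filtering).
Suprathreshold area per frame is normalized to the 10-frame baseline mean.
Onset = first ≥10% rise sustained ≥2 frames; relaxation = first return to
≤5% above baseline (truncated at the extrusion and flagged when never
reached). The onset/relaxation deltas are package decisions — the manual
workflow defines neither numerically — and are exposed in `LightningParams`.

Two departures from a naive whole-crop reading, both documented design
choices:

1. **Territory-masked counting.** When a label map is available, the area is
   counted inside the analyzed cell's own Voronoi territory rather than the
   whole 400-px crop. On a dense monolayer every crop contains many cells;
   whole-crop counting would make each cell's series respond to every
   neighbour's event, destroying per-cell calling at high shrink incidence.
   The territory mask is the automated analogue of the analyst isolating the
   cell of interest. `measure_area_series` keeps the crop-level default
   (`mask=None`).
2. **Event-anchored windows.** Cells with an observed extrusion (an ROI
   whose `frame_last` precedes the movie end) are analyzed over the 50
   frames preceding the extrusion plus the baseline window, mirroring the
   original cropping "before, during and briefly after" the event; cells
   that stay are analyzed over the whole movie with the leading 10 frames as
   baseline.

The batch driver processes all cells sharing a crop and baseline in one pass
(one threshold, per-frame label counts); a test asserts bit-equality with
the per-ROI composition of the elementary operations.

## Volumetrics

`volume_from_zstack` counts voxels above a per-frame Otsu threshold computed
inside the footprint's bounding box (the original analysis used an
unpublished commercial "threshold macro"; Otsu is the reproducible stand-in)
times the voxel volume (0.4 µm default z step). The Calcein quench is read
as linearly proportional to volume — the true quench curve is not published —
and always flagged `calcein_proxy`. Percent shrinkage is the maximum drop of
the normalized volume below baseline within the event span (per-cell maxima,
not a fixed post-shock time point). Because a minimum over a noisy trace is
biased downward, cohort pipelines apply a 5-frame centred rolling mean
first; the rendered volume trough is a plateau wider than the smoothing
window, so the trough itself is not attenuated. Classification uses the 17%
volume-loss commitment threshold with a strict-greater rule (exactly 17% →
stay). With loss distributions N(20, 3²) and N(11, 2.5²) this forces
confusion rates Φ(1) ≈ 84% and Φ(2.4) ≈ 99%, which the tests verify against
the Gaussian-tail oracle.

## Trace kinetics

Traces are ROI means (bounding-box per the standard workflow; a
territory-masked variant is used by cohort pipelines where absolute effect
sizes matter). Onsets are the first ±10% excursion sustained 2 frames —
the onset criterion is a package decision, as the original reports onset
times without defining a detector. Ramp-shaped signals (the ATP decline) are
therefore called late by ≈ delta/slope; onset *timing* is only used on
step-shaped channels (DiBAC, CoroNa), where the call lands on the first
frame at or after the true onset. User-marked medium-change frames break
onset runs (dye refreshes). Lags are averaged over cells with both onsets;
cells missing either are counted, never imputed. Because the original
experiments could not film Na⁺ and voltage together, `estimate_lag` reports
both the paired same-cell lag and the cohort-difference estimate.

## QPI dry mass

`mass = λ/(2πα) · Σφ · A_px` with λ = 0.623 µm (red LED) and α = 0.185
µm³/pg — the standard specific refractive increment; the original defers to
prior methods without printing a value. Background is the mean phase of
empty space subtracted from the whole field (idempotent on the empty mean).
Trends are classified from the least-squares slope over a trailing 2-h
window against ±0.05 × mean mass per hour (no numeric criterion is given in
the source; pre-division mass gain of ~10%/h against flat pre-extrusion mass
is separated by a wide margin at this tolerance). No halo or shade-off
correction is applied.

## Event statistics

Rates are per 1,000 cells by default (per-10,000 available). Uncertainty is
a seeded percentile bootstrap over cells (2,000 resamples), replacing the
original ANOVA/t-test battery: the acceptance surface here is parameter
recovery, not p-value replication. Cells present in <50% of frames without
extruding are dropped from denominators and counted as dropouts.
Fold-changes are treated/baseline ratios with cell-level bootstrap CIs; a
zero baseline statistic is an error directing the user to report counts.

## Problem sizes and numerical choices

Cohort pipelines generate fields until event quotas are met: ≥210 pooled
LCE over five experiment seeds (HES incidence, durations), ≥110 extruding
and ≥110 non-extruding shrinkers (volume-loss means), ≥310 apoptotic
extrusions (rare-shrink fraction), ≥60 paired onsets (lags), and ≥150/55
fields (≈5,700/2,100 cells) for the condition pair, sizes chosen so each
recovered mean's sampling error is several times smaller than the tolerance
it is compared at. The fold-change denominator additionally pools the LCE
experiment's fields into the control cohort — they are default-condition
movies measured by the same pipeline, and the control shrink incidence
(~3.5% of cells) dominates the ratio's sampling variance. The apoptotic cohort fixes the event type to apoptotic
(the shrink-given-apoptotic model keeps its default), and the non-extruding
cohort raises the background shrink probability to 0.15 (the volume-loss
model and noise keep their defaults) — stratified sampling of the stratum
being measured, not a change to the quantity estimated. Ties and edge cases:
thresholds use strict `>`; the 17% classification boundary resolves to
"stay"; percentile interpolation is linear; all randomness flows from
explicit integer seeds through `numpy.random.SeedSequence`, so every
dataset, test and report is bit-reproducible.

## Known limitations

- The generator's optical signatures are stylized; absolute peak
  percent-change values from the lightning assay are calibration-dependent
  and only their ordering (monotone in true volume loss) is meaningful.
- The Calcein linearity assumption propagates into every proxy readout.
- Apoptotic morphology (blebbing, caspase reporter) is not rendered; the
  class label lives in the truth table only.
- Division optics are deliberately sub-threshold (see above).
- The ATP-decline lead time (3.0 min) and hypertonic condition factors are
  generator choices without a quantitative source value.
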