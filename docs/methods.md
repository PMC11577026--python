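# Methods

## The assay and its coordinate frame

The apparatus is modelled as a 120 × 120 cm floor split into two
120 × 60 cm compartments stacked along y (origin at the outer top-left
corner, x rightward, y downward, units cm — the frame of an overhead
camera). The divider carries a 4 cm passage centred at x = 60. Each
compartment contains four 8 × 8 cm corner refuges, a central home-cage
footprint and a 10 cm diameter food-column disc. Twelve regions are
hiding-designated: 8 corners, 2 cage tops, 2 food tops. The water-dispenser
top is merged into the cage-top polygon rather than counted separately, so
the refuge count stays at twelve.

Tracking is two-dimensional, so "on top of" a cage and "inside" it are not
distinguishable; cage tops are treated as the structure footprints. The
cage footprint (default 25 × 25 cm) and the corner placement are
configuration defaults, not measured constants — they are flagged as
assumptions in the shipped layout file and freely editable there. Polygon
boundaries count as inside (closed regions) so membership is deterministic
at edges.

## Trajectory cleaning and dwell metrics

Pose tables carry (x, y, likelihood) per body part per frame at 45 Hz.
Cleaning: coordinates with likelihood below 0.6 are set missing; interior
missing runs no longer than 0.5 s are linearly interpolated; longer runs
stay missing; both coordinates are then smoothed by a centred moving
average of 5 frames. None of these three constants is dictated by the
assay itself; they are defaults of this implementation, exposed in the
run configuration and recorded in the metadata sidecar of every run.

All dwell quantities operate on half-open, 0-based frame intervals;
durations are computed in frames and divided by the frame rate once, so no
floating-point time accumulates. Occupancy bouts shorter than 1 s are
discarded per ROI independently, before any summation — sub-second
boundary crossings are treated as tracking artifacts, not visits. Hiding
time is the union of retained bouts over the twelve refuges (a frame in
two overlapping refuges counts once). Exploration is time in the
opponent's compartment minus time simultaneously in that compartment's
refuges, computed as a frame-mask difference so it cannot go negative.
Proximity is time below 10 cm separation while both mice occupy the same
member of the proximity ROI list (each compartment, cage top and food
top), with each mouse's occupancy sub-second-filtered first. The
occupancy anchor and the proximity distance are measured at the "middle
back" body part by default (the most stable centroid-like landmark);
both are configurable. Locomotion is the cumulative anchor displacement,
skipping steps with a missing endpoint.

## Flight-aligned kinematics

Around each scored flight onset, the moment of peak acceleration is the
frame of steepest positive slope of the speed trace within an asymmetric
window (30 s before to 60 s after onset). The slope is a centred finite
difference of the speed after a 0.5 s moving-average smoothing (smoothing
span not dictated by the assay; 0 disables it); ties resolve to the
earliest frame. Symmetric 8-s windows centred on those frames are cut
from the speed and inter-mouse distance traces and averaged frame-by-frame
across all flights, missing-aware; the SEM uses ddof = 1 (defined as 0 for
a single contributing window). Windows partially outside the recording
contribute their available frames; fully-outside flights are skipped and
reported.

## Dominance inference

The behavior matrix holds seven late-phase measures per mouse: attack,
chase, flight and upright counts, locomotion (cm), and the fractions of
the phase spent exploring and hiding. Columns are z-scored across the
pooled cohort — all strains together, so scores are comparable across
groups — using the sample SD (ddof = 1) by default; the population
convention is selectable. A full-SVD PCA of the standardised matrix
follows. Sign convention: every component is oriented so its loading on
attacks is positive; PC1 then separates the aggressive/exploratory
strategy (attack, chase, locomotion, exploration positive) from the
defensive one (flight, upright, hiding negative), and the pair member with
the higher PC1 score is labelled dominant. Exact score ties are flagged
rather than broken. The per-pair PC1 difference (dominant minus
subordinate, hence ≥ 0) is the effect size used in strain comparisons.

### Re-pairing permutation test

For each behavior, the observed statistic is the mean over true pairs of
the absolute within-pair difference. The null re-matches the whole cohort
into artificial pairs: when the number of distinct perfect matchings
(2n − 1)!! is at most 10,005 the full set is enumerated (the p-value is
then exact and deterministic); otherwise matchings are sampled uniformly
by seeded shuffling. The p-value is the fraction of null statistics **at
least as large as** the observed one. For continuous data this is almost
surely identical to the strict "larger than" rule, and it keeps the
degenerate all-identical cohort at p = 1 rather than a spurious p = 0. No
add-one smoothing is applied to sampled nulls, so a sampled p can be 0.

A structural property of this L1 statistic worth knowing: for any four
values a ≤ b ≤ c ≤ d, the two "crossing" pairings give the identical sum
(c + d) − (a + b). Consequently, in cohorts of two or three pairs a large
fraction of the matching statistics tie exactly, the attainable p-values
are lumpy, and the exact test is conservative (measured type-I ≈ 0.007 at
α = 0.05 for two pairs) — valid, but weak. At realistic cohort sizes the
tie mass is negligible: at ten pairs the measured type-I error is ≈ 0.048
at α = 0.05. The test suite asserts calibration at ten pairs and
conservativeness (never anti-conservativeness) at two.

### Correlations and group tests

Behavior correlation matrices default to Pearson (Spearman selectable)
with per-cell p-values and a significance mask at α = 0.05; no
multiple-testing correction is applied by default across the 21 behavior
pairs, and the output metadata records that choice. Constant columns are
flagged and masked rather than erroring the whole matrix. Wilcoxon
signed-rank and Kruskal–Wallis delegate to scipy; all-zero paired
differences return statistic 0 with p = 1 by convention. Dunn's post hoc
(rank-mean z statistics with tie correction, Holm or Bonferroni
adjustment) is implemented in-package and cross-checked against
hand-computed examples in the tests. The two validation indices —
open-field anxiety (T_center − T_corners)/(T_center + T_corners) and odor
preference (T_dye − T_saline)/(T_dye + T_saline) — share one
implementation; both are undefined (NaN) when both times are zero.

## Urine-mark segmentation

The interactively trained pixel classifier used in practice is replaced
here by a deterministic colour-rule classifier, trading fidelity to a
specific trained model for reproducibility: after gray-world white
balancing over the arena mask, pixels are classified by hue/saturation
windows (yellow-green hue 0.10–0.33 → fluorescein; pink-red 0.83–1.02
wrapped → erythrosin b; saturation ≥ 0.25, value ≥ 0.15). Pixels matching
both windows go to the nearer circular-hue centroid. Speck removal keeps
only connected components of at least 0.05 cm² — component-area filtering
rather than morphological opening, because erosion-based opening distorts
mark outlines (it shaves rectangle corners) while area filtering preserves
genuine mark shapes exactly. Marked area per dye is reported as a percent
of the arena-mask pixels; blob statistics use 8-connectivity. The dye
doses (fluorescein 39 mg/kg, erythrosin b 54 mg/kg), visibility latency
(~25 min) and persistence (≥ 12 h) are carried as protocol metadata only.
Users with a trained per-pixel classifier can substitute its label raster
and still use the area quantification.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with one cohort-level knob, the divergence δ ∈ [0, 1]:

- **Events.** Per-mouse inhomogeneous Poisson processes. Base rates at
  parity, per 20 min per mouse: attack 11, chase 8, flight 10, upright 5.
  The dominant's attack/chase rates scale by 1 + δ·ramp(t) and the
  subordinate's by 1 − δ·ramp(t) (flight/upright mirrored), with a linear
  ramp from 0 at gate opening to 1 at 100 min. The attack base was chosen
  once so that a fully diverged pair's dominant attacks ≈ 22 times per
  20 min, the order observed in strongly aggressive outbred pairs; the
  ramp endpoint is the start of the late observation window.
- **Movement.** A two-mode waypoint walk per mouse: roam bouts (waypoints
  drawn in the current compartment, speeds ~N(8, 2.5) clipped to
  ≤ 14 cm/s, passage-routed compartment switches, with the dominant's
  probability of exploring the opponent side rising and the subordinate's
  falling as δ·ramp grows) alternating with hide bouts at refuge centroids
  (whose probability and duration grow with δ·ramp for the subordinate).
  Scored flights inject a 1.2 s sinusoidal speed burst peaking at 70 cm/s,
  directed into the current compartment — reproducing the kinematic
  signature of real flights (> 50 cm/s peaks against a < 20 cm/s roaming
  baseline). Eight body parts are derived from the middle-back path and
  heading, with small Gaussian jitter and occasional low-confidence
  dropouts for the cleaning stage to exercise.
- **Marking.** Floor images are rendered with spots (discs) and streaks
  (capsules) of each dye painted to a requested percent area (defaults:
  dominant 3.0%, subordinate 0.2% at δ = 1; 0.8% each at δ = 0), over a
  near-white floor with optional Gaussian noise and illumination gradient;
  the painted label raster is the ground truth.

Per-pair generators are spawned from the cohort seed via
`numpy.random.SeedSequence.spawn`, so cohorts are reproducible and pairs
independent. A separate matrix-level generator draws the seven behaviors
directly from the same role-shifted distributions (no trajectories) and is
used where hundreds of cohorts are needed (permutation calibration,
recovery curves).

What the generator does **not** emulate: genuine interaction between the
two animals (paths are conditionally independent given roles), identity
swaps and other tracker pathologies beyond simple dropouts, strain-specific
behavioral styles, and arena soiling/lighting artifacts in floor images.
Passing tests therefore demonstrate correctness of the *analysis* under
the assumed data structure, not robustness to every failure mode of real
recordings.

## Problem sizes

The generator's defaults are the study conditions (45 frames/s, 120-min
sessions). The test suite and the acceptance script run the trajectory
simulator at 5–9 Hz and/or 20–60 min sessions — the dwell, speed and
alignment code paths are frame-rate-agnostic, so lower rates exercise the
same logic on proportionally smaller arrays — and use the matrix-level
generator for the statistics that need hundreds of cohorts (600 null
cohorts for type-I calibration; 8 cohorts × 25 pairs for recovery rates).

## Known limitations

- The PC1 sign convention anchors on the attack loading; a cohort in which
  attacks genuinely anti-correlate with dominance would be mis-oriented.
- Exploration cannot exceed compartment time by construction, but the
  spec-level identity "hiding + non-hiding = window" holds only for
  gap-free tracks; missing frames belong to neither side.
- The rule-based dye classifier assumes roughly white floors and saturated
  dyes; heavily soiled floors need a trained classifier via the label-
  raster hook.
- Small-cohort permutation p-values are conservative (see above); report
  them with the cohort size.
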