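# Methods

`reachlearn` analyses the single-pellet skilled-reaching task: a mouse
reaches through a narrow slit to grasp and retrieve a food-pellet reward,
filmed from the side and tracked markerlessly (paws, nose, pellet; per-frame
x, y and a likelihood score per point). The package covers the full path from
pose tables to learning statistics, plus a synthetic cohort generator that
provides exact ground truth for every stage.

## Coordinate and data conventions

Image pixel coordinates, origin top-left, y increasing downward; 0-based
frame indices. Pose tables use the stacked scorer/bodyparts/coords CSV
dialect with `x, y, likelihood` triples per bodypart; an HDF5 variant is read
but not written. Floats are serialized with shortest-round-trip `repr`, so a
write→read cycle is value-identical and writes are byte-stable.

## Filtering

Tracked points with likelihood below the p-cutoff (default 0.85) are
discarded, as are paw samples outside the tracking bounds — the rectangle
covering the region beyond the slit where reaching happens. Both boundaries
are inclusive: a likelihood exactly at the cutoff and a point on the bounds
edge are retained (the exclusion rule is "falling below"). Original frame
indices are preserved through filtering, so temporal gaps stay visible.
Likelihood filtering applies to every point; the bounds filter applies to the
paw track used for detection. Occluded points are modelled (and expected) as
present rows with near-zero likelihood, not missing rows. No temporal
smoothing is applied anywhere in the analysis path.

## Reach detection

Reach detection runs on the filtered track of the preferred paw, chosen per
session as the paw with more retained in-bounds samples (configurable
override). The detector scans step vectors between consecutive retained
samples:

* a **reach start** is the earliest sample whose next `window` (default 5)
  steps are pairwise adjacent (≤ `max_gap` = 5 frames apart, ≈ 21 ms at
  240 fps) and of which at least `consensus` (default 4) strictly decrease
  the Euclidean distance to the static per-trial pellet position;
* the **retraction onset** (reach end) is then located via the first
  subsequent window in which ≥ 4 of 5 steps strictly increase that distance,
  and is placed at the pellet-distance minimum inside that window — the
  sample where the paw actually begins to withdraw. The start keeps the
  window's first sample, matching how the outward crossing is marked;
* scanning resumes after the end sample, alternating direction until the
  track is exhausted; candidates with fewer than `min_points` (default 6)
  samples are discarded.

Design choices worth noting:

* "Toward the pellet" is formalized as strict decrease of Euclidean distance
  to the pellet reference: parameter-free, rotation-invariant, and it reduces
  to the obvious reading when the pellet lies along +x from the slit. A
  zero-length step counts as neither toward nor away.
* The reach interval is [outward start, retraction onset]; the retraction
  phase is excluded from kinematics.
* The `max_gap` cap prevents stitching a candidate window across long
  occlusions; the value is not part of the original rule set and is
  configurable.
* The same windowed rule is applied symmetrically to starts and ends; under
  the slit-left/pellet-right geometry the "away from pellet" and "toward the
  slit" readings of retraction coincide.
* The kinematics are insensitive to the end-refinement for monotone reaches;
  for reaches that overshoot and pass by the pellet, the detected end is the
  point of closest approach, which is where "reaching" turns into
  "returning" under the distance formalization.

A brute-force detector that re-derives every candidate window from scratch
(plain loops, no shared code) is kept in the test suite; the streaming
implementation must agree with it exactly on 1,000 random tracks.

## Outcome taxonomy and metrics

Labels: `success` (retrieval to the mouth), `complete_miss` (no paw–pellet
contact), `contact_miss` (contact, failed retrieval), `other` (residual
targeted reach), `vain` (reach with no pellet on the platform). All non-vain
reaches are *targeted*. Per subject-day:

* success by trial = 100 × success trials / trials with ≥ 1 reach ("No Try"
  trials are excluded from the denominator);
* success by reach, complete-miss % and contact-miss % use targeted reaches
  as denominator; vain % uses total reaches;
* first-reach success % = trials whose ordinal-1 reach succeeded, over
  attempted trials (the denominator choice is configurable in principle;
  this one parallels the trial-level metric);
* zero denominators yield missing values, never exceptions or zeros.

At most one success per trial is enforced (the pellet is removed on
retrieval). Last-day outcome distributions pool targeted reaches within
group by default; per-subject weighting is available.

An optional geometric auto-classifier substitutes for manual annotation:
vain if the reach starts outside the pellet-present interval, complete miss
if the minimal paw–pellet distance exceeds `contact_radius_px` (default
15 px), success if contact is followed by retrieval (pellet track crossing
back through the slit or disappearing with the retracting paw), contact miss
otherwise. It never emits `other`.

## Kinematics

Per reach: path length (sum of Euclidean step lengths; a chord variant is
selectable), ΔY = max(y) − min(y), and ΔX = maximal extension beyond the
slit plane in the pellet direction, floored at 0. Aggregation is the
arithmetic mean within subject-day before any group averaging, matching the
repeated-measures design; a subject-day with no reaches is missing, not 0.

## Learning statistics

* **Learning Index**: per-animal Day 1 vs Day 8 difference, signed by an
  orientation registry (success-type metrics Day8 − Day1; miss/vain/
  distance/ΔY/ΔX Day1 − Day8) so positive always means improvement.
* **Paired Day 1 vs Day 8**: Shapiro–Wilk (α = 0.05) on the paired
  differences gates between a paired t test and a Wilcoxon signed-rank test.
  Identical vectors short-circuit to the exact null; a constant nonzero
  shift goes to the t branch (the t test is exact there, and Shapiro is
  undefined on constants).
* **Unpaired comparisons** (Learning Indices): Welch's t test with
  Welch–Satterthwaite degrees of freedom; two identical zero-variance groups
  short-circuit to statistic 0, p 1.
* **Time courses**: complete subject × day tables go to a two-way
  repeated-measures ANOVA (between group, within day). The within and
  interaction effects are Greenhouse–Geisser corrected; the ANOVA engine
  corrects the within effect, and the same epsilon is applied to the
  interaction dfs by the package. Any missing cell switches to a linear
  mixed model — random intercept per subject, sum-coded fixed effects group,
  day (categorical) and group × day — with Wald chi-square tests per term.
  Constant (zero-variance) responses short-circuit to the exact null.
  Branch selection is a pure function of the data and is recorded in every
  result. Any grouping column (genotype, sex, condition) can be the between
  factor without code changes.

All tests are two-sided; no multiple-testing correction is applied across
metrics, and the report states so.

## Synthetic cohorts

The generator emulates the study conditions: 8 days × 50 trials, 13 s access
windows at 240 fps (3,120 frames/trial), slit at x = 100 px with the pellet
at (160, 200) — roughly 1 cm at the task geometry's scale. Nothing in the
generative model is estimated from recorded data; it is the simplest model
producing the measured quantities with controllable day trends:

* **Outcomes.** Per-attempt success probability follows a per-group logistic
  learning curve q(day) (defaults: baseline 0.08, asymptote 0.45 for WT and
  0.25 for the Fmr1-KO group, rate 1/day, midpoint day 4.5). Attempts are
  independent Bernoulli(q) draws capped by a planned count (probabilities
  0.35/0.30/0.20/0.15 for 1–4 attempts), ending on the first success; by
  Wald's identity the pooled success-by-reach equals q exactly in
  expectation, so effects imposed on q appear 1:1 in that metric. Misses
  split complete/contact/other 45/45/10. No-Try trials occur at rate 0.08;
  after a retrieval, up to two vain reaches follow at rate 0.15 each. These
  attempt-count and rate defaults are free parameters chosen to give
  plausible session structure (≈ 1.7 reaches per attempted trial), not
  estimates of any real cohort.
* **Trajectories.** Straight slit→apex drift with one point per frame
  (15–30 outward samples ≈ 60–125 ms), a smooth vertical arc whose amplitude
  is drawn with sd = vertical_spread_curve(day) (default 18 → 6 px), iid
  Gaussian jitter (default 3 → 1 px) on interior points, and a mirrored
  retraction. A success apex touches the pellet exactly; contact misses stop
  4–12 px away; complete misses overshoot the pellet in x by
  overshoot_curve(day) (default 25 → 5 px) and pass ≥ 20 px off in y.
  Retractions use 5–7 samples (fast withdrawal); this also keeps the
  re-approach run after an overshoot apex below the 4-vector consensus, so
  one generated excursion is detected as one reach.
* **Dropout** re-emits points with likelihood < 0.05 at a per-frame rate
  (default 0 in clean configurations), emulating occlusion.
* **Determinism.** All randomness derives from `SeedSequence(seed,
  spawn_key=(group, subject, day))`; identical configurations reproduce
  identical files byte for byte.

What the generator does **not** emulate: digit/grasp kinematics, pellet
physics beyond removal-on-retrieval, door motion, camera distortion,
tracking-error autocorrelation, or realistic attempt-timing distributions.
Passing tests therefore demonstrate correctness of the analysis pipeline
under the stated generative assumptions, not performance on recorded video.

## Verification problem sizes

The acceptance-style checks in `tests/test_acceptance.py` use: 1,000 random
tracks (≤ 200 samples) for detector/oracle equivalence; a noiseless
2 × 5 subjects × 8 days × 20 trials cohort for ground-truth recovery
(≥ 95% of trials with exact reach counts, starts within ±2 frames); 100
replicate cohorts at 10 subjects/group × 8 days × 50 trials for power
(imposed success-by-reach asymptotes 45% vs 25%, ≥ 80% detection at
α = 0.05); 200 replicates for type-I calibration (rejection rate within the
95% binomial interval around 0.05); and 100 replicates for Learning-Index
recovery under imposed ΔY decay (spread 30 → 8 px vs 30 → 20 px). Power and
calibration cohorts are simulated at the outcome level and Learning-Index
cohorts at the reach level, through the same label/trajectory generators the
full simulator uses — an exact shortcut, since the statistics consume
per-subject-day values either way. `scripts/acceptance.py` runs the
frame-level pipeline at 2 × 5 subjects × 8 days × 10 trials and the
statistics at the full 10/group × 8 × 50 outcome-level scale.

## Known limitations

* The Euclidean toward-predicate makes the detected end of an overshooting
  reach the closest approach rather than the maximal extension; ΔX is
  nevertheless well-defined because it maximizes over the detected interval,
  but extreme overshoot geometries shorten the measured path.
* The mixed-model branch reports Wald chi-square tests, not
  Kenward–Roger-corrected F tests; with ≤ 20 subjects its small-sample
  calibration is approximate (the repeated-measures branch is used whenever
  the table is complete).
* The auto-classifier is a geometric surrogate; its `other` category is
  unreachable by construction, so annotation-based scoring is preferred when
  labels exist.
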