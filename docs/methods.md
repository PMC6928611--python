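# Methods

`grazetrack` classifies free-ranging livestock behavior into two
classes — *grazing* (foraging, head lowered, including
foraging-while-walking) and *nongrazing* (standing, lying, ruminating,
or walking without foraging) — from two sensor streams logged at a
nominal 50-s cadence: GPS fixes and tri-axial accelerometers at three
body locations (neck, leg, tail). This note documents the models,
their assumptions, the tunable parameters, and the design choices made
where the design was genuinely open.

## Movement metrics

Fixes are projected from WGS84 latitude/longitude onto UTM so distances
are Euclidean in meters. The projection is a direct implementation of
the transverse Mercator (Karney's series formulation, terms to n⁴),
accurate to well under a millimeter across a UTM zone; forward and
inverse transforms are provided and a segment is always projected on a
single zone.

For a focal fix and lag *i* (i.e. a window of *i* × 50 s), the feature
table holds:

| column | meaning |
|---|---|
| `blin_i` / `flin_i` | straight-line distance between the focal fix and the fix *i* steps behind / ahead |
| `seg_b_i` / `seg_f_i` | the single 50-s segment distance at backward / forward offset *i* |
| `bacc_i` / `facc_i` | path length (sum of segment distances) over the same window |
| `angle_i` | deviation-from-straight turning angle at the focal fix, degrees in [0, 180] |

Lags run 1–16 (windows of 100–800 s; accumulative distances start at
lag 2). Counting distinct metrics at the full window: 32 focal-lag
linear + 30 segment distances (lag-1 segments coincide with lag-1
linear) = 62 linear distances, plus 30 accumulative = 92 distance
metrics. A model restricted to interval *T* uses every column with lag
≤ *T*/50. Turning angles are computed at matched lag (one angle per
interval) and included by default, with a switch to drop them; the
historical single-angle convention is subsumed by the lag-1 angle. A
lookup table (`D_INDEX_TABLE`) maps the opaque d-indices used in field
reports onto these canonical names (e.g. d19 → `blin_6`, the 300-s
backward linear distance).

Rows whose window would leave a recording segment carry missing values
and are excluded per interval rather than imputed — imputation would
fabricate movement. Gaps longer than cadence + tolerance split a track
into segments, and no metric ever spans a gap.

## Posture metrics

Each of the nine channels (3 locations × 3 axes: x superior–inferior,
y anteroposterior, z transverse, m/s²) contributes to 24 model columns
per timestamp: the raw channels, per-location vector magnitudes
`M = √(ax²+ay²+az²)`, windowed standard deviations (population divisor
*n*), and per-location ODBA. The raw signal splits into *static*
acceleration — the running mean over a centered 7-sample window (3
fixes ≈ 2.5 min each side plus the focal sample; the focal sample is
included because that is the only reading consistent with both the
7-sample count and a running mean) — and the *dynamic* residual
raw − static. ODBA is the sum of absolute dynamic components over one
location's three axes. The SD window equals the static window (a
whole-bout SD is available as an option). At series edges the window
shrinks to the available samples, never pads, and the row is flagged;
flagged rows are kept for modeling but reported.

## Classifier

A Random Forest (scikit-learn ensemble) with the study protocol around
it implemented here:

* **Tuning** is an explicit grid search over `mtry` (default 1–10) and
  `ntree` (default 500–2000), scored by repeated stratified
  cross-validation; ties break toward smaller `mtry`, then smaller
  `ntree`, and the winner is refit on all rows. Accuracy is the
  default selection metric; κ is always reported alongside because
  accuracy flatters the 80:20 class mix.
* **Importance** is the classical mean decrease in Gini: for each
  feature, the count-weighted impurity decrease summed over every node
  split on it in every tree, divided by the number of trees. This is
  computed from the tree internals, not the normalized importances the
  ensemble object exposes.
* **Probability of nongrazing** is the vote share — the fraction of
  trees whose leaf majority is nongrazing. Partial-dependence curves
  overwrite one column with each grid value (grid spanning the 5th–95th
  percentile, 50 points) and average the predicted probability over
  training rows. Because the vote share thresholds each tree at its
  leaf majority, a vote-share PD estimates (a smoothed indicator of)
  the decision boundary; a `prob="leaf"` mode averages leaf class
  fractions instead and tracks the conditional class probability — the
  correct scale when a threshold is read off the curve.
* **Determinism:** one seed feeds bootstrap, feature subsetting and
  fold assignment; identical data + seed give identical models.

## Evaluation

Overall accuracy is trace/total of the 2×2 confusion matrix; per-class
accuracy is row-wise recall; Cohen's κ = (p_o − p_e)/(1 − p_e) with
p_e from the row × column marginals. An empty matrix yields undefined
(NaN) metrics; if both marginals are degenerate (p_e = 1), κ is defined
as 0 and flagged. Cross-validation is stratified 10-fold repeated 5
times with distinct fold seeds (stratification keeps nongrazing
present in every fold at 20% prevalence); out-of-fold predictions pool
into one matrix per repeat and reported metrics are means ± SD over
repeats.

The **interval sweep** re-evaluates the GPS model at every T in
{100, 150, …, 800 s}, restricting columns by lag and dropping
incomplete rows (so retained rows are non-increasing in T). The
posture model has no window and is evaluated once. The **optimal
interval** is the smallest T whose mean κ is within δ (default 0.05)
of the maximum over T — a formalization of "κ has stabilized".
Intervals with fewer than 5 rows per fold per class are skipped.

**Threshold extraction:** on a partial-dependence curve, the plateau is
the mean over the top decile of grid positions; the threshold is the
smallest grid value from which the curve stays within ε (default 0.02,
widened to the tail's own spread if larger) of the plateau. A curve
whose total range is ≤ ε has no threshold; a threshold landing inside
the plateau-defining decile (e.g. a monotone ramp) is flagged low
confidence.

## Synthetic deployments

No labeled field data ship with the package, so a generator provides
ground-truth deployments with the structure the analysis assumes.

* **Behavior process:** two-state alternating renewal with geometric
  dwell times on the 50-s grid; defaults dwell 1200 s (grazing) /
  300 s (nongrazing), giving the 80:20 stationary mix. The
  constructor enforces consistency between dwell means and the target
  fraction.
* **Movement:** each state moves an *anchor* (the animal's true
  position) and observed fixes scatter isotropically around it
  (lognormal radius, default 4.0 ± 1.2 m) — the apparent movement of an
  animal observed at 50-s fix spacing. Grazing advances the anchor by
  small lognormal steps (2.75 ± 1.5 m per 50 s ≈ 0.05 m/s effective
  drift, a slowly advancing foraging patch) along a persistent
  wrapped-normal heading (concentration 4); walking advances it by
  large near-straight steps (25 ± 8 m ≈ 0.5 m/s, concentration 50);
  resting freezes it. The rest/walk choice is made once per
  nongrazing bout (default 80% rest), so walking bouts inherit the
  configured dwell scale.

  This kinematic structure is deliberate: grazing and resting fixes
  have nearly identical short-window displacement *and* turning-angle
  distributions (both scatter-dominated; consecutive scattered fixes
  are reversal-biased in angle for both states), while long-window
  displacement diverges linearly with the grazing drift. Short
  windows are therefore genuinely uninformative about rest vs graze
  and the classifier's κ(T) rises steeply before plateauing near the
  nongrazing bout scale — the property the interval-optimization layer
  is meant to discover. Earlier, simpler kernels (pure correlated
  random walks per state) leak the state through lag-1 angles or step
  lengths and make every interval equally good.
* **Accelerometers:** nine independent Gaussian channels with
  state-dependent means/SDs. Defaults put gravity on each x axis
  (−9.8 m/s²) and make the neck anteroposterior channel the
  discriminant: −5.0 m/s² while grazing (head lowered) vs −0.3 m/s²
  otherwise, SD 1.0 — separation chosen so posture-based recovery is
  unambiguous while the channel remains realistic.

What the generator does **not** emulate: herd interactions, explicit
GPS error models (scatter is part of the movement kernel, not an error
process with its own covariance), battery dropout, diel rhythm,
sub-50-s accelerometer dynamics, or more than two behavior classes.
Passing recovery tests therefore show the pipeline recovers the truth
of *this* generative world at field-realistic magnitudes; they do not
certify field accuracies.

## Ground-truth targets used in recovery tests

* Realized grazing fraction → 0.80 ± 0.03 at n = 10⁴.
* Kolmogorov–Smirnov distance between class-conditional 300-s
  displacements > 0.5 under defaults.
* Repeated-CV κ ≥ 0.85 for the posture model; shuffled labels within
  0 ± 0.1.
* `raw_neck_y` ranked first by mean decrease in Gini.
* The displacement threshold read off the single-feature
  (`blin_6`) leaf-probability PD curve within ±20% of the plateau
  threshold of the generative posterior P(nongrazing | displacement)
  (walking-bout windows excluded — the threshold of interest separates
  resting from grazing, and walking sits far beyond it where a PD
  curve no longer tracks the 1-D posterior).
* Sweep optimal interval within one 50-s grid step of the 300-s
  nongrazing bout scale; posture metrics identical across intervals.

## Problem sizes and numerical choices

Recovery checks run at n = 10,000 fixes (≈ 5.8 days of logging).
Cross-validated evaluations use 200-tree forests (500–2000 trees is
the tuning range; evaluation accuracy is flat in forest size well
below it, and the smaller forests keep repeated CV affordable), the
interval sweep runs at n = 4,000 fixes with 5-fold single-repeat CV,
and the permutation null at n = 2,500 — sizes chosen so the full
recovery layer completes in minutes on one core while leaving all
conclusions unchanged at larger n. Lognormal step distributions are
moment-matched (σ² = ln(1+s²/m²)); a zero SD degenerates to the mean,
a zero mean to zero. Heading concentration c maps to a wrapped-normal
increment SD of 1/√c, with c = ∞ walking a straight line. Single-
feature forests use `min_samples_leaf = 100`; fully grown 1-D trees
memorize individual rows and produce meaningless PD curves. Ties in
the majority vote (share exactly 0.5) go to grazing.

## Known limitations

* κ comparisons between the pooled-matrix and per-repeat aggregation
  surfaces can differ by a few points; both are reported and never
  forced to agree.
* The optimal-interval rule depends on δ; δ = 1 degenerates to the
  smallest computed interval by construction.
* Turning angles at 50-s spacing carry little information once
  positions are scatter-dominated — consistent with distance metrics
  dominating the importance rankings — but they are retained because
  dropping them is a modeling decision the user should make explicitly.
* UTM cross-zone tracks are handled by forcing a single zone per
  segment; tracks genuinely straddling a zone boundary lose a little
  projection fidelity at the far edge.
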