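# Methods

## Data model

A cohort is a set of users, each with a CGM stream (timestamped interstitial
glucose in mg/dL, nominal 5-minute cadence) and a static profile (gender,
age at enrollment, age at diagnosis, prior CGM use, most recent HbA1c, with
an optional HbA1c history for time-varying lookup). Timestamps are
timezone-naive wall-clock time because hour-of-day is a model feature and
must reflect the user's own day. At ingest, readings outside (0, 1000) mg/dL
are dropped with a logged count, duplicate timestamps keep the last-seen
value (a re-transmission artifact rule chosen for determinism), and streams
are sorted. No imputation, calibration or denoising happens anywhere in the
pipeline: gaps stay gaps.

## Synthetic cohort generator

The generator emulates the *statistical structure* of a young-adult T1D CGM
cohort; it is phenomenological, not a physiological glucose–insulin ODE, and
it has no sensor-error (MARD) model. Per user, a noiseless latent trace is
built on the full scheduled grid:

- **baseline** = 28.7·HbA1c − 46.7 mg/dL (the standard eAG linear map),
  minus the analytic mean of the meal signal so the user's long-run mean
  tracks HbA1c. This is what gives the HbA1c feature genuine predictive
  value. HbA1c ~ U[7.5, 11.0), ages U[14, 25), mixed gender and prior-CGM
  flags.
- **circadian** sinusoid, amplitude U(8, 18) mg/dL per user, phased so the
  daily high falls in the evening and the low in the early morning.
- **meals** at 08:00/13:00/20:00 anchors with ±90 min jitter; each a
  gamma-shaped pulse peaking 55 min after onset, amplitude
  Gamma(9, mean 75 mg/dL). Dinner amplitudes are scaled ×1.25 (breakfast/
  lunch ×0.9), which produces the evening high-glucose peak around 21:00.
  `hyper_propensity` adds a heavy-tailed amplitude boost — under-bolused
  meals that cross 270 mg/dL.
- **insulin-correction dips** 100–160 min after each meal, Gaussian with
  σ = 35 min. Depth = base U(10, 30) plus `hypo_propensity` × a heavy-tailed
  draw (1600·u³); dips after ~20:00 are deepened ×1.35 and daytime dips
  damped ×0.85. The sharp clock-time dependence and the propensity tails are
  deliberately non-linear in the feature set, so tree models have structure
  that a linear model cannot fully capture.
- **noise**: stationary AR(1) (sd 6 mg/dL, coefficient 0.7) on observations
  only — short-term trend features are autocorrelated signal, not white
  noise. Observed and latent values are clipped to the CGM reporting range
  [40, 400].
- **thinning**: i.i.d. dropout (default 8 %) plus a 3-hour sensor-swap gap
  every 10 days.

Ground-truth event intervals are maximal runs of the *latent* trace beyond
70/270 on the scheduled grid, so labeler recall can be checked against truth
without noise artifacts. All randomness is drawn in a fixed order
independent of the propensity values; propensities only scale the drawn
quantities, so event counts are monotone in each propensity under common
random numbers (a tested invariant).

Default propensities (0.15 hypo, 0.25 hyper) were calibrated once so that
hypo labels are rare — order 1–2 % of rows — with hyper around 12 %, the
imbalance regime in which average precision separates the models; they are
part of the shipped defaults, not a tuning knob of the experiments. What the
generator does **not** emulate: real meal/exercise/bolus covariance,
sensor-specific error profiles, weekday/weekend behavior differences, or
inter-user correlation. Passing tests therefore demonstrate that the
*machinery* is correct and that the performance ordering holds when the
assumed signal structure is present — not clinical-grade performance on real
cohorts.

## Features

Windows are trailing and half-open, (anchor − d, anchor], including the
anchor reading; d ∈ {1 h, 1 d, 1 week}. "Fraction of time" metrics are
fractions of *observed readings* (equivalent to wall-clock integration at
uniform cadence, and unambiguous under dropout). Threshold fractions use
strict inequalities (< 70, > 270, < 54), matching the event definitions.
SD is the population SD; runs count strictly positive/negative consecutive
deltas, with ties breaking runs. Anchors need a full week of history and
≥ 80 % one-week usage. Windows holding fewer than two readings yield
explicit missing values for SD and delta statistics — never silent zeros.
Window statistics are computed by a numba kernel that accumulates each
window left-to-right, so results are bit-identical to a naive-loop
reference (a tested invariant). `anchor_stride` subsamples eligible anchors
(every k-th reading) purely to scale experiment size; it changes no value.
The full Table-style enumeration is 9 static + 9×3 windowed columns
(11×3 with the extended set); no attempt is made to force any other count.

## Targets and horizons

y_hypo = 1 iff any reading in (t, t + 60 min] is < 70 mg/dL (y_hyper
analogous with > 270). Anchors already in-event are removed so metrics
measure genuine ahead-of-time skill. Anchors whose lookahead contains no
readings are dropped rather than labeled negative: absence of data is not
evidence of absence of an event. Boundary readings exactly at 70/270 are
in-range. The per-event *prediction horizon* is measured from the start of
the final contiguous run of firing anchors (score ≥ 0.5) leading into the
event — a lone early spike is not a warning; a `mode="first"` switch uses
the earliest firing anchor instead. Lookback is capped at the 60-minute
prediction contract. Events with no qualifying alarm count as missed and
are excluded from the mean horizon.

## Models

- **Heuristic**: fires iff G < 110 (hypo) / G > 240 (hyper). Its
  pseudo-probability is a piecewise-linear strictly monotone transform of
  the distance past the threshold — any monotone transform gives the same
  ROC — calibrated so p ≥ 0.5 exactly when the alert fires, making the
  P = 0.5 dichotomization agree with the strict rule at the boundary.
- **Logistic**: L2 penalty, ≤ 300 iterations (lbfgs, tol 1e-8), class
  weights n/(2·n_c), continuous features standardized on training
  statistics, gender and day-of-week one-hot. Rows with missing features
  are excluded. Rows are put in a canonical (user, time) order before
  fitting so training is exactly invariant to input row order.
- **Boosted trees**: XGBoost (`hist`, single thread for determinism),
  missing values consumed natively, gender ordinal. Hyperparameters are
  chosen by seeded random search maximizing mean average precision over
  user-disjoint 5-fold CV of the training set, then refit on all training
  rows; the full trial record (space, draws, fold count, scores) is stored
  in the bundle. Average precision is the objective because rare positives
  make it the discriminating metric. The default space spans depth 2–10,
  learning rate 1e-3–0.3 (log), 50–1000 rounds, child weight, row/column
  subsampling and L1/L2 regularization; a reduced space (depth ≤ 6,
  ≤ 200 rounds) is used for desk-scale cohorts.

The split is by person (75/25): a user's entire stream lands on one side,
so no within-person leakage can occur; CV folds during tuning are likewise
user-disjoint (asserted at fit time).

## Evaluation

All models are scored on the identical complete-case test rows. AUROC uses
midrank tie handling; average precision is the step-wise
precision-over-recall integral; sensitivity/specificity dichotomize at
score ≥ 0.5 (boundary inclusive). CIs are percentile bootstrap over 500
row resamples, seeded; resamples on which a metric is undefined are redrawn
with a logged cap. Because rows within a user are autocorrelated, a
user-level cluster bootstrap is available as an option (it yields wider,
more honest intervals; the row bootstrap is the default for comparability
with the usual "sampling with replacement" convention).

## Explanation

Attributions are exact TreeSHAP values computed natively by XGBoost
(`pred_contribs`), on the margin (log-odds) scale where local accuracy is
exact — base + Σφ = margin to < 1e-4 per row, a hard tested contract.
Importance is the mean of |φ| over selected rows (cohort, per-user, or any
time window); per-user-then-across-users averaging is available via the
user scope. Features roll up into five categories — current reading, clock
time → *device information*; gender, ages, prior use, HbA1c →
*demographics*; windowed features → *short/medium/long term* — defined in
`src/cgmrisk/config/categories.yaml` so the grouping is editable without
touching code. Category fractions are shares of summed mean-|SHAP| and sum
to one. Only the boosted-tree model is attributed; logistic coefficients
are available on their bundle directly. Recommendation sentences live in
`config/templates.yaml` (data, not code); they are explicitly interpretive
templates keyed by driver feature, filled with period statistics (e.g. the
peak high-glucose hour), with a generic fallback for unmapped features.

## Numerical and design choices

- Quartiles in dashboards use linear-interpolation percentiles.
- Dashboard "time" metrics are reading-count fractions, consistent with the
  feature engine; time-in-range uses 70 ≤ G ≤ 270 so the three shares
  partition to 1 exactly.
- The run manifest hashes the canonical JSON of the config and of all stage
  outputs; end-to-end determinism (identical manifests from one config) is
  a tested acceptance property.
- Degenerate inputs: empty cohorts produce empty tables; single-reading
  streams have no gaps and no delta statistics; single-class training data
  raises a named error rather than fitting silently.

## Problem sizes

Shipped experiment defaults are 20 users × 60 days (~315 k readings,
~80 k labeled rows at anchor stride 3), tuning budgets of 4–8 trials over
the reduced space, and 500 bootstrap resamples; the generator also exposes a
153-user full-scale option. The test suite uses smaller cohorts (6–8 users,
16–21 days) chosen to keep the full property suite comfortably
reproducible on a laptop-class single core.

## Known limitations

- The generator's simplifications (above) mean absolute performance numbers
  on synthetic data say nothing about real cohorts; only the relative
  structure (model ordering, rare-event behavior, explanation placement) is
  meaningful.
- The heuristic's pseudo-probability spacing is arbitrary away from the
  threshold; only its order statistics matter.
- Per-user individual models and multi-horizon label grids (30/90/120 min)
  are out of scope; the horizon parameter is exposed but shipped at 60 min.
- HbA1c history is supported but the generator emits a single value per
  user by default.
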