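# Methods

This note documents the models, defaults and design decisions behind
`dhdrisk`: what the synthetic cohort emulates and does not, how each
analysis stage is defined numerically, and where genuinely open choices
were resolved.

## The prediction problem

The outcome is delayed hospital discharge (DHD) within 90 days of an
acute-care admission: a binary, per-admission event with a population rate
near 9%, among community-dwelling adults aged 65+.  Predictors are fixed a
priori: demographics (age, sex), area-level socioeconomics (income
quintile, rural/urban residency, four marginalization-index quintile
dimensions dichotomized at the most-marginalized quintile Q5), a five-level
region label, and binary clinical-history flags (care-support need,
dementia, falls, fractures, rehabilitation-discharge history, palliative
care, mobility/disability, and a small comorbidity set) constructed over a
2-year look-back window.  Admissions are longitudinal: one patient
contributes repeated rows, which drives the patient-level splitting and
grouped cross-validation throughout.

## Synthetic cohort generator

The generator emulates the *structure* of an administrative hospital
cohort, not any real population:

* **Covariates.**  Patient-stable draws: sex (49% female), residency (16%
  rural), region (18/32/18/22/10% across the five labels), income quintile
  (21/21/20/19/19%), marginalization Q5 rates per dimension (ethnic 16%,
  dependency 37%, instability 28%, deprivation 21%).  Age at first
  admission is a truncated log-normal on [65, 105] with median ≈ 80 years.
  Admission counts are 1 + Poisson(mean − 1) with a default mean of 3
  admissions/patient; dates are uniform over 2004–2022 and sorted within
  patient.
* **Clinical flags.**  Per-admission occurrence probabilities are
  logistic-normal in a shared patient frailty latent (loading 0.8), which
  induces mild positive correlation between history flags — deliberately,
  so that attribution/partial-dependence caveats about correlated features
  can be exercised.  One flag (`noise_marker`) has zero frailty loading and
  zero outcome coefficient: a designated pure-noise feature for
  permutation-importance null tests.
* **Outcome.**  `dhd_90d ~ Bernoulli(σ(β₀ + xᵀβ))` where `x` are the
  *engineered look-back features* — the same features the preparation stage
  reconstructs — so parameter recovery and Bayes-AUC comparisons are exact
  end to end.  The intercept is solved numerically (bisection on the
  realized covariate draw) so the mean event probability over clean rows
  equals the configured 8.9% prevalence.  Default coefficients put the
  largest log-odds weights on care-support history (1.6), dementia (1.5),
  rehabilitation-discharge history (1.2), mobility issues (1.1) and
  fracture (0.9), with a linear age term (0.055/year); the implied Bayes
  AUC — the discrimination of the true probability itself, computed
  analytically by pairwise comparison — is ≈ 0.82.
* **Distortions and contamination.**  A distortion map applies a
  logit-scale `(shift a_g, scale b_g)` to a group's true outcome
  probability, creating controlled group-specific miscalibration.
  Contamination channels inject under-65 patients (5%), LTC-origin rows
  (2%) and missing marginalization quintiles (0.3%, matching the "<0.3%
  missingness" regime) to exercise the exclusion rules.

`generate_scored_set` bypasses covariates entirely: scores are logit-normal
with (μ, σ) solved by quadrature/grid integration so a calibrated outcome
draw has a requested AUC and prevalence; outcomes are then drawn through
per-group distortions.  With `(a, b) = (0, 1)` the scores are calibrated by
construction.

**What passing tests do not show.**  The generator's linear-logistic truth,
independence of covariate blocks, stationary coefficients over 18 years,
and area-level variables drawn independently of clinical state are all
idealizations.  Recovery and fairness-mitigation results on this cohort
demonstrate correctness of the machinery, not real-world performance.

## Cohort preparation

Exclusions run complete-case in a fixed order — age < 65, then LTC origin,
then any missing field — with each row tallied under the first rule it
violates, so the tally is deterministic and conserves row counts.  The
look-back window is half-open, `[index − 730 d, index)`: an event flag
(fall, fracture, care-support, rehabilitation discharge, palliative,
mobility) counts only from admissions with strictly earlier dates inside
the window, while comorbidity-type flags (dementia, CHF, diabetes,
cerebrovascular) also count the index admission as a current condition —
the boundary rule is a package choice since "prior" conditions have no
stated day-level convention.  Same-day admissions are never "prior" to one
another, which makes the construction invariant to input row order.

Class imbalance is handled on the training side only (default:
inverse-prevalence sample weights; optional majority-class downsampling),
leaving the test set untouched so calibration metrics keep their meaning.

## Risk models

LR is fitted unpenalized (ridge available by putting a finite `C` in the
grid); the GBT learner is XGBoost with a small default grid (tree depth
{2, 3} × learning rate {0.1, 0.3} × 100 rounds).  The tuning objective is
mean out-of-fold AUC over stratified, patient-grouped 5-fold CV; ties break
toward the simpler model (fewer rounds, then shallower trees) by
evaluating grid points in complexity order and requiring strict
improvement.  The tuning grid and objective are package choices: neither is
standard-specified for this problem.

## Calibration

Platt scaling regresses the outcome on the log-odds of the probability
clipped to [1e-6, 1 − 1e-6] (the covariate scale is recorded in the
calibrator).  Diagnostics follow logistic recalibration: the calibration
intercept comes from the offset model (slope fixed at 1) and the slope from
the free model; ECE uses 10 equal-width, count-weighted bins (configurable;
sparse or empty bins carry their count weight, including zero).
Calibrators are fitted on training data by default — no held-out
calibration slice is carved out, though one can be supplied.  A negative
fitted slope (anti-correlated scores) breaks monotonicity and triggers a
warning rather than an error.

Group-stratified Platt scaling fits one map per protected-group label with
the global map as fallback for unseen or single-class groups.  Note a
degeneracy worth knowing: when two equal-sized groups carry symmetric
miscalibration, *global* Platt splits the difference and leaves both groups
equally miscalibrated, so the ECE *ratio* can sit near 1 while calibration
is poor everywhere.  The mitigation contrast is meaningful when group sizes
differ (the global calibrator then tracks the majority), which is how the
recovery checks are constructed.

## Fairness audit

All metrics are threshold-free.  AUC and xAUC use the Mann–Whitney rank
statistic with ties counting ½, verified against O(n²) enumeration.
Parity is uniformly equity-seeking / regular; xAUC parity is forward
(equity positives vs regular negatives) over backward, and the convention
is recorded in every report.  Bands classify |ratio − 1| against 0.1 and
0.2.  A zero denominator ECE yields an explicit "undefined" flag rather
than an infinity.

## Decision curves

Positive classification at threshold t means score ≥ t (ties act
positive).  Treat-all is computed analytically from the prevalence —
`π − (1−π)·t/(1−t)`, strictly decreasing with its root exactly at t = π —
and treat-none is identically zero.  Both raw and standardized (÷ π) net
benefit are always emitted, because the raw scale is what common reference
values at low thresholds correspond to while the standardized scale has
the interpretable maximum of 1.0.  The default grid is 0.01–0.60 in steps
of 0.01.

## Explainability

Shapley and breakdown attributions share a single interventional value
function — `v(S)` is the mean prediction over a seeded background sample
with the coalition's features fixed to the instance — so the two methods
are directly comparable, and `v(all)` equals the instance's own prediction,
which makes local accuracy (baseline + Σ contributions = prediction) exact
for breakdown, exact Shapley, and (by telescoping) permutation-sampled
Shapley alike.  Exact Shapley enumerates coalitions up to 12 features;
beyond that, permutation sampling is required.  Breakdown's "auto" order is
decreasing absolute single-fix effect, recomputed per instance.  Local
explanations default to a seeded 10% subsample of the test set (capped per
run configuration) using the model's *uncalibrated* scores, whose
balanced-training scale places a meaningful stratum above the 0.5
high-risk threshold used downstream.

## Explanation clustering

Per-feature metrics over high-risk instances: signed mean contribution,
mean rank by decreasing |contribution| (rank 1 = largest; ties broken
lexicographically for determinism), and percentage of instances with the
feature in the top-10.  Columns are z-scored and decomposed by
eigendecomposition of the 3×3 correlation matrix; sign indeterminacy is
resolved by forcing the contribution loading ≥ 0 on each component.
Quadrants come from the signs of PC1/PC2 scores (zero counts as positive).
Note the score-norm extreme has two tails — consistently important
features (positive PC1 under this convention) and consistently irrelevant
ones — so "dominant category among high-|score| features" statements are
made on the positive-PC1 half-plane.

## Pipeline and problem sizes

The orchestrated run derives every stage seed from the single configured
seed, writes all artifacts as delimited text/JSON with a SHA-256 manifest,
and is bit-reproducible.  Default analysis sizes used by the test suite and
the acceptance script: ~1.2 × 10⁵ admissions (40k patients) for parameter
recovery; 34k scored rows (70/30 groups) for calibration-mitigation
recovery; ~50k admissions (17k patients) for the end-to-end run, with local
explanations on 60 instances × 10 sampled permutations over an 80-row
background.  These sizes put Monte-Carlo error well inside the asserted
tolerances while keeping a full run to a few minutes on one CPU.

## Known limitations

* The generator has no admission-to-admission outcome dependence and no
  secular trends, so temporal validation exercises the mechanics (first
  admission-year partition, patient disjointness) rather than genuine
  drift.
* "Non-Ontario resident" exclusions have no synthetic analogue; invalid
  records are represented only through the missingness channel.
* Comorbidity flags can "expire" out of the look-back window two years
  after their last recorded occurrence — a property of window-based
  history, not of chronic disease.
* Sampled Shapley returns exact totals but approximate per-feature splits;
  the pipeline's default sample counts favour speed, and per-feature
  Monte-Carlo error is the dominant noise in the clustering inputs.
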