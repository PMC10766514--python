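# Methods

## Model

The risk score is an additive log-relative-risk over a moving window:

φᵢ(t) = ρ(**z**ᵢ) + Σ_{τ ∈ [t−δ+1, t]} Σₖ Iᵢₖτ · θₖ(xᵢₖ(τ), τ).

The modeling assumptions, in order of importance:

1. **Non-stationarity.** The implication of a clinical value depends on the
   post-transplant day; every per-feature quantity (cutoff, bin
   probabilities, contribution θ) is a function of *t*.
2. **Smoothness.** The latent process linking features to onset risk drifts
   slowly, so information can be borrowed across neighboring days by
   smoothing the estimated class-conditional bin probabilities along time —
   in probability space, never on raw values, which keeps the model
   agnostic to each lab's distribution and units.
3. **Missingness as absence of evidence.** An unobserved cell contributes
   exactly 0 to φ. The only densification is a time-limited sample-and-hold
   (default 3 days) at the data layer, reflecting that most measurements
   stay clinically valid for a few days.
4. **Naive additivity.** Feature–day contributions add on the log scale;
   the static prior ρ(z) is a categorical Naive Bayes log-odds.

### Fitting pipeline

For each feature *k*:

- **Per-day cutoffs.** On each day *t*, among at-risk patients with an
  observed value, the cutoff c maximizing the Shannon mutual information
  between 1{x > c} and the moving-window outcome (onset in (t, t+δ]) is
  found by exhaustive search over midpoints of consecutive sorted distinct
  values. Days with a single-class label vector or fewer than two distinct
  values yield no cutoff. Ties in MI go to the smallest candidate, applied
  with a 1e-12 relative tolerance so that exact mathematical ties broken
  differently by floating-point noise cannot flip the choice.
- **Thresholds.** lₖ and uₖ are the 25th and 75th percentiles
  (linear-interpolation convention) of the defined per-day cutoffs. A
  feature with no defined cutoff on any day is uninformative (θ ≡ 0).
- **Bin probabilities.** For each day and class (onset / no onset in the
  window), the fractions of observed at-risk patients with x < lₖ and
  x > uₖ. A day with no observed patient of a class leaves that class's
  entries undefined.
- **Smoothing.** Each of the four probability series is smoothed over its
  defined days with a cubic smoothing spline whose penalty is selected by
  generalized cross-validation, then evaluated (extrapolating) on every day
  1..horizon. The GCV solver requires ≥ 5 knots; series with 1–4 defined
  days fall back to a constant extension of their mean, and all-undefined
  series stay undefined. Smoothed values may leave [0, 1]; they are clamped
  at 0 inside θ, and γ keeps the ratio finite.
- **Contribution.** θₖ(x, t) = log[(max{0, ρ̂₁} + γ) / (max{0, ρ̂₀} + γ)]
  for the bin containing x, with the middle bin using
  max{0, 1 − ρ̂⁽ᴸ⁾ − ρ̂⁽ᴴ⁾} per class. With smoothing off, raw per-day
  probabilities are used and any undefined required value gives θ = 0
  (no information, no contribution).

Parameters that matter: **δ = 14 days** (the prediction window; also the
span of the score's look-back), **γ = 0.1** (dimensionless probability
floor; larger γ shrinks every contribution toward 0 — as γ → ∞, φ collapses
to ρ(z)), **horizon = 100 days** (the modeled post-transplant period),
**hold = 3 days** (sample-and-hold validity), NB pseudocount 1.

### Conventions for edge cases

- Windows are closed integer day ranges; for t < δ the look-back truncates
  at day 1, and outcome windows near the horizon truncate at it.
- A patient leaves the risk set on the day of onset and after their last
  observed day; while at risk they count as negatives.
- ρ(z) is fit once against the static outcome "onset within horizon", not
  re-fit per day. With no peri covariates it is the class-prior log-odds.
- Categorical NB uses additive smoothing over each feature's training
  vocabulary; a category unseen in training receives pure pseudocount mass,
  keeping scores finite.
- Model files are JSON with full float precision; reload is bit-exact.

## Evaluation machinery

- Daily AUROC (midrank ties) and AUPRC (average precision, step
  interpolation) over at-risk patients; undefined (NaN) on single-class
  days. Percentile bootstrap over patients (default B = 1000) for CIs,
  skipping single-class resamples.
- Internal validation uses expanding-window temporal cross-validation: the
  cohort, in temporal order, is split into n_folds blocks; fold j trains on
  blocks 1..j and validates block j+1; out-of-fold scores are pooled before
  computing daily metrics. The seed block is never validated.
- Feature importance at day t is the AUPRC decrement when the feature is
  removed from fitting and scoring entirely, on pooled out-of-fold scores;
  features are ranked by their maximum importance over days 8–30 (ties
  alphabetical).
- The top-sextile hazard ratio compares onset within (t, t+δ] between
  patients strictly above the 5/6 score quantile and the rest, by an
  unadjusted proportional-hazards fit censored at the window end; zero
  events in either group returns an explicit "incalculable" marker.
- The 2×2 chi-square uses the Pearson statistic with continuity correction
  (each count moved 0.5 toward its expectation, never past it) — this
  correction is required to reproduce the reference p = 0.458 on the
  worked-example table (41, 23; 47, 36).

## Synthetic data

### Binary-panel benchmarking generator

Emulates the regime the model targets: p = 50 binary features over T = 14
steps, each an independent two-state Markov chain (stay 0.7 / switch 0.3,
stationary start), with event probability φᵢ = Σₜ Σₖ θₖ(xᵢₖ(t), t) used
literally against a uniform draw (φ ≤ 0 never fires, φ ≥ 1 always).
Effector contributions: 45 of 50 features ("complex") or 5 of 50
("simple"); per-feature curves αₖ(t) are either a multiplicative Gaussian
random walk (sd 0.05, "smooth") or iid uniform ("rough"), linearly rescaled
so min = 0.3 and max = 0.7 exactly, with θ(high) = logit(α) and
θ(low) = −θ(high) (so |θ| ≤ logit(0.7) ≈ 0.847). Cohorts are oversampled in
batches and downsampled without replacement to exactly 15% events
(n = 1000 default); 60%-missingness scenarios blank cells uniformly at
random *after* event assignment. For model fitting, events get a nominal
onset at day T+1 so the moving-window label equals the event flag on every
day.

What it does not emulate: continuous values, feature-specific sampling
schedules, informative missingness, censoring, static covariates. Passing
the directional comparisons here shows the model exploits temporal
smoothness and tolerates random missingness — not that it handles
informatively missing or miscalibrated real data.

### Clinical fixture

A 500-patient, 8-feature, 100-day cohort with continuous labs: latent
stationary AR(1) processes (autocorrelation 0.9) drive a proportional
hazard h₀(t)·exp(Σ βₖ sᵢₖ(t) + 0.5·1{mismatched donor}), with a
gamma-shaped h₀ peaking in weeks 3–4 scaled for ~15% cumulative incidence —
onset timing then lands near the real-world pattern (median around day 26).
One strong effector (β = 2, chosen so the fixture genuinely contains the
dominant-predictor regime its recovery tests probe), two weaker ones
(β = 0.6, 0.3), five dummies. Observations are latent values plus
measurement noise on feature-specific schedules (periods 1–7 days, 10%
dropout, per-feature affine unit changes that rank-based metrics ignore);
5% of patients are administratively censored between days 30 and 100.
Ground truth (βs, latent paths, h₀) is returned for recovery tests.

## Problem sizes in tests and acceptance

The directional simulation claims are checked at n = 1000 with 30
replications (model vs XGBoost) and 20 replications (smoothing ablation);
oracle-equivalence claims use 1000 random instances; the fixture recovery
runs at n = 500 with 5-fold expanding CV. These sizes give stable
directional outcomes at desk scale; the full 150-replication grid remains
available through the CLI.

## Known limitations

- The moving-window labels used to fit day-τ bin probabilities refer to
  onset in (τ, τ+δ], while the score at day t sums those contributions for
  all τ in its look-back; the two windows are deliberately not re-aligned,
  matching the model's definition.
- The spline may extrapolate aggressively outside the observed-day range;
  clamping and γ bound the effect on θ but extreme-day contributions are
  the least trustworthy.
- Sextile hazard ratios are unadjusted and returned as "incalculable"
  whenever a group has no events; no continuity-corrected fallback is
  attempted.
- The smartphone postural-transition adapter takes the published 561
  engineered features as given and treats segment windows as pseudo-days;
  the published recordings themselves are not redistributable, so its
  extraction conventions are validated against exhaustive synthetic
  oracles rather than the original files.
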