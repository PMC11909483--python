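# Methods

This note documents the models, estimators and design choices behind
`wbcbt`, and what the synthetic study conditions do and do not
demonstrate about real trial data.

## Scales and derived categories

GAD-7 (0–21) and PHQ-9 (0–27) are scored as integers; PHQ-ADS is their
exact sum (0–48).  Eligibility requires a baseline score of ≥ 10 on
either scale; joint remission requires ≤ 4 on both at a completed
follow-up wave.  Severity bands: GAD-7 0–9 mild/none, 10–14 moderate,
≥ 15 severe; PHQ-9 adds a moderately severe band at 15–19 with severe at
≥ 20.  The five-level comorbidity classification pools PHQ-9 moderately
severe into "severe", making it a total, mutually exclusive function on
the full score grid (asserted by enumeration in the tests).  Score pairs
with both scales mild/none cannot occur among eligible participants; for
totality they map to the lowest comorbidity level.

## The synthetic trial generator

The generator emulates a three-arm trial (guided wb-CBT, self-guided
wb-CBT, TAU; 1:1:1) in a two-country university-student population, with
defaults chosen as the study conditions:

* **Cohort.** n = 1319 by default, 78.7% female, 55% in the larger
  country; seven universities, three of which run mental-health clinics
  (waitlist-recruited / clinic-campus / no-clinic ≈ 22/46/32%).
  Baseline scores are drawn from a latent-severity model and
  rejection-sampled jointly with the latent until eligible, so the
  accepted latent reflects the eligible population.  About 40 numeric
  baseline covariates span 11 domains (sociodemographics, university
  factors, stressors, comorbid disorders, physical health, social
  networks, personality, internet preferences, ...), fixed in a
  versioned codebook so attribution outputs have stable names.
* **Randomization.** Permuted blocks (default block size 6) within
  sex × GAD-7 band × PHQ-9 band strata.  The stratum granularity and
  block size are configuration parameters: within complete blocks,
  per-stratum arm counts are exactly balanced.
* **Usage.** Weekly minutes are zero-inflated lognormal with three
  levels of sparsity: a participant-level engagement flag, a weekly
  use flag given engagement, and lognormal positive minutes.  The
  (mu, sigma) of each arm × period profile are solved in closed form
  from target participant-week means/SDs: guided 12.5 (SD 36.9) vs
  self-guided 5.9 (SD 27.7) min/week in weeks 1–12, reversing to 0.2
  (SD 4.4) vs 0.4 (SD 7.5) in weeks 13–52.  TAU has no platform access.
* **Compliance signal.** A standardized linear score over designated
  covariates (employment, work-activity impairment, social-anxiety
  severity, phobia history, role impairment, loneliness, confidants,
  feature preferences, past-year assault, depressive-episode months,
  high-baseline-severity indicator, ...) shifts the weeks-13–52
  engagement probability.  The loading is calibrated by cached bisection
  so the *population* R² of log1p(total weeks-13–52 minutes) on baseline
  covariates equals the configured `compliance_signal_r2` (default
  0.05).  The calibration uses the independent-replicates identity
  Cov(T₁, T₂ | shared score) = Var(E[T | score]), which is unbiased and
  needs no smoothing.  Verified at large n: targets 0.05 and 0.30 give
  population R² 0.052 and 0.297.
* **Outcomes.** PHQ-ADS follows a linear structural model per wave:
  3-month scores load on baseline and (negatively) on log1p early-usage
  minutes plus direct arm effects; 12-month scores load on baseline, the
  3-month score and (negatively) on log1p late-usage minutes, with no
  direct arm effects by default — the 12-month benefit is mediated
  entirely by post-guidance usage.  Scores are clipped to range, rounded
  and split into GAD-7/PHQ-9 components.  Noise draws are shared across
  arms, so potential outcomes under a null effect map are *identical*
  across arms, and every trial stores per-participant potential outcomes
  (never visible to estimation).
* **Dropout.** Wave-specific logistic models: the 3-month wave depends
  on arm, country, recruitment source and baseline severity (TAU and the
  waitlist-recruited complete most); the 12-month wave additionally
  depends on 3-month completion and the *observed* 3-month score — MAR
  by construction, so estimator bias is attributable to the estimator.
  All four completion patterns occur; defaults give ≈ 68/67/54%
  (3-month / 12-month / both) completion.

**What the generator does not emulate:** pandemic-era time trends,
university-level clustering beyond a categorical covariate, item-level
questionnaire responses, non-adherence within TAU, and any dependence of
dropout on unobservables (missingness is MAR by construction).  Passing
tests therefore certify the estimators *under their stated assumptions*,
not robustness to violations of them.

## Doubly robust estimation

Per-arm means use targeted estimation on the bounded-rescaled outcome
(remission already in [0,1]; PHQ-ADS divided by 48): outcome regressions
(logistic for remission, linear-clipped for PHQ-ADS) are fit per arm
among completers; the response propensity is a pooled logistic model
with arm indicators, truncated below at 0.01 (configurable); a weighted
intercept-only logistic fluctuation with clever weight
1{A=a, completed}/(π̂_a g(X)) solves the efficient score, and the
estimate averages the updated predictions over the full cohort.  π̂_a is
the empirical arm share, which makes the no-missingness collapse to the
arm sample mean exact for intercept-only (saturated-on-one-cell) outcome
models.  SEs are influence-curve based; covariances between arm
estimates come from cross-products of influence contributions, feeding
the pairwise Wald contrasts and the 2-df overall test (a quadratic form
invariant to the choice of contrast basis).  An augmented-IPW mode
(`mode="aipw"`) skips the fluctuation and is used as an arithmetic
cross-check.

The 12-month longitudinal variant is a two-stage sequential regression:
E[Y₁₂ | baseline, 3-month score] among double completers, targeted with
the cumulative propensity 1/(π̂_a g₃ g₁₂); those updated predictions are
regressed on baseline among 3-month completers and targeted with
1/(π̂_a g₃).  When no participant has partial follow-up the sequential
stage carries no information and the implementation delegates exactly to
the single-wave estimator (making the collapse identity exact rather
than approximate).  Participants with 12-month data but no 3-month data
are first handled by predictive-mean-matching multiple imputation
(type-1 PMM: linear model of the 3-month score on baseline covariates,
arm and the observed 12-month score among double completers; each
recipient takes the observed value of one of its k = 5 nearest donors by
predicted mean; m = 20 imputations by default, m = 10 in the pipeline
for runtime), pooled by Rubin's rules — for the three arm estimates
jointly, with a pooled covariance (mean within-covariance plus
(1 + 1/m) × between-covariance) so contrasts and the 2-df test remain
available after pooling.

Descriptive completion-pattern comparisons use Pearson chi-squares
without continuity correction.  p-values are two-sided at α = .05, no
multiplicity correction.  Two open modelling choices are exposed rather
than resolved: the covariate list entering the nuisance models
(default: country, recruitment source, sex, baseline PHQ-ADS — the
dropout drivers) and the SE mode (influence-curve throughout).

## The compliance model

The target is log1p total minutes in weeks 13–52 (flags allow the raw
total or per-week mean): the transform tames a severely right-skewed,
two-thirds-zero quantity.  The super learner is written from scratch:
V-fold cross-validated predictions of each base learner form the
meta-level design and simplex-constrained weights minimize CV squared
error.  Weights are initialized at normalized non-negative least
squares, polished with SLSQP on the simplex, and guarded by comparison
against every vertex — so the empirical oracle inequality (ensemble CV
risk ≤ best single learner's CV risk) holds by construction; normalized
NNLS alone does not guarantee it, because normalization changes the
objective.  The default library is mean-only (a guard against
negative-signal overfitting), ordinary linear regression, standardized
ridge (α = 100), standardized lasso (α = 0.03), shallow gradient-boosted
trees (60 trees, depth 2) and standardized 25-nearest-neighbours.  The
strong regularization matters: with ~40 covariates and ~440 training
rows, plain least squares overfits away a population R² of 0.05 (honest
CV R² ≈ R² − p/n < 0), while the ridge recovers it.

Nested cross-validation (outer 10 folds; inner folds fit the weights
entirely inside each outer training split) yields out-of-fold scores
whose honesty the tests certify two ways: a leakage canary (a copy of
the target planted among the covariates must drive cv R² to ≈ 1 — the
machinery responds to genuine signal) and a permutation null (shuffled
targets center cv R² at ≤ 0).  The SE of cv R² is a leave-one-fold-out
jackknife; the inner fold count (10 by default, 5 in simulation suites)
is configurable.  Scoring the full cohort uses out-of-fold predictions
for the training arm and the refit ensemble elsewhere, so every score
derives from pre-randomization information — a temporal firewall the
pipeline also asserts at run time.

## Heterogeneity by predicted compliance

Scores are dichotomized at the top 40% (ceil(n × fraction), ties broken
by stable participant-id order).  The interaction statistic contrasts
the self-guided-vs-comparator adjusted difference between strata:
χ²₁ = ((Δ_high − Δ_low)/√(SE²_high + SE²_low))²; strata are disjoint, so
the differences are independent.  The comparator pools guided and TAU by
default (weighted by arm sizes, with the pooled influence function), with
a flag for self-guided-vs-guided only.  An exploratory grid search over
top fractions 0.2–0.8 maximizing the interaction statistic is provided
with a permutation-adjusted p-value to acknowledge the selection; the
default pipeline always uses the fixed 40% cut.  Attrition tables report
per-predictor completion counts under three definitions with Pearson
main-effect tests and predictor × arm heterogeneity tested by logistic
likelihood ratio (df = (levels − 1) × 2) — a likelihood-based choice
where a stratified-Pearson construction would also have been defensible.

## Attribution

Kernel Shapley values solve the Shapley-kernel-weighted least squares
over coalitions with the local-accuracy constraint eliminated into the
solve, so attributions sum exactly to f(x) − f(reference) even under
coalition sampling (used above 12 features; paired complements halve the
sampling variance).  The reference is the covariate mean vector; one-hot
categorical columns thereby receive level-frequency-weighted references.
The mean-substitution value — mean |f(x_i) − f(x_i with feature j at its
mean)| — and its proportional version SHAP_P (percent of the whole-model
value mean |f(x_i) − f(x̄)|) are computed side by side with the kernel
values: SHAP_P follows the substitution definition; beeswarm-style
dominant directions (sign of the feature–attribution correlation, with
an indeterminacy flag for symmetric dependences and numerically zero
attributions) follow the kernel values.  Ranked reports keep, per
domain, the top 5 features with mean |SHAP| ≥ 0.01, ties alphabetical.

## Numerical choices and problem sizes

Fluctuation equations are solved by bracketed Brent iteration on
[−15, 15] with the boundary value used if the score does not change
sign; logit inputs are clipped at 1e−6.  Logistic nuisance fits use
lightly ridged maximum likelihood (C = 1e4) and degrade to
intercept-only fits on degenerate designs, with a logged warning.  The
certification suites run at sizes chosen to give adequate Monte-Carlo
precision on one CPU: double-robustness bias at n = 4000 over 500
replications (|bias| < 2 MC SEs with either nuisance correct), CI
coverage at n = 2000 over 500 replications (92–98% band), interaction
type-I error at n = 900 over 1000 replications (0.05 ± 0.02), and
signal-strength recovery at the full trial size (n = 1319, 439 in the
training arm) over 20 seeds per condition.  The acceptance script uses
somewhat smaller replication counts for the same quantities.

## Known limitations

Real trials from this family have restricted-access data, so no
real-data estimate is reproduced here; published per-arm values enter
only as arithmetic inputs to the contrast/accounting operations.  The
generator's MAR dropout means the pipeline's unbiasedness results say
nothing about MNAR mechanisms.  The interaction test treats the
dichotomization threshold as fixed; inference after the exploratory
fraction search is only approximately handled by the permutation
adjustment.  The compliance model's cv R² at the default signal is small
and seed-noisy by design — conclusions at a single seed should quote the
jackknife SE.
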