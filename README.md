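# wbcbt

Doubly robust analysis of three-arm web-based CBT trials — guided
wb-CBT, self-guided wb-CBT and treatment-as-usual (TAU) — with 3- and
12-month follow-up under attrition, and a counterfactual
predicted-compliance specifier for treatment-effect heterogeneity.

## Who this is for

Trial statisticians and digital-mental-health researchers analysing
randomized trials of web-delivered interventions in which (a) follow-up
questionnaires suffer substantial, non-random loss to follow-up, (b)
platform metadata record per-week engagement minutes, and (c) the
scientific question is whether *predicted* long-term compliance —
estimated from baseline covariates only — modifies the comparative
effects of guided vs self-guided delivery.  Because trial datasets of
this kind are typically restricted-access, the package ships a synthetic
trial generator with known ground truth so every stage of the pipeline
is testable end to end.

## What it computes

**Outcomes.** Anxiety is scored with the GAD-7 (0–21), depression with
the PHQ-9 (0–27), and their sum is the PHQ-ADS (0–48).  The primary
outcome is *joint remission*: GAD-7 ≤ 4 and PHQ-9 ≤ 4 at a follow-up
wave; the secondary outcome is the mean PHQ-ADS score.

**Adjusted per-arm estimates.** For arm *a*, the targeted estimator of
E[Y(a)] combines an outcome regression Q(X) with a response-propensity
model g(X) = P(complete | X, arm): Q is updated by a one-dimensional
logistic fluctuation with clever weight 1{A=a, completed}/(π_a · g(X))
on the bounded-rescaled outcome, and the estimate is the mean updated
prediction over the full cohort.  Standard errors come from the
empirical variance of the efficient-influence-curve contributions; the
estimator is consistent if either nuisance model is correct, and the
fluctuation keeps remission estimates inside [0, 100] under extreme
weights.  Pairwise adjusted risk differences (ARD) and mean differences
(AMD) carry 1-df Wald chi-squares; a 2-df Wald test covers overall
variation across the three arms.  At 12 months a sequential-regression
(longitudinal) variant exploits partial follow-up — participants with
3-month but no 12-month data — and participants with the reverse
pattern are handled by multiple imputation with predictive mean
matching and Rubin pooling.

**Predicted compliance.** Compliance is minutes logged on the platform
per week; the prediction target is (log1p) total minutes in weeks 13–52,
after guidance ends.  A from-scratch cross-validated stacking ensemble
("super learner": simplex-weighted base learners minimizing V-fold CV
squared error) is trained in the self-guided arm under *nested* 10-fold
cross-validation, so every training-arm participant is scored by a model
that never saw them; everyone else is scored by the ensemble refit on
the full training arm.  The top 40% of predicted compliers define the
"high" stratum, per-arm estimates are recomputed within strata, and a
contrast-of-contrasts Wald test χ²₁ = ((Δ_high − Δ_low)/SE)² assesses
effect modification.

**Attribution.** Kernel Shapley values (exact coalition enumeration up
to 12 features, weighted sampling above) explain the compliance model,
alongside the mean-substitution construction: for feature *j*,
mean_i |f(x_i) − f(x_i with x_j → x̄_j)|, reported proportionally
(SHAP_P, as a percent of the whole-model value mean_i |f(x_i) − f(x̄)|;
individual SHAP_P values can sum above 100%).

## Worked example

```python
from wbcbt import pipeline as pl

cfg = pl.RunConfig(seed=1, generator={"n": 1319, "seed": 1})
res = pl.run_pipeline(cfg)
print(res.ate_report.query("outcome=='joint_remission' and kind=='estimate'"))
print(f"cv R^2 {res.cv_r2:.3f} (SE {res.cv_r2_se:.3f})")
```

On the default synthetic conditions this prints (remission in percent,
with influence-curve SEs):

```
        outcome wave     kind  arm_or_pair     value       se      n
joint_remission  3mo estimate       guided 45.317144 2.913324  439.0
joint_remission  3mo estimate  self-guided 34.723326 2.743511  443.0
joint_remission  3mo estimate          TAU 31.592953 2.510945  437.0
joint_remission 12mo estimate       guided 22.019546 2.398256  439.0
joint_remission 12mo estimate  self-guided 22.592892 2.366663  443.0
joint_remission 12mo estimate          TAU  8.097234 1.478143  437.0

cv R^2 0.025 (SE 0.021)
```

Read: at 3 months the guided arm leads (45.3% vs 34.7% self-guided,
ARD 10.6, χ²₁ = 7.1, p = .008); by 12 months the guided advantage over
self-guided has dissolved (ARD −0.6, p = .86) while both wb-CBT arms
beat TAU — the pattern the generator builds in by routing the 12-month
benefit through post-guidance usage.  The compliance model's honest
nested-CV R² of 0.025 (SE 0.021) reflects the weak-but-nonzero
configured signal (population R² 0.05).  The SHAP report ranks the
configured drivers (not being employed, work-activity impairment,
social-anxiety severity, ...) with their dominant directions.

The same pipeline runs from the command line:

```bash
wbcbt simulate --config config.yaml --out sim/       # four CSVs + truth
wbcbt validate --baseline sim/baseline.csv --arms sim/arms.csv \
               --usage sim/usage.csv --followup sim/followup.csv
wbcbt analyze  --config config.yaml --out results/   # full bundle
```

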