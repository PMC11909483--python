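"""Doubly robust estimator: oracles, collapse identities, MI, tests."""

import numpy as np
import pandas as pd
import pytest

from wbcbt import estimation
from wbcbt import synthetic_trial as st
from wbcbt.codebook import ARMS
from wbcbt.estimation import (
    AdjustedEstimate,
    EstimandSpec,
    EstimatorOptions,
    ImputationConfig,
    NuisanceFits,
    build_analysis_frame,
    contrast,
    dr_estimate,
    fit_nuisances,
    impute_3mo_pmm,
    longitudinal_dr_estimate,
    overall_test,
    pearson_chi2,
    pool_rubin,
)

SPEC_R3 = EstimandSpec("joint_remission", "3mo")
SPEC_R12 = EstimandSpec("joint_remission", "12mo")
SPEC_P12 = EstimandSpec("phq_ads_mean", "12mo")

INTERCEPT_ONLY = EstimatorOptions(
    outcome_model="intercept_only", propensity_model="intercept_only"
)


# ---------------------------------------------------------------------------
# nuisances


def test_no_missingness_gives_unit_propensities(complete_frame):
    nuis = fit_nuisances(complete_frame, SPEC_R3)
    assert (nuis.propensity == 1.0).all()


def test_mcar_half_dropout_intercept_only_propensities_near_half(small_frame):
    frame = small_frame.copy()
    rng = np.random.default_rng(0)
    frame["completed_3"] = rng.random(len(frame)) < 0.5
    nuis = fit_nuisances(frame, SPEC_R3, INTERCEPT_ONLY)
    assert np.allclose(nuis.propensity, frame["completed_3"].mean())
    assert abs(nuis.propensity.mean() - 0.5) < 0.1


def test_propensities_below_the_bound_are_clipped_and_flagged():
    """A covariate cell with near-zero completion triggers truncation."""
    rng = np.random.default_rng(1)
    n = 1200
    x = (np.arange(n) % 2).astype(float)
    completed = np.where(x == 0, True, rng.random(n) < 0.004)
    frame = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(n)],
        "arm": np.tile(ARMS, n // 3),
        "x": x,
        "completed_3": completed,
        "remission_3": np.where(completed, (np.arange(n) % 5 == 0).astype(float),
                                np.nan),
    })
    opts = EstimatorOptions(covariates=("x",))
    nuis = fit_nuisances(frame, SPEC_R3, opts)
    assert nuis.clipped > 0
    assert nuis.propensity.min() >= opts.truncation


# ---------------------------------------------------------------------------
# the targeted / augmented estimator


def test_full_data_saturated_models_collapse_to_arm_means(complete_frame):
    """With everyone completing, adjusted estimates equal raw arm means."""
    for spec, col in ((SPEC_R3, "remission_3"), (SPEC_R12, "remission_12"),
                      (SPEC_P12, "phq_ads_12")):
        res = dr_estimate(complete_frame, spec, options=INTERCEPT_ONLY)
        scale = 100.0 if spec.outcome == "joint_remission" else 1.0
        for arm in ARMS:
            raw = complete_frame.loc[complete_frame["arm"] == arm, col].mean()
            assert res.estimates[arm].value == pytest.approx(raw * scale, abs=1e-9)


def test_augmented_estimator_matches_the_hand_worked_table():
    """12-row table, hand-specified nuisances: the guided-arm augmented
    estimate is 50% by direct arithmetic.

    Guided rows: (x=0, completed, y=1), (x=0, missing), (x=1, completed,
    y=0), (x=1, missing); g=0.5, Q(x=0)=0.8, Q(x=1)=0.2, pi=4/12.
    H=1/(pi*g)=6 for completed guided rows, so the AIPW sum is
    (6*0.2+0.8) + 0.8 + (-6*0.2+0.2) + 0.2 + 8*0.5 = 6.0, psi=0.5.
    """
    x = np.array([0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
    arm = np.array(["guided"] * 4 + ["self-guided"] * 4 + ["TAU"] * 4)
    completed = np.array([1, 0, 1, 0] + [1] * 8, dtype=bool)
    y = np.array([1, np.nan, 0, np.nan, 1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
    frame = pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(12)],
        "arm": arm, "x": x, "completed_3": completed, "remission_3": y,
    })
    qg = np.where(x == 0, 0.8, 0.2)
    nuis = NuisanceFits(
        propensity=np.where(arm == "guided", 0.5, 1.0),
        outcome_pred={"guided": qg,
                      "self-guided": np.full(12, 0.5),
                      "TAU": np.full(12, 0.5)},
        truncation=0.01,
    )
    res = dr_estimate(frame, SPEC_R3, nuisances=nuis,
                      options=EstimatorOptions(covariates=("x",), mode="aipw"))
    assert res.estimates["guided"].value == pytest.approx(50.0, abs=1e-10)


def test_remission_estimates_bounded_under_extreme_weights():
    """The fluctuation step keeps remission estimates inside [0, 100]."""
    rng = np.random.default_rng(3)
    for seed in range(5):
        trial = st.generate_trial(st.GeneratorConfig(n=240, seed=60 + seed))
        frame = build_analysis_frame(trial.baseline, trial.arms, trial.followup)
        # rig savage missingness to stress the weights
        frame["completed_3"] = frame["completed_3"] & (rng.random(len(frame)) < 0.4)
        try:
            res = dr_estimate(frame, SPEC_R3,
                              options=EstimatorOptions(truncation=0.001))
        except ValueError:
            continue
        for e in res.estimates.values():
            assert 0.0 <= e.value <= 100.0


def test_zero_completers_in_an_arm_is_an_error(small_frame):
    frame = small_frame.copy()
    frame.loc[frame["arm"] == "TAU", "completed_3"] = False
    with pytest.raises(ValueError, match="TAU"):
        dr_estimate(frame, SPEC_R3)


# ---------------------------------------------------------------------------
# longitudinal estimator


def test_longitudinal_collapses_exactly_without_partial_followup(complete_frame):
    res_l = longitudinal_dr_estimate(complete_frame, SPEC_R12)
    res_s = dr_estimate(complete_frame, SPEC_R12)
    for arm in ARMS:
        assert res_l.estimates[arm].value == res_s.estimates[arm].value
        assert res_l.estimates[arm].se == res_s.estimates[arm].se


def test_longitudinal_collapses_when_wave1_completion_implies_wave2():
    drop = st.DropoutModel(intercept12=-1.0, completed3_carry=60.0, y3_coef=0.0)
    trial = st.generate_trial(st.GeneratorConfig(n=500, seed=31, dropout=drop))
    frame = build_analysis_frame(trial.baseline, trial.arms, trial.followup)
    assert not (frame["completed_3"] & ~frame["completed_12"]).any()
    assert (~frame["completed_3"] & frame["completed_12"]).any()  # 12-only exist
    res_l = longitudinal_dr_estimate(frame, SPEC_R12)
    res_s = dr_estimate(frame, SPEC_R12)
    for arm in ARMS:
        assert res_l.estimates[arm].value == res_s.estimates[arm].value


def test_longitudinal_reduces_bias_under_outcome_dependent_wave2_dropout():
    """When 12-month dropout depends on the observed 3-month score, the
    baseline-only estimator is biased and the sequential estimator that
    uses the 3-month data is materially less so."""
    drop = st.DropoutModel(y3_coef=-2.0)
    bias_base, bias_long = [], []
    for rep in range(50):
        cfg = st.GeneratorConfig(n=1500, seed=900 + rep, dropout=drop)
        trial = st.generate_trial(cfg)
        frame = build_analysis_frame(trial.baseline, trial.arms, trial.followup)
        truth = trial.truth.arm_means("remission", "12")
        res_b = dr_estimate(frame, SPEC_R12)
        res_l = longitudinal_dr_estimate(frame, SPEC_R12)
        bias_base.append(np.mean(
            [res_b.estimates[a].value - truth[a] for a in truth]))
        bias_long.append(np.mean(
            [res_l.estimates[a].value - truth[a] for a in truth]))
    # the baseline-only estimator carries a real selection bias here ...
    assert abs(np.mean(bias_base)) > 0.3
    # ... and using the 3-month data removes most of it
    assert abs(np.mean(bias_long)) < 0.5 * abs(np.mean(bias_base))


# ---------------------------------------------------------------------------
# multiple imputation


def _pmm_frame():
    # donors with y3 = 10 * x exactly; one recipient with x = 8.45
    x = np.array([1.0, 2.0, 9.0, 8.45])
    frame = pd.DataFrame({
        "participant_id": ["D1", "D2", "D3", "R"],
        "arm": ["TAU"] * 4,
        "x": x,
        "completed_3": [True, True, True, False],
        "completed_12": [True] * 4,
        "phq_ads_3": [10.0, 20.0, 90.0, np.nan],
        "phq_ads_12": [5.0] * 4,
    })
    return frame


def test_pmm_imputes_the_nearest_donor_value():
    frames = impute_3mo_pmm(
        _pmm_frame(), ImputationConfig(m=2, k=1, seed=0), covariates=("x",)
    )
    for f in frames:
        assert f.loc[f["participant_id"] == "R", "phq_ads_3"].iloc[0] == 90.0
        assert f.loc[f["participant_id"] == "R", "completed_3"].iloc[0]


def test_pmm_without_12_only_rows_returns_identical_copies(complete_frame):
    frames = impute_3mo_pmm(complete_frame, ImputationConfig(m=3, k=5, seed=1))
    assert len(frames) == 3
    for f in frames:
        pd.testing.assert_frame_equal(f, complete_frame)


def test_pmm_draws_only_observed_donor_values(small_frame):
    frames = impute_3mo_pmm(small_frame, ImputationConfig(m=4, k=5, seed=2))
    observed = set(
        small_frame.loc[small_frame["completed_3"], "phq_ads_3"].dropna()
    )
    recipients = ~small_frame["completed_3"] & small_frame["completed_12"]
    assert recipients.any()
    for f in frames:
        imputed = f.loc[recipients.to_numpy(), "phq_ads_3"]
        assert set(imputed).issubset(observed)
        # only 12-only rows were altered
        untouched = ~recipients.to_numpy()
        pd.testing.assert_series_equal(
            f.loc[untouched, "phq_ads_3"],
            small_frame.loc[untouched, "phq_ads_3"],
        )


def test_rubin_pooling_hand_arithmetic():
    a = AdjustedEstimate("TAU", 1.0, 1.0, "phq_ads_mean", "12mo", 100)
    b = AdjustedEstimate("TAU", 3.0, 1.0, "phq_ads_mean", "12mo", 100)
    pooled = pool_rubin([a, b])
    assert pooled.value == 2.0
    assert pooled.variance == pytest.approx(1.0 + 1.5 * 2.0)
    identical = pool_rubin([a, a])
    assert identical.value == a.value
    assert identical.variance == pytest.approx(a.variance)


def test_rubin_pooling_preconditions():
    a = AdjustedEstimate("TAU", 1.0, 1.0, "phq_ads_mean", "12mo", 100)
    with pytest.raises(ValueError):
        pool_rubin([a])
    b = AdjustedEstimate("guided", 1.0, 1.0, "phq_ads_mean", "12mo", 100)
    with pytest.raises(ValueError):
        pool_rubin([a, b])


# ---------------------------------------------------------------------------
# contrasts and overall tests


def _est(arm, value, se=1.0, outcome="joint_remission", wave="3mo"):
    return AdjustedEstimate(arm, value, se, outcome, wave, 440)


def test_contrast_reproduces_differences_of_adjusted_estimates():
    # 3-month guided vs self-guided remission estimates
    c = contrast(_est("guided", 50.3, 2.9), _est("self-guided", 37.2, 2.9))
    assert c.difference == pytest.approx(13.1)
    # stratified 12-month PHQ-ADS means, high-compliance subsample
    c2 = contrast(
        _est("guided", 17.5, 0.7, "phq_ads_mean", "12mo"),
        _est("self-guided", 13.3, 0.5, "phq_ads_mean", "12mo"),
    )
    assert c2.difference == pytest.approx(4.2)


def test_contrast_antisymmetry_and_wald_identity():
    a, b = _est("guided", 42.0, 2.0), _est("TAU", 37.0, 1.5)
    ab, ba = contrast(a, b), contrast(b, a)
    assert ab.difference == -ba.difference
    assert ab.chi2 == pytest.approx((ab.difference / ab.se) ** 2)
    assert ab.chi2 == pytest.approx(ba.chi2)
    same = contrast(a, a)
    assert same.difference == 0.0 and same.chi2 == 0.0


def test_contrast_requires_matching_estimands():
    with pytest.raises(ValueError):
        contrast(_est("guided", 1.0), _est("TAU", 1.0, wave="12mo"))


def test_overall_test_closed_form_and_invariance():
    ests = [_est("guided", 1.0), _est("self-guided", 0.0), _est("TAU", 0.0)]
    res = overall_test(ests, np.eye(3))
    assert res.chi2 == pytest.approx(2.0 / 3.0)
    assert res.df == 2
    # invariant to arm ordering
    perm = [ests[2], ests[0], ests[1]]
    res_p = overall_test(perm, np.eye(3))
    assert res_p.chi2 == pytest.approx(res.chi2)
    # equal means give a zero statistic
    equal = [_est(a, 5.0) for a in ARMS]
    assert overall_test(equal, np.eye(3)).chi2 == pytest.approx(0.0)


def test_overall_test_rejects_singular_covariance():
    ests = [_est(a, v) for a, v in zip(ARMS, (1.0, 2.0, 3.0))]
    with pytest.raises(ValueError, match="singular"):
        overall_test(ests, np.ones((3, 3)))


def test_pearson_chi2_hand_computation():
    chi2, df, p = pearson_chi2([[10, 10], [5, 15]])
    assert chi2 == pytest.approx(8.0 / 3.0)
    assert df == 1
    chi2_0, _, p0 = pearson_chi2([[8, 12], [8, 12]])
    assert chi2_0 == pytest.approx(0.0)
    assert p0 == pytest.approx(1.0)


def test_pearson_chi2_matches_brute_force_on_a_trial_table(small_frame):
    table = pd.crosstab(small_frame["arm"], small_frame["completed_3"])
    chi2, df, _ = pearson_chi2(table.to_numpy())
    counts = table.to_numpy(dtype=float)
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    assert chi2 == pytest.approx(((counts - expected) ** 2 / expected).sum())
    assert df == 2


def test_pearson_chi2_rejects_zero_margins():
    with pytest.raises(ValueError, match="margin"):
        pearson_chi2([[0, 0], [5, 15]])
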