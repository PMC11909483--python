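"""Generator properties: eligibility, balance, calibration, ground truth."""

import numpy as np
import pandas as pd
import pytest

from wbcbt import codebook, estimation
from wbcbt import synthetic_trial as st
from wbcbt.synthetic_trial import (
    DropoutModel,
    EffectMap,
    GeneratorConfig,
    WEEK_COLS,
    block_randomize,
    generate_cohort,
    generate_trial,
    randomization_stratum,
    simulate_missingness,
    simulate_outcomes,
)


@pytest.fixture(scope="module")
def big_trial():
    return generate_trial(GeneratorConfig(n=5000, seed=3))


def test_cohort_size_eligibility_and_sex_mix(big_trial):
    b = big_trial.baseline
    assert len(b) == 5000
    assert ((b["gad7_0"] >= 10) | (b["phq9_0"] >= 10)).all()
    # binomial error band around the configured female fraction
    se = np.sqrt(0.787 * 0.213 / 5000)
    assert abs(b["female"].mean() - 0.787) < 4 * se
    assert b["participant_id"].is_unique


def test_empty_cohort_is_allowed():
    assert len(generate_cohort(GeneratorConfig(n=0, seed=1))) == 0


def test_generator_is_deterministic_under_a_fixed_seed():
    a = generate_trial(GeneratorConfig(n=300, seed=9))
    b = generate_trial(GeneratorConfig(n=300, seed=9))
    assert a.baseline.equals(b.baseline)
    assert a.arms.equals(b.arms)
    assert a.usage.equals(b.usage)
    assert a.followup.equals(b.followup)
    c = generate_trial(GeneratorConfig(n=300, seed=10))
    assert not c.baseline.equals(a.baseline)


def test_block_randomization_balances_within_strata(big_trial):
    arms = big_trial.arms.merge(
        big_trial.baseline[["participant_id"]], on="participant_id"
    )
    strata = randomization_stratum(big_trial.baseline)
    counts = pd.crosstab(strata.to_numpy(), big_trial.arms["arm"].to_numpy())
    # per stratum, arm counts can differ by at most the final partial block
    assert (counts.max(axis=1) - counts.min(axis=1)).max() <= 2
    totals = big_trial.arms["arm"].value_counts()
    assert totals.max() - totals.min() <= counts.shape[0]


def test_six_in_a_stratum_with_complete_blocks_gives_two_per_arm():
    cfg = GeneratorConfig(n=60, seed=4, block_size=3)
    cohort = generate_cohort(cfg)
    # force a single stratum by collapsing scores
    cohort["sex"] = "female"
    cohort["gad7_0"] = 12
    cohort["phq9_0"] = 12
    cohort = cohort.head(6)
    arms = block_randomize(cohort, cfg)
    assert arms["arm"].value_counts().to_dict() == {
        "guided": 2, "self-guided": 2, "TAU": 2
    }


def test_permuting_input_order_preserves_stratum_arm_counts():
    cfg = GeneratorConfig(n=400, seed=8)
    cohort = generate_cohort(cfg)
    arms1 = block_randomize(cohort, cfg)
    shuffled = cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
    arms2 = block_randomize(shuffled, cfg)
    s1 = randomization_stratum(cohort)
    s2 = randomization_stratum(shuffled)
    t1 = pd.crosstab(s1.to_numpy(), arms1["arm"].to_numpy())
    t2 = pd.crosstab(s2.to_numpy(), arms2["arm"].to_numpy())
    pd.testing.assert_frame_equal(t1, t2)


def test_usage_profiles_hit_the_calibration_targets(big_trial):
    mat = big_trial.usage[list(WEEK_COLS)].to_numpy()
    arm = big_trial.arms["arm"].to_numpy()
    assert (mat >= 0).all()
    assert (mat[arm == "TAU"] == 0).all()
    guided_early = mat[arm == "guided"][:, :12].mean()
    self_early = mat[arm == "self-guided"][:, :12].mean()
    assert abs(guided_early - 12.5) / 12.5 < 0.15
    assert abs(self_early - 5.9) / 5.9 < 0.15
    # the pattern reverses after guidance ends
    guided_late = mat[arm == "guided"][:, 12:].mean()
    self_late = mat[arm == "self-guided"][:, 12:].mean()
    assert guided_early > self_early
    assert self_late > guided_late


def test_zeroed_usage_profiles_give_an_all_zero_matrix():
    zero = st.UsageProfile(0.0, 0.0, 0.0, 0.0)
    profiles = {a: {"early": zero, "late": zero} for a in codebook.ARMS}
    cfg = GeneratorConfig(n=100, seed=5, usage_profiles=profiles)
    trial = generate_trial(cfg)
    assert (trial.usage[list(WEEK_COLS)].to_numpy() == 0).all()


def test_null_effect_map_gives_identical_potential_outcomes():
    cfg = GeneratorConfig(n=800, seed=6, effects=EffectMap.null())
    trial = generate_trial(cfg)
    pot = trial.truth.potential
    for wave in ("3", "12"):
        base = pot[f"phqads_{wave}_guided"]
        for arm in ("self-guided", "TAU"):
            # shared noise draws make null potential outcomes exactly equal
            assert (pot[f"phqads_{wave}_{arm}"] == base).all()


def test_default_effects_give_guided_best_at_3mo_and_self_guided_at_12mo(big_trial):
    m3 = big_trial.truth.arm_means("remission", "3")
    m12 = big_trial.truth.arm_means("remission", "12")
    assert m3["guided"] > m3["self-guided"] and m3["guided"] > m3["TAU"]
    assert m12["self-guided"] > m12["guided"] and m12["self-guided"] > m12["TAU"]


def test_zero_usage_and_zero_effects_follow_the_configured_trajectory():
    """With zero noise, zero effects and zero usage the 3-month score is
    exactly drift3 + rho3 * baseline (clipped and rounded)."""
    eff = EffectMap(
        drift3=2.0, rho3=0.5, arm3=(0, 0, 0), usage3_coef=0.0, noise3_sd=0.0,
        drift12=1.0, rho12_baseline=0.25, rho12_y3=0.5, arm12=(0, 0, 0),
        usage12_coef=0.0, noise12_sd=0.0,
    )
    zero = st.UsageProfile(0.0, 0.0, 0.0, 0.0)
    profiles = {a: {"early": zero, "late": zero} for a in codebook.ARMS}
    cfg = GeneratorConfig(n=50, seed=7, usage_profiles=profiles, effects=eff)
    cohort = generate_cohort(cfg)
    arms = block_randomize(cohort, cfg)
    usage = st.simulate_usage(cohort, arms, cfg)
    out = simulate_outcomes(cohort, arms, usage, cfg)
    y0 = cohort["gad7_0"] + cohort["phq9_0"]
    expected3 = np.clip(np.round(2.0 + 0.5 * y0), 0, 48)
    y3 = out["gad7_3"] + out["phq9_3"]
    np.testing.assert_array_equal(y3.to_numpy(), expected3.to_numpy())
    expected12 = np.clip(np.round(1.0 + 0.25 * y0 + 0.5 * y3), 0, 48)
    y12 = out["gad7_12"] + out["phq9_12"]
    np.testing.assert_array_equal(y12.to_numpy(), expected12.to_numpy())


def test_no_dropout_model_completes_everyone(complete_trial):
    assert complete_trial.followup["completed"].all()


def test_all_four_completion_patterns_occur_and_tau_completes_most(big_trial):
    f = big_trial.followup.pivot(
        index="participant_id", columns="wave", values="completed"
    ).astype(bool)
    patterns = set(map(tuple, f[[3, 12]].to_numpy().tolist()))
    assert patterns == {(True, True), (True, False), (False, True), (False, False)}
    joint = (f[3] & f[12]).rename("both").reset_index()
    joint = joint.merge(big_trial.arms, on="participant_id")
    rates = joint.groupby("arm")["both"].mean()
    assert rates["TAU"] == rates.max()


def test_null_compliance_signal_is_unpredictable():
    cfg = GeneratorConfig(n=1500, seed=13, compliance_signal_r2=0.0)
    trial = generate_trial(cfg)
    late = trial.usage[[f"week_{w}" for w in range(13, 53)]].sum(axis=1)
    target = np.log1p(late.to_numpy())
    arm = trial.arms["arm"].to_numpy()
    sg = arm == "self-guided"
    s = codebook.signal_score(trial.baseline)[sg]
    y = target[sg]
    # in-sample correlation with the signal score should be near zero
    r = np.corrcoef(s, y)[0, 1]
    assert abs(r) < 0.1


def test_score_ranges_and_arm_balance_hold_across_random_configs():
    for seed in (21, 22, 23):
        cfg = GeneratorConfig(
            n=240, seed=seed,
            female_fraction=0.5 + 0.1 * (seed % 3),
            compliance_signal_r2=0.02 * (seed % 3),
        )
        trial = generate_trial(cfg)
        b = trial.baseline
        assert b["gad7_0"].between(0, 21).all()
        assert b["phq9_0"].between(0, 27).all()
        assert ((b["gad7_0"] >= 10) | (b["phq9_0"] >= 10)).all()
        totals = trial.arms["arm"].value_counts()
        assert totals.max() - totals.min() <= 30  # block-imbalance bound
        f = trial.followup
        done = f[f["completed"] == 1]
        assert done["gad7"].between(0, 21).all()
        assert done["phq9"].between(0, 27).all()


def test_wave2_only_outcome_dependence_shows_in_wave2_dropout():
    """Wave-1 dropout ignores the 3-month score; wave-2 dropout tracks it."""
    drop = DropoutModel(
        intercept3=0.5, arm3=(0, 0, 0), mexico3=0, waitlist3=0,
        clinic_campus3=0, severity3=0.0,
        intercept12=0.5, arm12=(0, 0, 0), mexico12=0, waitlist12=0,
        clinic_campus12=0, severity12=0.0, completed3_carry=0.0, y3_coef=-1.5,
    )
    cfg = GeneratorConfig(n=4000, seed=14, dropout=drop)
    cohort = generate_cohort(cfg)
    arms = block_randomize(cohort, cfg)
    usage = st.simulate_usage(cohort, arms, cfg)
    out = simulate_outcomes(cohort, arms, usage, cfg)
    flags = simulate_missingness(cohort, arms, out, cfg)
    y3 = (out["gad7_3"] + out["phq9_3"]).to_numpy(dtype=float)
    c3 = flags["completed_3"].to_numpy()
    c12 = flags["completed_12"].to_numpy()
    # wave-1 completion unrelated to the 3-month score
    assert abs(y3[c3].mean() - y3[~c3].mean()) < 0.6
    # wave-2 completion strongly related among wave-1 completers
    assert y3[c3 & ~c12].mean() - y3[c3 & c12].mean() > 2.0


def test_truth_contrasts_match_the_null_closed_form():
    cfg = GeneratorConfig(n=2000, seed=15, effects=EffectMap.null())
    trial = generate_trial(cfg)
    for outcome in ("remission", "phqads"):
        for wave in ("3", "12"):
            assert trial.truth.true_contrast(outcome, wave, "guided", "TAU") == 0.0
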