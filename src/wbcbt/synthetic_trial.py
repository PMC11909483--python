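"""Synthetic three-arm trial generator with known ground truth.

Emulates the structure of a guided wb-CBT vs self-guided wb-CBT vs
treatment-as-usual (TAU) trial in a university-student population with
clinically significant anxiety or depression:

* block randomization with equal allocation, stratified by sex and
  baseline severity bands;
* weekly platform-usage minutes over 52 weeks, zero-inflated lognormal,
  with guided usage concentrated in weeks 1-12 (while human guidance is
  active) and self-guided usage persisting in weeks 13-52;
* weeks-13-52 usage weakly predictable from baseline covariates, with
  the population R^2 of the log1p-total usage on covariates calibrated
  to a configurable target;
* 3- and 12-month symptom outcomes in which the 3-month benefit tracks
  early usage and the 12-month benefit is mediated by weeks-13-52 usage;
* wave-specific missing-at-random dropout depending on arm, country,
  recruitment source and baseline severity (and, for the 12-month wave,
  on the observed 3-month outcome), so that all four completion
  patterns (both waves / 3-month only / 12-month only / neither) occur.

Every generated trial carries a :class:`TruthRecord` of per-participant
potential outcomes under each arm, so estimator bias and coverage are
measurable exactly.  Truth is never consumed by the estimation modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import codebook
from .codebook import ARMS
from .scales import (
    GAD7_MAX,
    PHQ9_MAX,
    PHQ_ADS_MAX,
    is_eligible,
    severity_category,
    SymptomScores,
    Wave,
)

N_WEEKS = 52
EARLY_WEEKS = tuple(range(1, 13))   # guidance phase
LATE_WEEKS = tuple(range(13, 53))   # post-guidance phase
WEEK_COLS = tuple(f"week_{w}" for w in range(1, N_WEEKS + 1))

_STAGE_COHORT, _STAGE_RAND, _STAGE_USAGE, _STAGE_OUTCOME, _STAGE_MISS = range(5)


@dataclass(frozen=True)
class UsageProfile:
    """Zero-inflated lognormal weekly-usage model for one arm x period.

    A participant *engages* with probability ``p_engage``; an engaged
    participant uses the platform in a given week with probability
    ``q_week``; positive weekly minutes are LogNormal(mu, sigma).
    """

    p_engage: float
    q_week: float
    mu: float
    sigma: float

    @property
    def weekly_mean(self) -> float:
        return self.p_engage * self.q_week * math.exp(self.mu + self.sigma**2 / 2)


def _profile_from_moments(
    mean: float, sd: float, p_engage: float, q_week: float
) -> UsageProfile:
    """Solve (mu, sigma) so the participant-week mean and SD are hit exactly."""
    if mean <= 0:
        return UsageProfile(p_engage, q_week, 0.0, 0.0)
    p_use = p_engage * q_week
    m1 = mean / p_use                      # E[LN]
    m2 = (sd**2 + mean**2) / p_use         # E[LN^2]
    ratio = m2 / m1**2                     # exp(sigma^2), must exceed 1
    if ratio <= 1:
        raise ValueError("target SD too small for the zero-inflation level")
    sigma2 = math.log(ratio)
    mu = math.log(m1) - sigma2 / 2
    return UsageProfile(p_engage, q_week, mu, sigma2**0.5)


def default_usage_profiles() -> dict[str, dict[str, UsageProfile]]:
    """Per-arm, per-period profiles calibrated to the study conditions.

    Weeks 1-12: guided mean 12.5 SD 36.9, self-guided mean 5.9 SD 27.7
    minutes per participant-week; weeks 13-52 the pattern reverses
    (guided 0.2 SD 4.4, self-guided 0.4 SD 7.5).  TAU has no platform
    access and is always zero.
    """
    zero = UsageProfile(0.0, 0.0, 0.0, 0.0)
    return {
        "guided": {
            "early": _profile_from_moments(12.5, 36.9, 0.90, 0.50),
            "late": _profile_from_moments(0.2, 4.4, 0.20, 0.05),
        },
        "self-guided": {
            "early": _profile_from_moments(5.9, 27.7, 0.75, 0.35),
            "late": _profile_from_moments(0.4, 7.5, 0.33, 0.0606),
        },
        "TAU": {"early": zero, "late": zero},
    }


@dataclass(frozen=True)
class EffectMap:
    """Structural outcome model on the PHQ-ADS scale.

    3-month score: ``drift3 + rho3 * Y0 + arm3[arm] - usage3_coef *
    log1p(minutes weeks 1-12) + noise``.  12-month score: ``drift12 +
    rho12_baseline * Y0 + rho12_y3 * Y3 + arm12[arm] - usage12_coef *
    log1p(minutes weeks 13-52) + noise``.  Scores are clipped to the
    valid PHQ-ADS range and split into GAD-7/PHQ-9 components.  With all
    arm effects and usage coefficients zero the three arms have
    *identical* potential outcomes (noise draws are shared across arms).
    """

    drift3: float = 1.5
    rho3: float = 0.35
    arm3: tuple[float, float, float] = (-1.6, -0.4, 0.0)  # guided, self-guided, TAU
    usage3_coef: float = 0.15
    noise3_sd: float = 5.5
    drift12: float = 6.5
    rho12_baseline: float = 0.20
    rho12_y3: float = 0.35
    arm12: tuple[float, float, float] = (0.0, 0.0, 0.0)
    usage12_coef: float = 2.0
    noise12_sd: float = 5.0

    @classmethod
    def null(cls) -> "EffectMap":
        """No arm or usage effects: all arms share identical outcomes."""
        return cls(arm3=(0.0, 0.0, 0.0), usage3_coef=0.0,
                   arm12=(0.0, 0.0, 0.0), usage12_coef=0.0)


@dataclass(frozen=True)
class DropoutModel:
    """Wave-specific logistic completion model (MAR by construction).

    Wave-1 (3-month) completion depends on baseline covariates and arm
    only.  Wave-2 (12-month) completion may additionally depend on
    wave-1 completion and on the *observed* 3-month PHQ-ADS score, which
    keeps missingness MAR while making baseline-only adjustment at 12
    months insufficient.
    """

    intercept3: float = -0.06
    arm3: tuple[float, float, float] = (0.0, -0.15, 0.6)
    mexico3: float = 0.95
    waitlist3: float = 0.8
    clinic_campus3: float = 0.35
    severity3: float = -0.10        # per SD of baseline PHQ-ADS
    intercept12: float = -0.55
    arm12: tuple[float, float, float] = (0.0, -0.10, 0.3)
    mexico12: float = -0.05
    waitlist12: float = 0.2
    clinic_campus12: float = 0.2
    severity12: float = -0.10
    completed3_carry: float = 1.8   # completing wave 1 predicts completing wave 2
    y3_coef: float = -0.15          # per SD of observed 3-month PHQ-ADS

    @classmethod
    def none(cls) -> "DropoutModel":
        """Degenerate model: everyone completes both waves."""
        return cls(intercept3=math.inf, intercept12=math.inf)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of a synthetic trial."""

    n: int = 1319
    seed: int = 0
    female_fraction: float = 0.787
    mexico_fraction: float = 0.55
    compliance_signal_r2: float = 0.05
    block_size: int = 6
    usage_profiles: dict[str, dict[str, UsageProfile]] = field(
        default_factory=default_usage_profiles
    )
    effects: EffectMap = field(default_factory=EffectMap)
    dropout: DropoutModel = field(default_factory=DropoutModel)
    max_rejection_rounds: int = 100

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        for p in (self.female_fraction, self.mexico_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.compliance_signal_r2 < 0.75:
            raise ValueError("compliance_signal_r2 must lie in [0, 0.75)")
        if self.block_size % len(ARMS) != 0:
            raise ValueError("block_size must be a multiple of the number of arms")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthRecord:
    """Per-participant potential outcomes under every arm and wave.

    Columns ``phqads_{3,12}_{arm}`` and ``remission_{3,12}_{arm}``; the
    implied true per-arm means and contrasts are exposed through
    :meth:`arm_means` and :meth:`true_contrast`.  Estimation code never
    sees this object.
    """

    potential: pd.DataFrame

    def arm_means(self, outcome: str, wave: str) -> dict[str, float]:
        """True mean potential outcome per arm (remission in percent)."""
        scale = 100.0 if outcome == "remission" else 1.0
        key = "remission" if outcome == "remission" else "phqads"
        return {
            arm: float(self.potential[f"{key}_{wave}_{arm}"].mean()) * scale
            for arm in ARMS
        }

    def true_contrast(self, outcome: str, wave: str, arm_a: str, arm_b: str) -> float:
        means = self.arm_means(outcome, wave)
        return means[arm_a] - means[arm_b]


@dataclass
class SyntheticTrial:
    """A complete generated trial: the four analysis tables plus truth."""

    baseline: pd.DataFrame
    arms: pd.DataFrame       # participant_id, arm
    usage: pd.DataFrame      # participant_id, week_1..week_52 (observed arm)
    followup: pd.DataFrame   # participant_id, wave, completed, gad7, phq9
    truth: TruthRecord
    config: GeneratorConfig


def _rng(config: GeneratorConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), stage]))


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the baseline table: demographics, covariates, scores.

    Every participant is eligible (GAD-7 >= 10 or PHQ-9 >= 10); baseline
    scores are redrawn for ineligible draws up to
    ``config.max_rejection_rounds`` rounds, after which a ValueError is
    raised (an infeasible score configuration).
    """
    n = config.n
    rng = _rng(config, _STAGE_COHORT)
    cols: dict[str, np.ndarray] = {}
    ids = np.array([f"P{i:05d}" for i in range(n)])
    cols["participant_id"] = ids

    female = rng.random(n) < config.female_fraction
    mexico = rng.random(n) < config.mexico_fraction
    # universities: U1-U3 in Colombia, U4-U7 in Mexico; U1/U4/U5 have clinics
    uni = np.empty(n, dtype=object)
    col_idx = rng.choice(3, size=n, p=[0.4, 0.35, 0.25])
    mex_idx = rng.choice(4, size=n, p=[0.35, 0.25, 0.2, 0.2])
    uni[~mexico] = np.array(["U1", "U2", "U3"])[col_idx[~mexico]]
    uni[mexico] = np.array(["U4", "U5", "U6", "U7"])[mex_idx[mexico]]
    has_clinic = np.isin(uni, ("U1", "U4", "U5"))
    waitlist = has_clinic & (rng.random(n) < 0.32)
    clinic_status = np.where(
        waitlist, "waitlist", np.where(has_clinic, "clinic_campus", "no_clinic")
    )
    orientation = rng.choice(
        codebook.SEXUAL_ORIENTATIONS, size=n, p=[0.695, 0.046, 0.149, 0.110]
    )
    age_group = rng.choice(
        codebook.AGE_GROUPS, size=n, p=[0.268, 0.190, 0.301, 0.241]
    )
    first_gen = rng.random(n) < 0.56
    employed = rng.random(n) < 0.35

    # latent baseline severity drives scores and a few covariates; the
    # latent is rejection-sampled jointly with the scores conditional on
    # eligibility, so accepted z_sev reflects the eligible population
    z_sev = np.zeros(n)
    gad7 = np.zeros(n, dtype=int)
    phq9 = np.zeros(n, dtype=int)
    pending = np.ones(n, dtype=bool)
    rounds = 0
    while pending.any():
        if rounds >= config.max_rejection_rounds:
            raise ValueError(
                "eligibility unreachable under the configured score model"
            )
        m = int(pending.sum())
        z = rng.standard_normal(m)
        g = np.clip(np.round(9.5 + 3.5 * z + 3.0 * rng.standard_normal(m)), 0, GAD7_MAX)
        p = np.clip(np.round(11.5 + 4.0 * z + 3.2 * rng.standard_normal(m)), 0, PHQ9_MAX)
        ok = (g >= 10) | (p >= 10)
        idx = np.flatnonzero(pending)[ok]
        z_sev[idx] = z[ok]
        gad7[idx] = g[ok].astype(int)
        phq9[idx] = p[ok].astype(int)
        pending[idx] = False
        rounds += 1

    cols["country"] = np.where(mexico, "Mexico", "Colombia")
    cols["university"] = uni
    cols["clinic_status"] = clinic_status
    cols["sex"] = np.where(female, "female", "male")
    cols["sexual_orientation"] = orientation
    cols["age_group"] = age_group

    def _scale(base, load, sd, low, high, integer=False):
        x = base + load * z_sev + sd * rng.standard_normal(n)
        x = np.clip(x, low, high)
        return np.round(x).astype(int) if integer else np.round(x, 2)

    phq_ads0 = gad7 + phq9
    cols.update({
        "female": female.astype(int),
        "age_20": (age_group == "20").astype(int),
        "age_21_22": (age_group == "21-22").astype(int),
        "age_23_plus": (age_group == "23+").astype(int),
        "sexual_minority": (orientation != "heterosexual").astype(int),
        "employed": employed.astype(int),
        "mexico": mexico.astype(int),
        "first_generation": first_gen.astype(int),
        "waitlist_recruited": (clinic_status == "waitlist").astype(int),
        "clinic_campus": (clinic_status == "clinic_campus").astype(int),
        "unam": (uni == "U4").astype(int),
        "covid_financial_stress": _scale(4.5, 0.8, 2.2, 0, 10),
        "covid_infection_household": (rng.random(n) < 0.30).astype(int),
        "sexual_assault_past_year": (rng.random(n) < 0.08).astype(int),
        "chronic_health_stressors": _scale(3.0, 0.6, 2.0, 0, 10),
        "mde_months_past_year": _scale(3.0, 1.2, 2.5, 0, 12, integer=True),
        "high_baseline_score": ((phq_ads0 >= 20) & (phq9 >= 10)).astype(int),
        "age_of_onset_early": (rng.random(n) < 0.45).astype(int),
        "work_activity_impairment": _scale(4.0, 1.5, 2.2, 0, 10),
        "sad_situational": _scale(6.0, 1.8, 3.2, 0, 16),
        "social_anxiety_disorder": (expit(-0.8 + 0.6 * z_sev) > rng.random(n)).astype(int),
        "phobia_history": (rng.random(n) < 0.25).astype(int),
        "lifetime_comorbidity_count": _scale(1.8, 0.7, 1.2, 0, 6, integer=True),
        "prior_treatment": (rng.random(n) < 0.40).astype(int),
        "psych_med_current": (rng.random(n) < 0.15).astype(int),
        "role_impairment_home": _scale(3.5, 1.0, 2.3, 0, 10),
        "role_impairment_relationships": _scale(3.8, 1.0, 2.4, 0, 10),
        "underweight": (rng.random(n) < 0.10).astype(int),
        "loneliness": _scale(8.0, 1.6, 3.0, 0, 16),
        "confidant_count": _scale(2.5, -0.4, 1.8, 0, 10, integer=True),
        "irritability": _scale(5.0, 1.0, 2.2, 0, 10),
        "alexithymia": _scale(4.5, 0.9, 2.2, 0, 10),
        "negative_urgency": _scale(4.8, 0.8, 2.2, 0, 10),
        "openness": _scale(6.0, 0.0, 2.0, 0, 10),
        "helpfulness_reminders": _scale(1.8, 0.1, 0.8, 0, 3),
        "helpfulness_texting": _scale(1.6, 0.1, 0.8, 0, 3),
        "desire_stress_features": _scale(2.0, 0.2, 0.7, 0, 3),
        "desire_sleep_features": _scale(1.9, 0.2, 0.7, 0, 3),
        "gad7_0": gad7,
        "phq9_0": phq9,
    })
    df = pd.DataFrame(cols)
    if n:
        assert all(
            is_eligible(SymptomScores(Wave.BASELINE, True, int(g), int(p)))
            for g, p in zip(df["gad7_0"].head(50), df["phq9_0"].head(50))
        )
    return df


# ---------------------------------------------------------------------------
# randomization


def randomization_stratum(cohort: pd.DataFrame) -> pd.Series:
    """Stratum label: sex x GAD-7 severity band x PHQ-9 severity band."""
    gad = cohort["gad7_0"].map(lambda s: severity_category("GAD-7", int(s)).value)
    phq = cohort["phq9_0"].map(lambda s: severity_category("PHQ-9", int(s)).value)
    return cohort["sex"].astype(str) + "|" + gad + "|" + phq


def block_randomize(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Permuted-block 1:1:1 assignment within sex x severity strata.

    Within every stratum, complete blocks of ``config.block_size`` are
    balanced exactly; a final partial block is the truncation of a fresh
    permuted block, so per-stratum arm counts differ by at most one per
    block.  Assignment depends only on the stratum sequence, never on
    potential outcomes.
    """
    rng = _rng(config, _STAGE_RAND)
    strata = randomization_stratum(cohort)
    arm = np.empty(len(cohort), dtype=object)
    reps = config.block_size // len(ARMS)
    base_block = np.repeat(np.arange(len(ARMS)), reps)
    for stratum in sorted(strata.unique()):
        idx = np.flatnonzero((strata == stratum).to_numpy())
        assigned = []
        while len(assigned) < len(idx):
            block = base_block[rng.permutation(len(base_block))]
            assigned.extend(block.tolist())
        labels = np.array(ARMS, dtype=object)[np.array(assigned[: len(idx)])]
        arm[idx] = labels
    return pd.DataFrame(
        {"participant_id": cohort["participant_id"].to_numpy(), "arm": arm,
         "stratum": strata.to_numpy()}
    )


# ---------------------------------------------------------------------------
# usage


@lru_cache(maxsize=32)
def _signal_loading(
    r2: float, p_engage: float, q_week: float, mu: float, sigma: float
) -> float:
    """Loading beta on the latent covariate score s.t. the population R^2
    of log1p(weeks-13-52 minutes) on baseline covariates equals ``r2``.

    Solved by bisection against a Monte-Carlo population R^2 computed as
    the correlation-of-independent-replicates identity: for two usage
    draws T1, T2 sharing the same covariate score s,
    Cov(T1, T2) = Var(E[T | s]), hence R^2 = Cov(T1, T2) / Var(T).
    """
    if r2 <= 0 or p_engage <= 0:
        return 0.0
    m, weeks = 60_000, len(LATE_WEEKS)
    rng = np.random.default_rng(np.random.SeedSequence([987_654_321]))
    s = rng.standard_normal(m)
    u = [rng.random((m, 1)) for _ in range(2)]          # engagement draws
    uw = [rng.random((m, weeks)) for _ in range(2)]     # weekly-use draws
    ln = [
        np.exp(mu + sigma * rng.standard_normal((m, weeks))) for _ in range(2)
    ]

    def pop_r2(beta: float) -> float:
        c = _recenter_logit(p_engage, beta * s)
        p_i = expit(c + beta * s)[:, None]
        ts = []
        for k in range(2):
            engaged = u[k] < p_i
            mins = np.where(engaged & (uw[k] < q_week), ln[k], 0.0)
            ts.append(np.log1p(mins.sum(axis=1)))
        t1, t2 = ts
        v = 0.5 * (t1.var() + t2.var())
        if v == 0:
            return 0.0
        return float(np.cov(t1, t2)[0, 1] / v)

    lo, hi = 0.0, 12.0
    if pop_r2(hi) < r2:
        raise ValueError(f"compliance_signal_r2={r2} not achievable by this profile")
    for _ in range(22):
        mid = (lo + hi) / 2
        if pop_r2(mid) < r2:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _recenter_logit(target_mean: float, shift: np.ndarray) -> float:
    """Intercept c with mean(expit(c + shift)) == target_mean (in-sample)."""
    if target_mean <= 0:
        return -math.inf
    if target_mean >= 1:
        return math.inf
    lo, hi = -20.0, 20.0
    for _ in range(50):
        mid = (lo + hi) / 2
        if expit(mid + shift).mean() < target_mean:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _usage_for_arm(
    cohort: pd.DataFrame, arm: str, config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Weekly minutes (n x 52) as if every participant were in ``arm``."""
    n = len(cohort)
    out = np.zeros((n, N_WEEKS))
    if n == 0:
        return out
    s = codebook.signal_score(cohort)
    for period, week_idx in (("early", EARLY_WEEKS), ("late", LATE_WEEKS)):
        prof = config.usage_profiles[arm][period]
        if prof.p_engage <= 0 or prof.q_week <= 0:
            continue
        if period == "late" and arm in ("guided", "self-guided"):
            # signal loading calibrated on the self-guided late profile,
            # the arm in which the compliance model is trained
            ref = config.usage_profiles["self-guided"]["late"]
            beta = _signal_loading(
                config.compliance_signal_r2, ref.p_engage, ref.q_week,
                ref.mu, ref.sigma,
            )
            c = _recenter_logit(prof.p_engage, beta * s)
            p_engage_i = expit(c + beta * s)
        else:
            p_engage_i = np.full(n, prof.p_engage)
        engaged = rng.random(n) < p_engage_i
        w = len(week_idx)
        active = (rng.random((n, w)) < prof.q_week) & engaged[:, None]
        minutes = np.where(
            active, np.exp(prof.mu + prof.sigma * rng.standard_normal((n, w))), 0.0
        )
        out[:, [i - 1 for i in week_idx]] = np.round(minutes, 1)
    return out


def simulate_usage(
    cohort: pd.DataFrame, arms: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Observed weekly usage matrix (TAU rows are all zero)."""
    potential = potential_usage(cohort, config)
    arm_vec = arms.set_index("participant_id")["arm"].reindex(
        cohort["participant_id"]
    ).to_numpy()
    out = np.zeros((len(cohort), N_WEEKS))
    for arm in ARMS:
        mask = arm_vec == arm
        out[mask] = potential[arm][mask]
    df = pd.DataFrame(out, columns=list(WEEK_COLS))
    df.insert(0, "participant_id", cohort["participant_id"].to_numpy())
    return df


def potential_usage(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> dict[str, np.ndarray]:
    """Counterfactual usage matrices under each arm (shared per-arm seeds)."""
    return {
        arm: _usage_for_arm(
            cohort, arm, config,
            np.random.default_rng(
                np.random.SeedSequence([int(config.seed) % (2**31), _STAGE_USAGE, k])
            ),
        )
        for k, arm in enumerate(ARMS)
    }


# ---------------------------------------------------------------------------
# outcomes


def _split_phq_ads(
    total: np.ndarray, frac_gad: np.ndarray, jitter: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split an integer PHQ-ADS total into valid GAD-7/PHQ-9 components."""
    gad = np.round(total * frac_gad + jitter)
    gad = np.clip(gad, np.maximum(0, total - PHQ9_MAX), np.minimum(GAD7_MAX, total))
    phq = total - gad
    return gad.astype(int), phq.astype(int)


def _outcomes_for_arm(
    cohort: pd.DataFrame, arm: str, usage: np.ndarray, config: GeneratorConfig,
    noise: dict[str, np.ndarray],
) -> pd.DataFrame:
    eff = config.effects
    a = ARMS.index(arm)
    y0 = (cohort["gad7_0"] + cohort["phq9_0"]).to_numpy(dtype=float)
    early = np.log1p(usage[:, [i - 1 for i in EARLY_WEEKS]].sum(axis=1))
    late = np.log1p(usage[:, [i - 1 for i in LATE_WEEKS]].sum(axis=1))

    y3 = (
        eff.drift3 + eff.rho3 * y0 + eff.arm3[a]
        - eff.usage3_coef * early + eff.noise3_sd * noise["e3"]
    )
    y3 = np.clip(np.round(y3), 0, PHQ_ADS_MAX)
    y12 = (
        eff.drift12 + eff.rho12_baseline * y0 + eff.rho12_y3 * y3 + eff.arm12[a]
        - eff.usage12_coef * late + eff.noise12_sd * noise["e12"]
    )
    y12 = np.clip(np.round(y12), 0, PHQ_ADS_MAX)

    frac = cohort["gad7_0"].to_numpy() / np.maximum(y0, 1.0)
    g3, p3 = _split_phq_ads(y3, frac, noise["split3"])
    g12, p12 = _split_phq_ads(y12, frac, noise["split12"])
    return pd.DataFrame({
        "participant_id": cohort["participant_id"].to_numpy(),
        "gad7_3": g3, "phq9_3": p3, "gad7_12": g12, "phq9_12": p12,
    })


def _outcome_noise(n: int, config: GeneratorConfig) -> dict[str, np.ndarray]:
    rng = _rng(config, _STAGE_OUTCOME)
    return {
        "e3": rng.standard_normal(n),
        "e12": rng.standard_normal(n),
        "split3": 1.0 * rng.standard_normal(n),
        "split12": 1.0 * rng.standard_normal(n),
    }


def simulate_outcomes(
    cohort: pd.DataFrame, arms: pd.DataFrame, usage: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Pre-dropout follow-up scores at 3 and 12 months for the assigned arm.

    Noise draws depend only on the participant (not the arm), so under a
    null effect map the three arms' potential outcomes are identical.
    """
    noise = _outcome_noise(len(cohort), config)
    arm_vec = arms.set_index("participant_id")["arm"].reindex(
        cohort["participant_id"]
    ).to_numpy()
    mat = usage[list(WEEK_COLS)].to_numpy(dtype=float)
    pieces = []
    for arm in ARMS:
        mask = arm_vec == arm
        if mask.any():
            pieces.append(
                _outcomes_for_arm(cohort[mask], arm, mat[mask], config,
                                  {k: v[mask] for k, v in noise.items()})
            )
    if not pieces:
        return pd.DataFrame(
            columns=["participant_id", "gad7_3", "phq9_3", "gad7_12", "phq9_12"]
        )
    out = pd.concat(pieces, ignore_index=True)
    return out.set_index("participant_id").reindex(
        cohort["participant_id"]
    ).reset_index()


def potential_outcomes(
    cohort: pd.DataFrame, config: GeneratorConfig,
    usage_by_arm: dict[str, np.ndarray] | None = None,
) -> TruthRecord:
    """Potential outcomes under every arm, sharing all noise draws."""
    if usage_by_arm is None:
        usage_by_arm = potential_usage(cohort, config)
    noise = _outcome_noise(len(cohort), config)
    data = {"participant_id": cohort["participant_id"].to_numpy()}
    for arm in ARMS:
        df = _outcomes_for_arm(cohort, arm, usage_by_arm[arm], config, noise)
        for wave, (g, p) in (("3", ("gad7_3", "phq9_3")),
                             ("12", ("gad7_12", "phq9_12"))):
            data[f"phqads_{wave}_{arm}"] = (df[g] + df[p]).to_numpy()
            data[f"remission_{wave}_{arm}"] = (
                (df[g] <= 4) & (df[p] <= 4)
            ).to_numpy().astype(float)
    return TruthRecord(pd.DataFrame(data))


# ---------------------------------------------------------------------------
# missingness


def simulate_missingness(
    cohort: pd.DataFrame, arms: pd.DataFrame, outcomes: pd.DataFrame,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Completion flags per wave under the logistic MAR dropout model."""
    n = len(cohort)
    rng = _rng(config, _STAGE_MISS)
    d = config.dropout
    arm_vec = arms.set_index("participant_id")["arm"].reindex(
        cohort["participant_id"]
    ).to_numpy()
    arm_idx = np.array([ARMS.index(a) for a in arm_vec]) if n else np.array([], int)
    mexico = cohort["mexico"].to_numpy(dtype=float) if n else np.array([])
    waitlist = cohort["waitlist_recruited"].to_numpy(dtype=float) if n else np.array([])
    clinic = cohort["clinic_campus"].to_numpy(dtype=float) if n else np.array([])
    y0 = (cohort["gad7_0"] + cohort["phq9_0"]).to_numpy(dtype=float) if n else np.array([])
    z0 = (y0 - 25.0) / 7.0

    lin3 = (
        d.intercept3 + np.asarray(d.arm3)[arm_idx] + d.mexico3 * mexico
        + d.waitlist3 * waitlist + d.clinic_campus3 * clinic + d.severity3 * z0
    )
    c3 = rng.random(n) < expit(lin3)

    y3 = (outcomes["gad7_3"] + outcomes["phq9_3"]).to_numpy(dtype=float)
    z3 = np.where(c3, (y3 - 15.0) / 8.0, 0.0)
    lin12 = (
        d.intercept12 + np.asarray(d.arm12)[arm_idx] + d.mexico12 * mexico
        + d.waitlist12 * waitlist + d.clinic_campus12 * clinic + d.severity12 * z0
        + d.completed3_carry * c3 + d.y3_coef * z3
    )
    c12 = rng.random(n) < expit(lin12)
    return pd.DataFrame({
        "participant_id": cohort["participant_id"].to_numpy(),
        "completed_3": c3, "completed_12": c12,
    })


# ---------------------------------------------------------------------------
# full trial


def followup_table(
    outcomes: pd.DataFrame, flags: pd.DataFrame
) -> pd.DataFrame:
    """Long-format follow-up table; scores blank when not completed."""
    rows = []
    merged = outcomes.merge(flags, on="participant_id")
    for wave, (g, p, c) in (
        (3, ("gad7_3", "phq9_3", "completed_3")),
        (12, ("gad7_12", "phq9_12", "completed_12")),
    ):
        rows.append(pd.DataFrame({
            "participant_id": merged["participant_id"],
            "wave": wave,
            "completed": merged[c].astype(int),
            "gad7": merged[g].where(merged[c]),
            "phq9": merged[p].where(merged[c]),
        }))
    return pd.concat(rows, ignore_index=True)


def generate_trial(config: GeneratorConfig) -> SyntheticTrial:
    """Generate a complete synthetic trial with ground truth."""
    cohort = generate_cohort(config)
    arms = block_randomize(cohort, config)
    usage_by_arm = potential_usage(cohort, config)
    arm_vec = arms["arm"].to_numpy()
    obs = np.zeros((len(cohort), N_WEEKS))
    for arm in ARMS:
        mask = arm_vec == arm
        obs[mask] = usage_by_arm[arm][mask]
    usage = pd.DataFrame(obs, columns=list(WEEK_COLS))
    usage.insert(0, "participant_id", cohort["participant_id"].to_numpy())
    outcomes = simulate_outcomes(cohort, arms, usage, config)
    truth = potential_outcomes(cohort, config, usage_by_arm)
    flags = simulate_missingness(cohort, arms, outcomes, config)
    return SyntheticTrial(
        baseline=cohort,
        arms=arms[["participant_id", "arm"]],
        usage=usage,
        followup=followup_table(outcomes, flags),
        truth=truth,
        config=config,
    )
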