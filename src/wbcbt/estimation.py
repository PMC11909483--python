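"""Doubly robust estimation of per-arm outcomes under attrition.

Per-arm mean outcomes (joint-remission rate, mean PHQ-ADS) at a
follow-up wave are estimated with a targeted estimator that combines an
outcome regression with a response-propensity model: outcome-regression
predictions are updated by a one-dimensional logistic fluctuation
(weighted by the inverse response propensity) on the bounded-rescaled
outcome, and standard errors come from the empirical variance of the
efficient-influence-curve contributions.  The estimator is consistent if
either nuisance model is correctly specified, and the fluctuation step
keeps estimates inside the outcome's natural bounds under extreme
weights.  A plain augmented-IPW mode is provided for cross-checking.

A longitudinal (sequential-regression) variant uses partial follow-up —
participants who responded at 3 months but not at 12 — to adjust the
12-month estimates; participants with 12-month data but no 3-month data
are handled upstream by multiple imputation with predictive mean
matching (:func:`impute_3mo_pmm`) and Rubin pooling
(:func:`pool_rubin`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit
from sklearn.linear_model import LinearRegression, LogisticRegression

from .codebook import ARMS
from .scales import PHQ_ADS_MAX, REMISSION_THRESHOLD

logger = logging.getLogger(__name__)

Outcome = Literal["joint_remission", "phq_ads_mean"]
WaveLabel = Literal["3mo", "12mo"]

#: covariates adjusted for by default (drivers of dropout plus severity)
DEFAULT_ADJUSTMENT_COVARIATES = (
    "mexico",
    "waitlist_recruited",
    "clinic_campus",
    "female",
    "phq_ads_0",
)


@dataclass(frozen=True)
class EstimandSpec:
    outcome: Outcome
    wave: WaveLabel

    def __post_init__(self) -> None:
        if self.outcome not in ("joint_remission", "phq_ads_mean"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.wave not in ("3mo", "12mo"):
            raise ValueError(f"unknown wave {self.wave!r}")

    @property
    def scale(self) -> float:
        """Reporting scale: remission in percent, PHQ-ADS in scale points."""
        return 100.0 if self.outcome == "joint_remission" else float(PHQ_ADS_MAX)


@dataclass(frozen=True)
class EstimatorOptions:
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT_COVARIATES
    truncation: float = 0.01
    mode: Literal["tmle", "aipw"] = "tmle"
    #: intercept-only nuisance models (useful for misspecification studies)
    outcome_model: Literal["default", "intercept_only"] = "default"
    propensity_model: Literal["default", "intercept_only"] = "default"


@dataclass
class AdjustedEstimate:
    arm: str
    value: float
    se: float
    outcome: Outcome
    wave: WaveLabel
    n_arm: int

    @property
    def variance(self) -> float:
        return self.se**2

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.value - z * self.se, self.value + z * self.se


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    difference: float
    se: float
    chi2: float
    df: int
    p: float
    outcome: Outcome | None = None
    wave: WaveLabel | None = None


@dataclass
class OverallTest:
    chi2: float
    df: int
    p: float


@dataclass
class NuisanceFits:
    """Fitted response propensities and outcome-regression predictions."""

    propensity: np.ndarray                  # P(complete | X, assigned arm)
    outcome_pred: dict[str, np.ndarray]     # per-arm prediction on [0, 1]
    truncation: float
    clipped: int = 0                        # propensities raised to the bound
    fallbacks: list[str] = field(default_factory=list)


@dataclass
class ArmEstimates:
    """Per-arm adjusted estimates plus influence contributions.

    The influence matrix (n participants x arms, reporting scale) yields
    the covariances used by pairwise contrasts and the 2-df overall test.
    """

    estimates: dict[str, AdjustedEstimate]
    influence: pd.DataFrame
    spec: EstimandSpec

    def covariance(self, arm_a: str, arm_b: str) -> float:
        n = len(self.influence)
        ic_a = self.influence[arm_a].to_numpy()
        ic_b = self.influence[arm_b].to_numpy()
        return float((ic_a * ic_b).sum() / n**2)

    def contrast(self, arm_a: str, arm_b: str) -> ContrastResult:
        return contrast(
            self.estimates[arm_a], self.estimates[arm_b],
            cov=self.covariance(arm_a, arm_b),
        )

    def overall(self) -> OverallTest:
        arms = list(self.estimates)
        cov = np.array([[self.covariance(a, b) for b in arms] for a in arms])
        return overall_test([self.estimates[a] for a in arms], cov)


# ---------------------------------------------------------------------------
# analysis frame


def build_analysis_frame(
    baseline: pd.DataFrame,
    arms: pd.DataFrame,
    followup: pd.DataFrame,
    usage: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the wide per-participant analysis table.

    Adds ``phq_ads_0``, per-wave completion flags, per-wave outcome
    columns (``remission_{3,12}``, ``phq_ads_{3,12}``) and, when a usage
    table is supplied, total minutes per period.
    """
    df = baseline.copy()
    df["phq_ads_0"] = df["gad7_0"] + df["phq9_0"]
    df = df.merge(arms[["participant_id", "arm"]], on="participant_id", how="left")
    for wave in (3, 12):
        sub = followup[followup["wave"] == wave].set_index("participant_id")
        sub = sub.reindex(df["participant_id"])
        df[f"completed_{wave}"] = sub["completed"].fillna(0).astype(bool).to_numpy()
        gad = sub["gad7"].to_numpy(dtype=float)
        phq = sub["phq9"].to_numpy(dtype=float)
        df[f"phq_ads_{wave}"] = gad + phq
        df[f"remission_{wave}"] = np.where(
            np.isnan(gad), np.nan,
            ((gad <= REMISSION_THRESHOLD) & (phq <= REMISSION_THRESHOLD)).astype(float),
        )
    return df


def _wave_columns(spec: EstimandSpec) -> tuple[str, str]:
    wave = "3" if spec.wave == "3mo" else "12"
    out = "remission" if spec.outcome == "joint_remission" else "phq_ads"
    return f"{out}_{wave}", f"completed_{wave}"


def _scaled_outcome(frame: pd.DataFrame, spec: EstimandSpec) -> np.ndarray:
    """Outcome on [0, 1] (NaN where not observed)."""
    ycol, _ = _wave_columns(spec)
    y = frame[ycol].to_numpy(dtype=float)
    if spec.outcome == "phq_ads_mean":
        y = y / PHQ_ADS_MAX
    return y


# ---------------------------------------------------------------------------
# nuisance models


def _design(frame: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    return frame[list(covariates)].to_numpy(dtype=float)


def _fit_binary(X: np.ndarray, y: np.ndarray, label: str,
                fallbacks: list[str]) -> "callable":
    """Logistic fit returning a P(y=1 | X) predictor, with graceful
    degradation to the empirical mean on degenerate designs."""
    mean = float(np.mean(y)) if len(y) else 0.5
    if len(np.unique(y)) < 2 or X.shape[1] == 0 or len(y) < X.shape[1] + 2:
        if len(np.unique(y)) < 2:
            fallbacks.append(f"{label}: constant response, intercept-only fit")
        return lambda Xn: np.full(len(Xn), mean)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LogisticRegression(C=1e4, max_iter=500)
            model.fit(X, y)
        return lambda Xn: model.predict_proba(Xn)[:, 1]
    except Exception:  # pragma: no cover - defensive
        fallbacks.append(f"{label}: fit failure, intercept-only fallback")
        return lambda Xn: np.full(len(Xn), mean)


def _fit_continuous(X: np.ndarray, y: np.ndarray, label: str,
                    fallbacks: list[str]) -> "callable":
    """Linear fit on the [0, 1] scale, predictions clipped to [0, 1]."""
    mean = float(np.mean(y)) if len(y) else 0.5
    if X.shape[1] == 0 or len(y) < X.shape[1] + 2:
        fallbacks.append(f"{label}: degenerate design, intercept-only fit")
        return lambda Xn: np.full(len(Xn), mean)
    model = LinearRegression()
    model.fit(X, y)
    return lambda Xn: np.clip(model.predict(Xn), 0.0, 1.0)


def fit_nuisances(
    frame: pd.DataFrame,
    spec: EstimandSpec,
    options: EstimatorOptions = EstimatorOptions(),
) -> NuisanceFits:
    """Fit the response-propensity and outcome-regression models.

    The propensity model is a pooled logistic regression of the wave's
    completion flag on baseline covariates and arm indicators, truncated
    below at ``options.truncation``.  Outcome regressions are fit per
    arm among completers (logistic for remission, linear for PHQ-ADS on
    the [0, 1] scale) and produce a prediction for every participant
    under every arm.
    """
    fallbacks: list[str] = []
    _, ccol = _wave_columns(spec)
    completed = frame[ccol].to_numpy(dtype=bool)
    y = _scaled_outcome(frame, spec)
    arm = frame["arm"].to_numpy()

    X = _design(frame, options.covariates)
    arm_dummies = np.column_stack([(arm == a).astype(float) for a in ARMS[1:]])
    Xg = np.hstack([X, arm_dummies])
    if options.propensity_model == "intercept_only":
        Xg = np.empty((len(frame), 0))
    if completed.all():
        g = np.ones(len(frame))
    else:
        g = _fit_binary(Xg, completed.astype(int), "propensity", fallbacks)(Xg)
    clipped = int((g < options.truncation).sum())
    g = np.clip(g, options.truncation, 1.0)

    Xq = X if options.outcome_model == "default" else np.empty((len(frame), 0))
    preds: dict[str, np.ndarray] = {}
    fit = _fit_binary if spec.outcome == "joint_remission" else _fit_continuous
    for a in ARMS:
        rows = (arm == a) & completed
        if not rows.any():
            raise ValueError(f"no completed outcomes in arm {a!r}")
        predict = fit(Xq[rows], y[rows], f"outcome[{a}]", fallbacks)
        preds[a] = predict(Xq)
    for msg in fallbacks:
        logger.warning(msg)
    return NuisanceFits(g, preds, options.truncation, clipped, fallbacks)


# ---------------------------------------------------------------------------
# targeted estimation


_BOUND = 1e-6


def dr_estimate(
    frame: pd.DataFrame,
    spec: EstimandSpec,
    nuisances: NuisanceFits | None = None,
    options: EstimatorOptions = EstimatorOptions(),
) -> ArmEstimates:
    """Targeted doubly robust per-arm estimates at one wave.

    For arm ``a`` with empirical randomization share ``pi_a`` and
    response propensity ``g``, outcome-regression predictions are
    fluctuated with the clever weight ``1{A=a, completed}/(pi_a g)`` and
    the estimate is the mean fluctuated prediction over the full cohort.
    In ``aipw`` mode the fluctuation is skipped and the usual augmented
    inverse-probability-weighted estimator is computed instead.
    """
    if nuisances is None:
        nuisances = fit_nuisances(frame, spec, options)
    n = len(frame)
    if n == 0:
        raise ValueError("empty analysis frame")
    _, ccol = _wave_columns(spec)
    completed = frame[ccol].to_numpy(dtype=bool)
    yfull = _scaled_outcome(frame, spec)
    arm = frame["arm"].to_numpy()

    estimates: dict[str, AdjustedEstimate] = {}
    influence: dict[str, np.ndarray] = {}
    for a in ARMS:
        in_arm = arm == a
        n_arm = int(in_arm.sum())
        if n_arm == 0:
            raise ValueError(f"arm {a!r} has no participants")
        if not (in_arm & completed).any():
            raise ValueError(f"no completed outcomes in arm {a!r}")
        pi_a = n_arm / n
        h = np.where(in_arm & completed, 1.0 / (pi_a * nuisances.propensity), 0.0)
        q = nuisances.outcome_pred[a]
        y = np.where(in_arm & completed, yfull, 0.0)
        if options.mode == "tmle":
            rows = in_arm & completed
            # fluctuate on the completer rows, update q everywhere
            lq = logit(np.clip(q, _BOUND, 1 - _BOUND))

            def score(eps: float) -> float:
                return float(np.sum(h[rows] * (yfull[rows] - expit(lq[rows] + eps))))

            lo, hi = -15.0, 15.0
            if score(lo) <= 0:
                eps = lo
            elif score(hi) >= 0:
                eps = hi
            else:
                eps = optimize.brentq(score, lo, hi, xtol=1e-12)
            qstar = expit(lq + eps)
            psi = float(qstar.mean())
            ic = h * (y - np.where(in_arm & completed, qstar, 0.0)) + qstar - psi
        else:  # aipw
            psi = float(np.mean(h * (y - np.where(in_arm & completed, q, 0.0)) + q))
            ic = h * (y - np.where(in_arm & completed, q, 0.0)) + q - psi
        scale = spec.scale
        se = float(np.std(ic, ddof=0) / np.sqrt(n)) * scale
        estimates[a] = AdjustedEstimate(a, psi * scale, se, spec.outcome, spec.wave, n_arm)
        influence[a] = ic * scale
    return ArmEstimates(estimates, pd.DataFrame(influence), spec)


def longitudinal_dr_estimate(
    frame: pd.DataFrame,
    spec: EstimandSpec,
    options: EstimatorOptions = EstimatorOptions(),
) -> ArmEstimates:
    """Sequential-regression doubly robust estimate at 12 months.

    Uses 3-month information (the observed 3-month PHQ-ADS score) for
    participants with partial follow-up: the 12-month outcome is first
    regressed on baseline covariates plus the 3-month score among
    double completers, those (fluctuated) predictions are regressed on
    baseline covariates among 3-month completers, and each stage is
    targeted with its cumulative response propensity.  When no
    participant has partial follow-up (3-month data without 12-month
    data) the sequential stage carries no information and the estimator
    reduces exactly to :func:`dr_estimate`.
    """
    if spec.wave != "12mo":
        raise ValueError("the longitudinal estimator targets the 12-month wave")
    c3 = frame["completed_3"].to_numpy(dtype=bool)
    c12 = frame["completed_12"].to_numpy(dtype=bool)
    partial = c3 & ~c12
    if not partial.any():
        return dr_estimate(frame, spec, options=options)

    n = len(frame)
    yfull = _scaled_outcome(frame, spec)
    arm = frame["arm"].to_numpy()
    X = _design(frame, options.covariates)
    if options.outcome_model == "intercept_only":
        X = np.empty((n, 0))
    y3 = frame["phq_ads_3"].to_numpy(dtype=float)
    y3_z = np.where(c3, (np.nan_to_num(y3) - np.nanmean(y3[c3])) / PHQ_ADS_MAX, 0.0)
    X2 = np.column_stack([X, y3_z])

    fallbacks: list[str] = []
    arm_dummies = np.column_stack([(arm == a).astype(float) for a in ARMS[1:]])
    Xg = np.hstack([_design(frame, options.covariates), arm_dummies])
    if options.propensity_model == "intercept_only":
        Xg = np.empty((n, 0))
    g3 = (np.ones(n) if c3.all()
          else _fit_binary(Xg, c3.astype(int), "g3", fallbacks)(Xg))
    g3 = np.clip(g3, options.truncation, 1.0)
    Xg2 = np.hstack([Xg, y3_z[:, None]])
    if c12[c3].all():
        g12 = np.ones(n)
    else:
        g12 = _fit_binary(Xg2[c3], c12[c3].astype(int), "g12", fallbacks)(Xg2)
    g12 = np.clip(g12, options.truncation, 1.0)

    fit = _fit_binary if spec.outcome == "joint_remission" else _fit_continuous
    estimates: dict[str, AdjustedEstimate] = {}
    influence: dict[str, np.ndarray] = {}
    for a in ARMS:
        in_arm = arm == a
        n_arm = int(in_arm.sum())
        pi_a = n_arm / n if n_arm else 0.0
        if not (in_arm & c3 & c12).any():
            raise ValueError(f"no completed outcomes in arm {a!r}")
        both = in_arm & c3 & c12
        # stage 2: E[Y12 | X, 3-month data] among double completers
        q2 = fit(X2[both], yfull[both], f"q2[{a}]", fallbacks)(X2)
        h2 = np.where(both, 1.0 / (pi_a * g3 * g12), 0.0)
        lq2 = logit(np.clip(q2, _BOUND, 1 - _BOUND))

        def score2(eps: float) -> float:
            return float(np.sum(h2[both] * (yfull[both] - expit(lq2[both] + eps))))

        eps2 = _solve_score(score2)
        q2s = expit(lq2 + eps2)
        # stage 1: regress targeted stage-2 predictions on baseline
        w1 = in_arm & c3
        q1 = _fit_continuous(X[w1], q2s[w1], f"q1[{a}]", fallbacks)(X)
        h1 = np.where(w1, 1.0 / (pi_a * g3), 0.0)
        lq1 = logit(np.clip(q1, _BOUND, 1 - _BOUND))

        def score1(eps: float) -> float:
            return float(np.sum(h1[w1] * (q2s[w1] - expit(lq1[w1] + eps))))

        eps1 = _solve_score(score1)
        q1s = expit(lq1 + eps1)
        psi = float(q1s.mean())
        ic = (
            h2 * np.where(both, yfull - q2s, 0.0)
            + h1 * np.where(w1, q2s - q1s, 0.0)
            + q1s - psi
        )
        scale = spec.scale
        se = float(np.std(ic, ddof=0) / np.sqrt(n)) * scale
        estimates[a] = AdjustedEstimate(a, psi * scale, se, spec.outcome, spec.wave, n_arm)
        influence[a] = ic * scale
    for msg in fallbacks:
        logger.warning(msg)
    return ArmEstimates(estimates, pd.DataFrame(influence), spec)


def _solve_score(score) -> float:
    lo, hi = -15.0, 15.0
    if score(lo) <= 0:
        return lo
    if score(hi) >= 0:
        return hi
    return float(optimize.brentq(score, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# multiple imputation (predictive mean matching)


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 20
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.k < 1:
            raise ValueError("k must be at least 1")


def impute_3mo_pmm(
    frame: pd.DataFrame,
    config: ImputationConfig = ImputationConfig(),
    column: str = "phq_ads_3",
    covariates: tuple[str, ...] = DEFAULT_ADJUSTMENT_COVARIATES,
) -> list[pd.DataFrame]:
    """Multiply impute the 3-month value for 12-month-only completers.

    A linear model of the 3-month value on baseline covariates, arm and
    the observed 12-month PHQ-ADS score is fit among double completers;
    each recipient (12-month data, no 3-month data) receives the
    observed value of one of its ``k`` nearest donors by predicted mean.
    Only the recipients' cells differ across the ``m`` returned copies;
    the 3-month completion flag is set on imputed rows so downstream
    estimators treat the filled value as wave-1 information.
    """
    c3 = frame["completed_3"].to_numpy(dtype=bool)
    c12 = frame["completed_12"].to_numpy(dtype=bool)
    recipients = np.flatnonzero(~c3 & c12)
    if len(recipients) == 0:
        return [frame.copy() for _ in range(config.m)]
    donors = np.flatnonzero(c3 & c12)
    if len(donors) == 0:
        raise ValueError("no double completers available as donors")

    X = frame[list(covariates)].to_numpy(dtype=float)
    arm_d = pd.get_dummies(frame["arm"]).to_numpy(dtype=float)
    y12 = frame["phq_ads_12"].to_numpy(dtype=float)
    Z = np.column_stack([X, arm_d, y12])
    y = frame[column].to_numpy(dtype=float)
    model = LinearRegression().fit(Z[donors], y[donors])
    pred = np.full(len(frame), np.nan)
    have_12 = np.flatnonzero(c12)
    pred[have_12] = model.predict(Z[have_12])

    k = min(config.k, len(donors))
    if k < config.k:
        logger.warning("only %d donors available; using all of them", len(donors))
    rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.m):
        filled = frame.copy()
        yimp = y.copy()
        for r in recipients:
            d = donors[np.argsort(np.abs(pred[donors] - pred[r]), kind="stable")[:k]]
            yimp[r] = y[rng.choice(d)]
        filled[column] = yimp
        filled.loc[filled.index[recipients], "completed_3"] = True
        out.append(filled)
    return out


@dataclass
class PooledArmEstimates:
    """Rubin-pooled per-arm estimates with a pooled covariance matrix."""

    estimates: dict[str, AdjustedEstimate]
    cov: np.ndarray                 # pooled covariance, arm order as dict
    spec: EstimandSpec

    def contrast(self, arm_a: str, arm_b: str) -> ContrastResult:
        arms = list(self.estimates)
        i, j = arms.index(arm_a), arms.index(arm_b)
        return contrast(self.estimates[arm_a], self.estimates[arm_b],
                        cov=float(self.cov[i, j]))

    def overall(self) -> OverallTest:
        return overall_test(list(self.estimates.values()), self.cov)


def pool_rubin_arms(results: list[ArmEstimates]) -> PooledArmEstimates:
    """Pool per-arm estimates across imputed datasets (Rubin's rules).

    Pooled values are means across imputations; the pooled covariance is
    the mean within-imputation covariance plus ``(1 + 1/m)`` times the
    between-imputation covariance of the arm estimates.
    """
    if len(results) < 2:
        raise ValueError("pooling requires at least two imputed analyses")
    spec = results[0].spec
    arms = list(results[0].estimates)
    m = len(results)
    values = np.array([[r.estimates[a].value for a in arms] for r in results])
    within = np.mean(
        [[[r.covariance(a, b) for b in arms] for a in arms] for r in results],
        axis=0,
    )
    centered = values - values.mean(axis=0)
    between = centered.T @ centered / (m - 1)
    cov = within + (1 + 1 / m) * between
    pooled = {
        a: AdjustedEstimate(
            a, float(values[:, i].mean()), float(np.sqrt(cov[i, i])),
            spec.outcome, spec.wave, results[0].estimates[a].n_arm,
        )
        for i, a in enumerate(arms)
    }
    return PooledArmEstimates(pooled, cov, spec)


def pool_rubin(estimates: list[AdjustedEstimate]) -> AdjustedEstimate:
    """Combine multiply-imputed estimates by Rubin's rules."""
    if len(estimates) < 2:
        raise ValueError("pooling requires at least two imputed estimates")
    first = estimates[0]
    for e in estimates[1:]:
        if (e.arm, e.outcome, e.wave) != (first.arm, first.outcome, first.wave):
            raise ValueError("cannot pool estimates of different estimands")
    m = len(estimates)
    values = np.array([e.value for e in estimates])
    within = np.mean([e.variance for e in estimates])
    between = values.var(ddof=1)
    total = within + (1 + 1 / m) * between
    return AdjustedEstimate(
        first.arm, float(values.mean()), float(np.sqrt(total)),
        first.outcome, first.wave, first.n_arm,
    )


# ---------------------------------------------------------------------------
# contrasts and tests


def contrast(
    a: AdjustedEstimate, b: AdjustedEstimate, cov: float = 0.0
) -> ContrastResult:
    """Pairwise ARD/AMD with Wald chi-square (1 df)."""
    if (a.outcome, a.wave) != (b.outcome, b.wave):
        raise ValueError("contrast requires estimates of the same estimand")
    diff = a.value - b.value
    var = a.variance + b.variance - 2 * cov
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        if diff != 0.0:
            raise ValueError("zero standard error with a nonzero difference")
        return ContrastResult((a.arm, b.arm), 0.0, 0.0, 0.0, 1, 1.0, a.outcome, a.wave)
    chi2 = (diff / se) ** 2
    p = float(stats.chi2.sf(chi2, 1))
    return ContrastResult((a.arm, b.arm), float(diff), se, float(chi2), 1, p,
                          a.outcome, a.wave)


def overall_test(
    estimates: list[AdjustedEstimate], cov: np.ndarray
) -> OverallTest:
    """2-df Wald test of any overall variation across the three arms.

    Built from two independent contrasts against the last arm; the
    quadratic form is invariant to which contrasts (and which arm
    ordering) are chosen.
    """
    if len(estimates) != 3:
        raise ValueError("overall test requires exactly three arm estimates")
    values = np.array([e.value for e in estimates])
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError("covariance matrix must be 3x3")
    L = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0]])
    d = L @ values
    V = L @ cov @ L.T
    if np.linalg.matrix_rank(V) < 2 or np.linalg.cond(V) > 1e12:
        raise ValueError("singular contrast covariance")
    chi2 = float(d @ np.linalg.solve(V, d))
    return OverallTest(chi2, 2, float(stats.chi2.sf(chi2, 2)))


def pearson_chi2(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("table must contain nonnegative integer counts")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
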