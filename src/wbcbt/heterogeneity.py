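"""Predicted-compliance subgroup (specifier) machinery.

The predicted-compliance score — produced from baseline covariates only —
is dichotomized at a top fraction (default 40%) and used as a specifier
of comparative intervention effects: doubly robust estimates are
recomputed within each stratum, and a contrast-of-contrasts Wald test
assesses whether the self-guided advantage differs between strata.
Attrition tables summarize completion patterns by baseline predictors
with main-effect and predictor-by-arm heterogeneity tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .codebook import ARMS
from . import estimation
from .estimation import (
    AdjustedEstimate,
    ArmEstimates,
    ContrastResult,
    EstimandSpec,
    EstimatorOptions,
    OverallTest,
)

logger = logging.getLogger(__name__)


@dataclass
class SpecifierSplit:
    """Top-fraction dichotomization of predicted-compliance scores."""

    top_fraction: float
    threshold: float
    labels: pd.Series        # 'high' / 'low', indexed by participant_id

    @property
    def n_high(self) -> int:
        return int((self.labels == "high").sum())

    @property
    def n_low(self) -> int:
        return int((self.labels == "low").sum())


@dataclass
class InteractionResult:
    chi2: float
    df: int
    p: float
    delta_high: float
    delta_low: float
    se_high: float
    se_low: float


def dichotomize(scores: pd.Series, top_fraction: float = 0.40) -> SpecifierSplit:
    """Label the ``ceil(n * top_fraction)`` largest scores as 'high'.

    Ties at the threshold are broken by stable participant-id order, so
    the split is deterministic for any score vector.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    n = len(scores)
    if n == 0:
        raise ValueError("no scores to dichotomize")
    n_high = math.ceil(n * top_fraction)
    df = pd.DataFrame({"score": scores})
    df = df.sort_index(kind="stable").sort_values(
        "score", ascending=False, kind="stable"
    )
    high_ids = df.index[:n_high]
    labels = pd.Series("low", index=scores.index, name="compliance_stratum")
    labels[high_ids] = "high"
    threshold = float(df["score"].iloc[n_high - 1])
    return SpecifierSplit(top_fraction, threshold, labels)


def _delta_self_guided(
    frame: pd.DataFrame,
    spec: EstimandSpec,
    options: EstimatorOptions,
    comparator: str,
) -> tuple[float, float]:
    """ARD/AMD of self-guided vs a comparator within one stratum.

    ``comparator='others'`` pools guided and TAU into a single group;
    ``comparator='guided'`` contrasts the two wb-CBT arms only.
    """
    res = estimation.dr_estimate(frame, spec, options=options)
    if comparator == "guided":
        c = res.contrast("self-guided", "guided")
        return c.difference, c.se
    e = res.estimates
    ic = res.influence
    n = len(ic)
    shares = np.array([e[a].n_arm for a in ("guided", "TAU")], dtype=float)
    w = shares / shares.sum()
    pooled_value = w[0] * e["guided"].value + w[1] * e["TAU"].value
    ic_pooled = w[0] * ic["guided"].to_numpy() + w[1] * ic["TAU"].to_numpy()
    ic_diff = ic["self-guided"].to_numpy() - ic_pooled
    se = float(np.std(ic_diff, ddof=0) / np.sqrt(n))
    return e["self-guided"].value - pooled_value, se


def wald_interaction(
    delta_high: float, se_high: float, delta_low: float, se_low: float
) -> tuple[float, float]:
    """Contrast-of-contrasts Wald statistic and p-value (1 df)."""
    se = math.sqrt(se_high**2 + se_low**2)
    chi2 = ((delta_high - delta_low) / se) ** 2 if se > 0 else 0.0
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def interaction_test(
    frame: pd.DataFrame,
    split: SpecifierSplit,
    spec: EstimandSpec = EstimandSpec("joint_remission", "12mo"),
    options: EstimatorOptions = EstimatorOptions(),
    comparator: str = "others",
) -> InteractionResult:
    """Wald test of specifier x self-guided-randomization interaction.

    Within each predicted-compliance stratum the self-guided-vs-comparator
    adjusted difference is computed; the statistic is
    ``((delta_high - delta_low) / sqrt(se_high^2 + se_low^2))^2`` on 1 df
    (the strata are disjoint, so the two differences are independent).
    """
    labels = split.labels.reindex(frame["participant_id"]).to_numpy()
    deltas: dict[str, tuple[float, float]] = {}
    for stratum in ("high", "low"):
        sub = frame[labels == stratum]
        if sub.empty or sub["arm"].nunique() < len(ARMS):
            raise ValueError(f"stratum {stratum!r} lacks participants in every arm")
        deltas[stratum] = _delta_self_guided(sub, spec, options, comparator)
    (dh, seh), (dl, sel) = deltas["high"], deltas["low"]
    chi2, p = wald_interaction(dh, seh, dl, sel)
    return InteractionResult(chi2, 1, p, dh, dl, seh, sel)


@dataclass
class SplitSearchResult:
    """Exploratory search for the most discriminating dichotomization."""

    best_fraction: float
    best_chi2: float
    p_naive: float
    p_permutation: float          # adjusted for the selection over fractions
    chi2_by_fraction: dict[float, float]


def best_split_search(
    frame: pd.DataFrame,
    scores: pd.Series,
    fractions: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
    spec: EstimandSpec = EstimandSpec("joint_remission", "12mo"),
    options: EstimatorOptions = EstimatorOptions(),
    n_permutations: int = 100,
    seed: int = 0,
) -> SplitSearchResult:
    """Grid search over top fractions maximizing the interaction statistic.

    Because the cut is chosen to maximize the statistic, the naive 1-df
    p-value is anti-conservative; a permutation p-value (scores permuted
    across participants, the max-over-fractions statistic recomputed)
    acknowledges the selection.  This is exploratory machinery — the
    default pipeline uses the fixed 40% cut.
    """
    def max_chi2(sc: pd.Series) -> tuple[float, float, dict[float, float]]:
        by_frac: dict[float, float] = {}
        for f in fractions:
            try:
                res = interaction_test(frame, dichotomize(sc, f), spec, options)
                by_frac[f] = res.chi2
            except ValueError:
                continue
        if not by_frac:
            raise ValueError("no feasible dichotomization in the grid")
        best_f = max(by_frac, key=by_frac.get)
        return by_frac[best_f], best_f, by_frac

    observed, best_f, by_frac = max_chi2(scores)
    rng = np.random.default_rng(seed)
    exceed = 0
    values = scores.to_numpy()
    for _ in range(n_permutations):
        perm = pd.Series(rng.permutation(values), index=scores.index)
        try:
            stat, _, _ = max_chi2(perm)
        except ValueError:
            continue
        exceed += stat >= observed
    return SplitSearchResult(
        best_fraction=best_f,
        best_chi2=observed,
        p_naive=float(stats.chi2.sf(observed, 1)),
        p_permutation=(exceed + 1) / (n_permutations + 1),
        chi2_by_fraction=by_frac,
    )


@dataclass
class StratifiedATE:
    """Per-stratum adjusted estimates, pairwise contrasts, overall tests."""

    results: dict[tuple[str, str, str], ArmEstimates]
    # keyed by (stratum, outcome, wave)

    def table(self) -> pd.DataFrame:
        rows = []
        for (stratum, outcome, wave), res in self.results.items():
            for arm, e in res.estimates.items():
                rows.append({
                    "stratum": stratum, "outcome": outcome, "wave": wave,
                    "kind": "estimate", "arm_or_pair": arm,
                    "value": e.value, "se": e.se, "chi2": np.nan,
                    "df": np.nan, "p": np.nan, "n": e.n_arm,
                })
            for a, b in (("guided", "self-guided"), ("guided", "TAU"),
                         ("self-guided", "TAU")):
                c = res.contrast(a, b)
                rows.append({
                    "stratum": stratum, "outcome": outcome, "wave": wave,
                    "kind": "contrast", "arm_or_pair": f"{a} vs {b}",
                    "value": c.difference, "se": c.se, "chi2": c.chi2,
                    "df": c.df, "p": c.p, "n": np.nan,
                })
            o = res.overall()
            rows.append({
                "stratum": stratum, "outcome": outcome, "wave": wave,
                "kind": "overall", "arm_or_pair": "all arms",
                "value": np.nan, "se": np.nan, "chi2": o.chi2,
                "df": o.df, "p": o.p, "n": np.nan,
            })
        return pd.DataFrame(rows)


def stratified_ate(
    frame: pd.DataFrame,
    split: SpecifierSplit,
    options: EstimatorOptions = EstimatorOptions(),
    outcomes: tuple[str, ...] = ("joint_remission", "phq_ads_mean"),
    waves: tuple[str, ...] = ("3mo", "12mo"),
) -> StratifiedATE:
    """Doubly robust per-arm tables within each specifier stratum.

    Reuses the estimation module inside each stratum.  The split must be
    computed from scores that never saw follow-up outcomes (enforced
    upstream by the pipeline's stage ordering).
    """
    labels = split.labels.reindex(frame["participant_id"]).to_numpy()
    results: dict[tuple[str, str, str], ArmEstimates] = {}
    strata = ["high", "low"] if (labels == "low").any() else ["high"]
    for stratum in strata:
        sub = frame[labels == stratum]
        for outcome in outcomes:
            for wave in waves:
                spec = EstimandSpec(outcome, wave)
                results[(stratum, outcome, wave)] = estimation.dr_estimate(
                    sub, spec, options=options
                )
    return StratifiedATE(results)


# ---------------------------------------------------------------------------
# attrition analysis


@dataclass
class AttritionTable:
    """Completion patterns by baseline predictor levels.

    ``counts`` has one row per predictor level with n and completion
    counts/percentages under the three definitions (both waves, 3-month,
    12-month); ``tests`` holds, per definition, the Pearson main-effect
    chi-square and the predictor-by-arm heterogeneity likelihood-ratio
    test (df = (levels - 1) x 2).
    """

    predictor: str
    counts: pd.DataFrame
    tests: pd.DataFrame


COMPLETION_DEFINITIONS = {
    "both": lambda d: d["completed_3"] & d["completed_12"],
    "3mo": lambda d: d["completed_3"],
    "12mo": lambda d: d["completed_12"],
}


def attrition_analysis(
    frame: pd.DataFrame, predictors: list[str]
) -> list[AttritionTable]:
    """Completion-pattern tables with main-effect and heterogeneity tests.

    The main effect is a Pearson chi-square of predictor level by
    completion; heterogeneity compares logistic models
    ``completion ~ predictor + arm`` vs ``completion ~ predictor * arm``
    by likelihood ratio.
    """
    out = []
    for pred in predictors:
        if pred not in frame.columns:
            raise ValueError(f"unknown predictor {pred!r}")
        levels = [
            lv for lv in pd.unique(frame[pred])
            if (frame[pred] == lv).any()
        ]
        dropped = [lv for lv in levels if (frame[pred] == lv).sum() == 0]
        for lv in dropped:
            logger.warning("predictor %s level %r has no rows; dropped", pred, lv)
        count_rows = []
        for lv in levels:
            sub = frame[frame[pred] == lv]
            row = {"level": lv, "n": len(sub)}
            for name, fn in COMPLETION_DEFINITIONS.items():
                k = int(fn(sub).sum())
                row[f"completed_{name}_n"] = k
                row[f"completed_{name}_pct"] = 100.0 * k / len(sub)
            count_rows.append(row)
        counts = pd.DataFrame(count_rows)

        test_rows = []
        for name, fn in COMPLETION_DEFINITIONS.items():
            comp = fn(frame).astype(int)
            table = pd.crosstab(frame[pred], comp)
            chi2, df, p = estimation.pearson_chi2(table.to_numpy())
            het_chi2, het_df, het_p = _heterogeneity_lrt(frame, pred, comp)
            test_rows.append({
                "definition": name, "main_chi2": chi2, "main_df": df,
                "main_p": p, "het_chi2": het_chi2, "het_df": het_df,
                "het_p": het_p,
            })
        out.append(AttritionTable(pred, counts, pd.DataFrame(test_rows)))
    return out


def _heterogeneity_lrt(
    frame: pd.DataFrame, pred: str, comp: pd.Series
) -> tuple[float, int, float]:
    d = pd.DataFrame({
        "y": comp.to_numpy(),
        "pred": frame[pred].astype(str).to_numpy(),
        "arm": frame["arm"].astype(str).to_numpy(),
    })
    main = smf.glm("y ~ C(pred) + C(arm)", data=d,
                   family=sm.families.Binomial()).fit()
    inter = smf.glm("y ~ C(pred) * C(arm)", data=d,
                    family=sm.families.Binomial()).fit()
    lr = 2 * (inter.llf - main.llf)
    df = int(inter.df_model - main.df_model)
    return float(max(lr, 0.0)), df, float(stats.chi2.sf(max(lr, 0.0), df))
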