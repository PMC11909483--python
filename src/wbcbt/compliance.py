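"""Platform-usage (compliance) metrics.

Compliance is measured from intervention-portal metadata as minutes
logged on per week over 52 weeks.  The guidance phase covers weeks 1-12;
the post-guidance phase covers weeks 13-52, and total minutes in that
window (log1p-transformed by default) is the target the compliance
prediction model is trained on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_trial import EARLY_WEEKS, LATE_WEEKS

PERIODS: dict[str, tuple[int, ...]] = {
    "weeks_1_12": EARLY_WEEKS,
    "weeks_13_52": LATE_WEEKS,
}
THRESHOLDS = (5.0, 10.0, 30.0)


@dataclass
class PeriodSummary:
    """Per-arm usage summary for one period, with a between-arm test.

    ``mean``/``sd`` are over participant-weeks; ``prop_ge`` maps each
    minutes threshold to the per-arm proportion of participant-weeks at
    or above it.  The guided vs self-guided comparison is a rank-based
    (Wilcoxon rank-sum) 1-df chi-square on participant period totals.
    """

    period: str
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    prop_ge: dict[float, dict[str, float]]
    chi2: float
    df: int
    p: float


def _usage_matrix(usage: pd.DataFrame, weeks: tuple[int, ...]) -> np.ndarray:
    cols = [f"week_{w}" for w in weeks]
    mat = usage[cols].to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("usage matrix contains negative minutes")
    return mat


def summarize_usage(
    usage: pd.DataFrame,
    arms: pd.DataFrame,
    period: str,
    thresholds: tuple[float, ...] = THRESHOLDS,
    per_participant: bool = False,
) -> PeriodSummary:
    """Summarize minutes/week per arm within a period.

    ``per_participant=True`` computes threshold proportions as the share
    of participants whose *average* weekly minutes reach the threshold,
    instead of the default share of participant-weeks.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; use one of {sorted(PERIODS)}")
    weeks = PERIODS[period]
    merged = usage.merge(arms[["participant_id", "arm"]], on="participant_id")
    mat = _usage_matrix(merged, weeks)
    arm_vec = merged["arm"].to_numpy()

    n: dict[str, int] = {}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    prop: dict[float, dict[str, float]] = {t: {} for t in thresholds}
    totals: dict[str, np.ndarray] = {}
    for arm in pd.unique(arm_vec):
        rows = mat[arm_vec == arm]
        if rows.size == 0:
            raise ValueError(f"arm {arm!r} has no participants")
        n[arm] = rows.shape[0]
        mean[arm] = float(rows.mean())
        sd[arm] = float(rows.std())
        totals[arm] = rows.sum(axis=1)
        for t in thresholds:
            if per_participant:
                prop[t][arm] = float((rows.mean(axis=1) >= t).mean())
            else:
                prop[t][arm] = float((rows >= t).mean())

    chi2 = p = float("nan")
    if "guided" in totals and "self-guided" in totals:
        z = stats.ranksums(totals["guided"], totals["self-guided"]).statistic
        chi2 = float(z**2)
        p = float(stats.chi2.sf(chi2, 1))
    return PeriodSummary(period, n, mean, sd, prop, chi2, 1, p)


def compliance_target(
    usage: pd.DataFrame,
    transform: Literal["log1p_total", "total", "mean"] = "log1p_total",
) -> pd.Series:
    """Per-participant compliance scalar: minutes over weeks 13-52.

    The default is log1p of total post-guidance minutes (the heavy right
    skew of usage makes the raw total a poor regression target); raw
    ``total`` and per-week ``mean`` variants are available by flag.
    """
    mat = _usage_matrix(usage, LATE_WEEKS)
    total = mat.sum(axis=1)
    if transform == "log1p_total":
        values = np.log1p(total)
    elif transform == "total":
        values = total
    elif transform == "mean":
        values = total / mat.shape[1]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return pd.Series(values, index=usage["participant_id"].to_numpy(), name="compliance")
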