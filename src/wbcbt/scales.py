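"""Scoring rules for the GAD-7, PHQ-9 and PHQ-ADS scales.

The GAD-7 (7 items, 0-21) measures anxiety and the PHQ-9 (9 items, 0-27)
depression; their sum is the PHQ-ADS (0-48), a combined anxiety-depression
severity scale.  This module holds the scalar definitions the rest of the
package relies on: eligibility (clinically significant anxiety OR
depression), joint remission (0-4 on both scales simultaneously), the
severity bands used for stratified randomization and descriptive tables,
and the five-level comorbidity classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Literal

GAD7_MAX = 21
PHQ9_MAX = 27
PHQ_ADS_MAX = GAD7_MAX + PHQ9_MAX

#: score >= this on either scale makes a participant eligible
ELIGIBILITY_THRESHOLD = 10
#: score <= this on both scales defines joint remission
REMISSION_THRESHOLD = 4

_SCALE_MAX = {"GAD-7": GAD7_MAX, "PHQ-9": PHQ9_MAX}


class Wave(str, Enum):
    """Assessment wave: baseline or a follow-up."""

    BASELINE = "baseline"
    M3 = "3mo"
    M12 = "12mo"


class Severity(str, Enum):
    """Ordered severity bands (moderately-severe exists for PHQ-9 only)."""

    MILD_NONE = "mild/none"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately severe"
    SEVERE = "severe"


class Comorbidity(str, Enum):
    """Five-level cross-classification of GAD-7 and PHQ-9 severity.

    For this classification PHQ-9 "severe" pools the severe (>=20) and
    moderately severe (15-19) bands, so both scales contribute three
    effective levels (severe / moderate / mild-none).
    """

    SEVERE_BOTH = "severe on both"
    SEVERE_ONE_MODERATE_OTHER = "severe on one, moderate on the other"
    SEVERE_ONE_MILD_OTHER = "severe on one, mild/none on the other"
    MODERATE_BOTH = "moderate on both"
    MODERATE_ONE_MILD_OTHER = "moderate on one, mild/none on the other"


@dataclass(frozen=True)
class SymptomScores:
    """GAD-7 / PHQ-9 scores at one wave.

    ``gad7``/``phq9`` must be present iff ``completed`` is True; the
    PHQ-ADS is always the exact sum of the two components.
    """

    wave: Wave
    completed: bool = True
    gad7: int | None = None
    phq9: int | None = None

    def __post_init__(self) -> None:
        if self.completed:
            if self.gad7 is None or self.phq9 is None:
                raise ValueError("completed wave requires gad7 and phq9 scores")
            _check_range("GAD-7", self.gad7)
            _check_range("PHQ-9", self.phq9)
        elif self.gad7 is not None or self.phq9 is not None:
            raise ValueError("scores must be absent when the wave was not completed")

    @property
    def phq_ads(self) -> int:
        if not self.completed:
            raise ValueError("PHQ-ADS undefined for a non-completed wave")
        return score_phq_ads(self.gad7, self.phq9)


def _check_range(scale: Literal["GAD-7", "PHQ-9"], score: int) -> None:
    if scale not in _SCALE_MAX:
        raise ValueError(f"unknown scale {scale!r}")
    if not (isinstance(score, (int,)) and not isinstance(score, bool)):
        # numpy integers pass through via int() below
        try:
            if int(score) != score:
                raise TypeError
            score = int(score)
        except (TypeError, ValueError):
            raise ValueError(f"{scale} score must be an integer, got {score!r}") from None
    if not 0 <= score <= _SCALE_MAX[scale]:
        raise ValueError(
            f"{scale} score {score} outside valid range 0-{_SCALE_MAX[scale]}"
        )


def score_phq_ads(gad7: int, phq9: int) -> int:
    """Combined anxiety-depression score: GAD-7 + PHQ-9, range 0-48."""
    _check_range("GAD-7", gad7)
    _check_range("PHQ-9", phq9)
    return int(gad7) + int(phq9)


def is_joint_remission(scores: SymptomScores) -> bool:
    """True iff both scales score 0-4 at a completed follow-up wave."""
    if not scores.completed:
        raise ValueError("remission is undefined for a non-completed wave")
    return scores.gad7 <= REMISSION_THRESHOLD and scores.phq9 <= REMISSION_THRESHOLD


def is_eligible(scores: SymptomScores) -> bool:
    """Trial eligibility: GAD-7 >= 10 or PHQ-9 >= 10 at baseline."""
    if not scores.completed:
        raise ValueError("eligibility requires completed baseline scores")
    return (
        scores.gad7 >= ELIGIBILITY_THRESHOLD or scores.phq9 >= ELIGIBILITY_THRESHOLD
    )


def severity_category(scale: Literal["GAD-7", "PHQ-9"], score: int) -> Severity:
    """Severity band of a score.

    GAD-7: 0-9 mild/none, 10-14 moderate, >=15 severe.
    PHQ-9: 0-9 mild/none, 10-14 moderate, 15-19 moderately severe, >=20 severe.
    """
    _check_range(scale, score)
    if score <= 9:
        return Severity.MILD_NONE
    if score <= 14:
        return Severity.MODERATE
    if scale == "PHQ-9" and score <= 19:
        return Severity.MODERATELY_SEVERE
    return Severity.SEVERE


def _pooled_level(scale: Literal["GAD-7", "PHQ-9"], score: int) -> int:
    """3-level severity with PHQ-9 moderately-severe pooled into severe.

    Returns 2 (severe), 1 (moderate) or 0 (mild/none).
    """
    cat = severity_category(scale, score)
    if cat in (Severity.SEVERE, Severity.MODERATELY_SEVERE):
        return 2
    if cat is Severity.MODERATE:
        return 1
    return 0


def comorbidity_category(gad7: int, phq9: int) -> Comorbidity:
    """Five-level comorbidity classification of a score pair.

    PHQ-9 counts as severe when >= 15 (moderately severe pooled with
    severe); the mapping is total and mutually exclusive on the
    0-21 x 0-27 score grid.
    """
    a = _pooled_level("GAD-7", gad7)
    d = _pooled_level("PHQ-9", phq9)
    hi, lo = max(a, d), min(a, d)
    if hi == 2:
        if lo == 2:
            return Comorbidity.SEVERE_BOTH
        if lo == 1:
            return Comorbidity.SEVERE_ONE_MODERATE_OTHER
        return Comorbidity.SEVERE_ONE_MILD_OTHER
    if hi == 1:
        if lo == 1:
            return Comorbidity.MODERATE_BOTH
        return Comorbidity.MODERATE_ONE_MILD_OTHER
    # both mild/none cannot occur among eligible participants but the
    # function is total: classify with the lowest comorbidity level
    return Comorbidity.MODERATE_ONE_MILD_OTHER
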