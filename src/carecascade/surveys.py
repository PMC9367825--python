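"""Scoring of the baseline psychosocial survey instruments.

* Incentive acceptability: mean of four 0-4 Likert items, the fourth
  reverse-scored; complete cases only.
* AUDIT-C hazardous alcohol use: score >= 4 for men, >= 3 for women and for
  gender-minority respondents.
* PHQ-9 depressive symptoms: sum of nine 0-3 items (0-27).
* CASE adherence index: 3-16 total, accepted directly when item-level data
  are unavailable.
* Internalized HIV stigma: mean of 1-5 items.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .synthetic import SurveyResponse

__all__ = [
    "InstrumentScores",
    "acceptability_score",
    "hazardous_alcohol",
    "scale_totals",
]

# (low, high) range metadata reported with each score
SCORE_RANGES = {
    "acceptability": (0.0, 4.0),
    "phq9_total": (0, 27),
    "case_total": (3, 16),
    "stigma_mean": (1.0, 5.0),
}


@dataclass(frozen=True)
class InstrumentScores:
    acceptability: float | None
    hazardous_alcohol: bool | None
    phq9_total: int | None
    case_total: int | None
    stigma_mean: float | None
    ranges: dict = None

    def __post_init__(self):
        object.__setattr__(self, "ranges", dict(SCORE_RANGES))


def acceptability_score(items: Sequence) -> float | None:
    """Mean of the four acceptability items with item 4 reverse-scored.

    Returns None unless all four items are present (complete-case rule).
    """
    if len(items) != 4:
        raise ValueError("acceptability takes exactly 4 items")
    if any(i is None for i in items):
        return None
    for i in items:
        if not 0 <= i <= 4:
            raise ValueError(f"acceptability item {i} outside [0, 4]")
    i1, i2, i3, i4 = items
    return (i1 + i2 + i3 + (4 - i4)) / 4.0


def hazardous_alcohol(auditc_score: int | None, gender: str) -> bool | None:
    """Gender-specific AUDIT-C cutoff: >= 4 for men, >= 3 otherwise."""
    if auditc_score is None:
        return None
    if auditc_score < 0:
        raise ValueError("AUDIT-C score must be non-negative")
    if gender == "male":
        return auditc_score >= 4
    if gender in ("female", "gender_minority"):
        return auditc_score >= 3
    raise ValueError(f"unknown gender code: {gender!r}")


def _sum_complete(items: Sequence, low: int, high: int, name: str) -> int | None:
    if any(i is None for i in items):
        return None
    for i in items:
        if not low <= i <= high:
            raise ValueError(f"{name} item {i} outside [{low}, {high}]")
    return int(sum(items))


def scale_totals(response: SurveyResponse) -> InstrumentScores:
    """Score every instrument on one response; missing propagates per scale."""
    phq9 = _sum_complete(response.phq9_items, 0, 3, "PHQ-9")
    if any(i is None for i in response.stigma_items):
        stigma = None
    else:
        for i in response.stigma_items:
            if not 1 <= i <= 5:
                raise ValueError(f"stigma item {i} outside [1, 5]")
        stigma = sum(response.stigma_items) / len(response.stigma_items)
    case = response.case_total
    if case is not None and not 3 <= case <= 16:
        raise ValueError(f"CASE total {case} outside [3, 16]")
    return InstrumentScores(
        acceptability=acceptability_score(response.acceptability_items),
        hazardous_alcohol=hazardous_alcohol(response.auditc_score, response.gender),
        phq9_total=phq9,
        case_total=case,
        stigma_mean=stigma,
    )
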