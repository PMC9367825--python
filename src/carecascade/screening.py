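"""Eligibility screening for an incentive program serving people with HIV.

Base criteria: confirmed HIV diagnosis, local residence with no plans to
move within 12 months, age 18+, able to take part in English, and not
excluded (concurrent care-continuum study, currently institutionalized).
On top of those, a participant must meet at least one criterion from:

Category A (out of care / unsuppressed)
    no viral-load test in the last 8 months; or two consecutive detectable
    (>= 200 copies/mL) results at least 90 days apart; or >= 2 missed
    visits in the last 6 months.
Category B (newly diagnosed or at risk of falling out of care)
    diagnosed 3-12 months ago with no HIV care since diagnosis; or at least
    one self-reported risk factor (unstable housing, unemployed >= 3
    months, incarceration history, or a behavioral-health condition within
    the last 12 months).

All "N months" clauses use a uniform 30-day month (8 months = 240 days).
Category A takes precedence when both hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import pandas as pd

from .synthetic import LabTest, Participant

__all__ = [
    "RISK_FACTORS",
    "ScreeningRecord",
    "EligibilityResult",
    "screen_category_a",
    "screen_category_b",
    "check_eligibility",
    "record_from_participant",
    "screen_cohort",
]

MONTH_DAYS = 30

RISK_FACTORS = frozenset({
    "unstable_housing",
    "unemployed_3mo",
    "incarceration_history",
    "behavioral_health_12mo",  # within the 12 months before enrollment, by definition
})


@dataclass(frozen=True)
class ScreeningRecord:
    age_years: float
    resident: bool
    plans_to_move: bool
    english_ok: bool
    confirmed_hiv: bool
    missed_visits_6mo: int
    risk_factors: frozenset
    lab_history: tuple          # LabTest, sorted by date
    diagnosis_date: date
    screening_date: date
    in_other_study: bool = False
    institutionalized: bool = False

    def __post_init__(self):
        if self.missed_visits_6mo < 0:
            raise ValueError("missed_visits_6mo must be non-negative")
        unknown = set(self.risk_factors) - RISK_FACTORS
        if unknown:
            raise ValueError(f"unknown risk factors: {sorted(unknown)}")
        dates = [t.test_date for t in self.lab_history]
        if dates != sorted(dates):
            raise ValueError("lab_history must be sorted by test date")


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    category: str               # "A", "B", or "none"
    reasons: tuple = ()

    def __post_init__(self):
        if self.eligible != (self.category != "none"):
            raise ValueError("eligible must agree with category")
        if self.eligible and not self.reasons:
            raise ValueError("eligible results must carry at least one rule code")


def screen_category_a(record: ScreeningRecord) -> tuple[bool, list[str]]:
    """Out-of-care / unsuppressed criteria; any one clause suffices."""
    reasons: list[str] = []
    cutoff = record.screening_date - timedelta(days=8 * MONTH_DAYS)
    recent = [t for t in record.lab_history
              if cutoff <= t.test_date <= record.screening_date]
    if not recent:
        reasons.append("NO_VL_8MO")
    history = list(record.lab_history)
    for prev, nxt in zip(history, history[1:]):  # consecutive = adjacent in date order
        if (prev.viral_load >= 200 and nxt.viral_load >= 200
                and (nxt.test_date - prev.test_date).days >= 90):
            reasons.append("TWO_DETECTABLE_90D")
            break
    if record.missed_visits_6mo >= 2:
        reasons.append("MISSED_2_VISITS")
    return bool(reasons), reasons


def screen_category_b(record: ScreeningRecord) -> tuple[bool, list[str]]:
    """Newly-diagnosed-not-in-care or self-reported risk-factor criteria."""
    if record.diagnosis_date > record.screening_date:
        raise ValueError("diagnosis_date after screening_date")
    reasons: list[str] = []
    since_dx = (record.screening_date - record.diagnosis_date).days
    tests_since_dx = [t for t in record.lab_history
                      if record.diagnosis_date <= t.test_date <= record.screening_date]
    if 3 * MONTH_DAYS <= since_dx <= 12 * MONTH_DAYS and not tests_since_dx:
        reasons.append("NEW_DX_NOT_IN_CARE")
    if record.risk_factors:
        reasons.append("RISK_FACTOR")
    return bool(reasons), reasons


def check_eligibility(record: ScreeningRecord) -> EligibilityResult:
    """Base criteria plus Category A or B; A takes precedence when both hold."""
    base_ok = (
        record.confirmed_hiv
        and record.resident
        and not record.plans_to_move
        and record.age_years >= 18
        and record.english_ok
        and not record.in_other_study
        and not record.institutionalized
    )
    if not base_ok:
        return EligibilityResult(False, "none")
    a_ok, a_reasons = screen_category_a(record)
    if a_ok:
        return EligibilityResult(True, "A", tuple(a_reasons))
    b_ok, b_reasons = screen_category_b(record)
    if b_ok:
        return EligibilityResult(True, "B", tuple(b_reasons))
    return EligibilityResult(False, "none")


def record_from_participant(p: Participant, tests: Sequence[LabTest]) -> ScreeningRecord:
    """Screening view of a participant: pre-enrollment labs and self-reported
    risk factors mapped from the baseline characteristics."""
    risk = set()
    if p.housing == "unstable":
        risk.add("unstable_housing")
    if p.employment == "unemployed":
        risk.add("unemployed_3mo")
    if p.incarceration == "recent":
        risk.add("incarceration_history")
    pre = tuple(sorted((t for t in tests if t.test_date < p.enrollment_date),
                       key=lambda t: t.test_date))
    return ScreeningRecord(
        age_years=p.age_years, resident=True, plans_to_move=False,
        english_ok=True, confirmed_hiv=True, missed_visits_6mo=0,
        risk_factors=frozenset(risk), lab_history=pre,
        diagnosis_date=p.diagnosis_date, screening_date=p.enrollment_date,
    )


def screen_cohort(participants: Sequence[Participant],
                  lab_tests: Sequence[LabTest]) -> pd.DataFrame:
    """Apply the eligibility rules across a cohort; one row per participant."""
    by_pid: dict[str, list[LabTest]] = {}
    for t in lab_tests:
        by_pid.setdefault(t.participant_id, []).append(t)
    rows = []
    for p in participants:
        res = check_eligibility(record_from_participant(p, by_pid.get(p.id, [])))
        rows.append({"id": p.id, "eligible": res.eligible,
                     "category": res.category, "reasons": ";".join(res.reasons)})
    return pd.DataFrame(rows)
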