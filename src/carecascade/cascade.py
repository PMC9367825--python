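"""HIV care-continuum outcome classification from dated viral-load tests.

Three binary outcomes per participant per timepoint (t0 = enrollment,
t1 = 6 months, t2 = 12 months):

engagement
    at least one viral-load test inside the timepoint's window;
retention
    at least two in-window tests at least 90 days apart;
suppression
    the most recent test within +/- one month of the reporting date has a
    viral load below 200 copies/mL.

Conventions (all exposed on :class:`CascadeConfig`): a month is 30 days; the
"12-month period (+/- 1 month)" is a 390-day post-enrollment window; t0
engagement and retention look back over the 360 days before enrollment,
excluding the enrollment-day baseline visit itself; t0 suppression uses the
enrollment-day test. A participant with no test in a window is classified
negative (the cohort denominator is everyone enrolled), unless the
complete-case convention is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Literal, Sequence

import pandas as pd

from .synthetic import LabTest

__all__ = [
    "CascadeConfig",
    "CascadeStatus",
    "classify_engagement",
    "classify_retention",
    "classify_suppression",
    "classify_participant",
    "classify_cohort",
    "cascade_table",
]

Timepoint = Literal["t0", "t1", "t2"]
TIMEPOINTS: tuple[Timepoint, ...] = ("t0", "t1", "t2")
OUTCOMES = ("engaged", "retained", "suppressed")


@dataclass(frozen=True)
class CascadeConfig:
    suppression_threshold: int = 200       # copies/mL, strict "<"
    window_tolerance_days: int = 30        # the "+/- 1 month"
    retention_gap_days: int = 90
    month_days: int = 30

    def __post_init__(self):
        for name in ("suppression_threshold", "window_tolerance_days",
                     "retention_gap_days", "month_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CascadeConfig.{name} must be positive")

    def horizon_days(self, months: int) -> int:
        """Forward window length: N months plus the one-month tolerance."""
        return months * self.month_days + self.window_tolerance_days


@dataclass(frozen=True)
class CascadeStatus:
    participant_id: str
    timepoint: Timepoint
    engaged: bool
    retained: bool
    suppressed: bool
    n_tests_in_window: int = 0

    def __post_init__(self):
        if self.retained and not self.engaged:
            raise ValueError("retained implies engaged over the same window")


def _dates_in_window(tests: Sequence[LabTest], start: date, end: date,
                     exclude: date | None = None) -> list[date]:
    """Test dates in [start, end], both endpoints inclusive."""
    return [t.test_date for t in tests
            if start <= t.test_date <= end and t.test_date != exclude]


def classify_engagement(
    tests: Sequence[LabTest],
    anchor_date: date,
    config: CascadeConfig = CascadeConfig(),
    lookback: bool = False,
    horizon_months: int = 12,
) -> bool:
    """>= 1 test in the window anchored at ``anchor_date``.

    Forward windows span [anchor, anchor + horizon + tolerance]; the
    baseline lookback spans the 12 months strictly before the anchor.
    The enrollment-day (anchor) test never counts: it is the incented
    baseline study visit, not evidence of routine care.
    """
    if lookback:
        start = anchor_date - timedelta(days=12 * config.month_days)
        end = anchor_date - timedelta(days=1)
    else:
        start = anchor_date
        end = anchor_date + timedelta(days=config.horizon_days(horizon_months))
    return len(_dates_in_window(tests, start, end, exclude=anchor_date)) >= 1


def classify_retention(
    tests: Sequence[LabTest],
    anchor_date: date,
    config: CascadeConfig = CascadeConfig(),
    lookback: bool = False,
    horizon_months: int = 12,
) -> bool:
    """>= 2 in-window tests at least ``retention_gap_days`` apart."""
    if lookback:
        start = anchor_date - timedelta(days=12 * config.month_days)
        end = anchor_date - timedelta(days=1)
    else:
        start = anchor_date
        end = anchor_date + timedelta(days=config.horizon_days(horizon_months))
    dates = sorted(_dates_in_window(tests, start, end, exclude=anchor_date))
    if len(dates) < 2:
        return False
    return (dates[-1] - dates[0]).days >= config.retention_gap_days


def classify_suppression(
    tests: Sequence[LabTest],
    report_date: date,
    config: CascadeConfig = CascadeConfig(),
) -> bool:
    """Most recent test within +/- tolerance of the reporting date is < threshold.

    No test in the window classifies as not suppressed.
    """
    tol = timedelta(days=config.window_tolerance_days)
    in_window = [t for t in tests
                 if report_date - tol <= t.test_date <= report_date + tol]
    if not in_window:
        return False
    latest = max(in_window, key=lambda t: t.test_date)
    return latest.viral_load < config.suppression_threshold


def _count_window(tests, start, end, exclude=None) -> int:
    return len(_dates_in_window(tests, start, end, exclude=exclude))


def classify_participant(
    tests: Sequence[LabTest],
    participant_id: str,
    enrollment_date: date,
    config: CascadeConfig = CascadeConfig(),
) -> list[CascadeStatus]:
    """Full t0/t1/t2 status triple for one participant's lab stream."""
    tests = sorted(tests, key=lambda t: t.test_date)
    out: list[CascadeStatus] = []
    # t0: lookback engagement/retention; suppression from the enrollment-day test
    eng0 = classify_engagement(tests, enrollment_date, config, lookback=True)
    ret0 = classify_retention(tests, enrollment_date, config, lookback=True)
    baseline_tests = [t for t in tests if t.test_date <= enrollment_date]
    sup0 = classify_suppression(baseline_tests, enrollment_date, config)
    n0 = _count_window(tests, enrollment_date - timedelta(days=12 * config.month_days),
                       enrollment_date - timedelta(days=1))
    out.append(CascadeStatus(participant_id, "t0", eng0, ret0, sup0, n0))
    for tp, months in (("t1", 6), ("t2", 12)):
        report = enrollment_date + timedelta(days=months * config.month_days)
        eng = classify_engagement(tests, enrollment_date, config, horizon_months=months)
        ret = classify_retention(tests, enrollment_date, config, horizon_months=months)
        sup = classify_suppression(tests, report, config)
        n = _count_window(tests, enrollment_date,
                          enrollment_date + timedelta(days=config.horizon_days(months)),
                          exclude=enrollment_date)
        out.append(CascadeStatus(participant_id, tp, eng, ret, sup, n))
    return out


def classify_cohort(
    participants,
    lab_tests: Iterable[LabTest],
    config: CascadeConfig = CascadeConfig(),
) -> list[CascadeStatus]:
    by_pid: dict[str, list[LabTest]] = {}
    for t in lab_tests:
        by_pid.setdefault(t.participant_id, []).append(t)
    statuses: list[CascadeStatus] = []
    for p in participants:
        statuses.extend(
            classify_participant(by_pid.get(p.id, []), p.id, p.enrollment_date, config)
        )
    return statuses


def cascade_table(
    statuses: Sequence[CascadeStatus],
    convention: Literal["missing_as_false", "complete_case"] = "missing_as_false",
) -> pd.DataFrame:
    """Per-timepoint counts and proportions for the three outcomes.

    With the default convention the denominator is every enrolled
    participant; ``complete_case`` restricts each timepoint's denominator to
    participants with at least one test in that timepoint's window.
    """
    if not statuses:
        raise ValueError("empty cohort: no statuses to tabulate")
    seen = set()
    for s in statuses:
        key = (s.participant_id, s.timepoint)
        if key in seen:
            raise ValueError(f"duplicate status for {key}")
        seen.add(key)
    rows = []
    for tp in TIMEPOINTS:
        at_tp = [s for s in statuses if s.timepoint == tp]
        if not at_tp:
            continue
        if convention == "complete_case":
            denom_set = [s for s in at_tp if s.n_tests_in_window > 0]
        else:
            denom_set = at_tp
        denom = len(denom_set)
        for outcome in OUTCOMES:
            count = sum(1 for s in denom_set if getattr(s, outcome))
            rows.append({
                "timepoint": tp,
                "outcome": outcome,
                "count": count,
                "denominator": denom,
                "proportion": count / denom if denom else float("nan"),
            })
    return pd.DataFrame(rows)
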