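"""Conditional financial incentive accrual and audit.

Participants earn USD10 per completed lab visit (at most four per year) and
USD50 for achieving viral suppression at each of the 6- and 12-month
follow-ups, capping the intervention component at USD140 per participant.
Survey compensation (USD50 baseline, USD15 follow-up) is tracked on the same
ledger but sits outside the intervention cap.

Ledger arithmetic is exact-cent Decimal so that audit identities (per-
participant caps, the at-least-k / total-events identity) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from decimal import Decimal
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "EventType",
    "IncentiveSchedule",
    "IncentiveEvent",
    "LedgerAuditError",
    "accrue",
    "ledger_summary",
    "build_ledger",
]


class EventType(str, Enum):
    LAB = "LAB"
    SUPPRESSION_6M = "SUPPRESSION_6M"
    SUPPRESSION_12M = "SUPPRESSION_12M"
    SURVEY_BASELINE = "SURVEY_BASELINE"
    SURVEY_FOLLOWUP = "SURVEY_FOLLOWUP"


INTERVENTION_TYPES = {EventType.LAB, EventType.SUPPRESSION_6M, EventType.SUPPRESSION_12M}

_TRIGGER_TO_TYPE = {
    "lab_completed": EventType.LAB,
    "suppressed_6m": EventType.SUPPRESSION_6M,
    "suppressed_12m": EventType.SUPPRESSION_12M,
    "survey_baseline": EventType.SURVEY_BASELINE,
    "survey_followup": EventType.SURVEY_FOLLOWUP,
}


class LedgerAuditError(ValueError):
    """An accrual that violates the schedule; carries an audit code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class IncentiveSchedule:
    """The incentive schedule; the defaults encode the USD140 intervention design."""

    lab_amount: Decimal = Decimal("10")
    lab_max_count: int = 4
    suppression_amount: Decimal = Decimal("50")
    intervention_cap: Decimal = Decimal("140")
    survey_baseline: Decimal = Decimal("50")
    survey_followup: Decimal = Decimal("15")

    def __post_init__(self):
        for name in ("lab_amount", "suppression_amount", "intervention_cap",
                     "survey_baseline", "survey_followup"):
            object.__setattr__(self, name, Decimal(str(getattr(self, name))))
        expected = self.lab_amount * self.lab_max_count + self.suppression_amount * 2
        if expected != self.intervention_cap:
            raise ValueError(
                "schedule inconsistent: lab_amount*lab_max_count + 2*suppression_amount "
                f"= {expected} != intervention_cap {self.intervention_cap}"
            )

    def amount_for(self, event_type: EventType) -> Decimal:
        return {
            EventType.LAB: self.lab_amount,
            EventType.SUPPRESSION_6M: self.suppression_amount,
            EventType.SUPPRESSION_12M: self.suppression_amount,
            EventType.SURVEY_BASELINE: self.survey_baseline,
            EventType.SURVEY_FOLLOWUP: self.survey_followup,
        }[event_type]


@dataclass(frozen=True)
class IncentiveEvent:
    participant_id: str
    event_type: EventType
    date: date
    amount: Decimal
    # Incentives earned but not yet handed over at study close are still
    # counted as distributed for analysis; the flag preserves the distinction.
    distributed: bool = True


def _participant_events(ledger: Sequence[IncentiveEvent], pid: str) -> list[IncentiveEvent]:
    return [e for e in ledger if e.participant_id == pid]


def accrue(
    events_so_far: Sequence[IncentiveEvent],
    trigger: str,
    participant_id: str,
    event_date: date,
    schedule: IncentiveSchedule = IncentiveSchedule(),
) -> IncentiveEvent | None:
    """Apply one trigger against a participant's ledger.

    Returns the newly earned event, or None when the trigger earns nothing
    (lab count already at the yearly maximum). Duplicate suppression triggers
    are schedule violations and raise :class:`LedgerAuditError`.
    """
    if trigger not in _TRIGGER_TO_TYPE:
        raise ValueError(f"unknown trigger: {trigger!r}")
    mine = _participant_events(events_so_far, participant_id)
    if any(e.date > event_date for e in mine):
        raise ValueError("ledger must be sorted by date: trigger predates existing events")
    etype = _TRIGGER_TO_TYPE[trigger]
    if etype is EventType.LAB:
        n_labs = sum(1 for e in mine if e.event_type is EventType.LAB)
        if n_labs >= schedule.lab_max_count:
            return None
    elif etype in (EventType.SUPPRESSION_6M, EventType.SUPPRESSION_12M):
        if any(e.event_type is etype for e in mine):
            raise LedgerAuditError(
                f"DUPLICATE_{etype.value}",
                f"{participant_id}: {etype.value} incentive already issued",
            )
    amount = schedule.amount_for(etype)
    if etype in INTERVENTION_TYPES:
        spent = sum((e.amount for e in mine if e.event_type in INTERVENTION_TYPES), Decimal(0))
        if spent + amount > schedule.intervention_cap:
            raise LedgerAuditError(
                "INTERVENTION_CAP",
                f"{participant_id}: accrual would exceed the "
                f"USD{schedule.intervention_cap} intervention cap",
            )
    return IncentiveEvent(participant_id, etype, event_date, amount)


def ledger_summary(
    events: Iterable[IncentiveEvent],
    schedule: IncentiveSchedule = IncentiveSchedule(),
) -> dict:
    """Cohort-level audit summary of an incentive ledger.

    ``at_least_k`` counts participants with >= k lab incentives, k = 1..max;
    their sum equals the total number of lab incentives distributed (each
    participant with m lab events contributes m to the sum).
    """
    lab_counts: dict[str, int] = {}
    supp = {EventType.SUPPRESSION_6M: 0, EventType.SUPPRESSION_12M: 0}
    survey = {EventType.SURVEY_BASELINE: 0, EventType.SURVEY_FOLLOWUP: 0}
    total_amount = Decimal(0)
    intervention_amount = Decimal(0)
    for e in events:
        total_amount += e.amount
        if e.event_type in INTERVENTION_TYPES:
            intervention_amount += e.amount
        if e.event_type is EventType.LAB:
            lab_counts[e.participant_id] = lab_counts.get(e.participant_id, 0) + 1
        elif e.event_type in supp:
            supp[e.event_type] += 1
        else:
            survey[e.event_type] += 1
    kmax = schedule.lab_max_count
    at_least = {k: sum(1 for m in lab_counts.values() if m >= k) for k in range(1, kmax + 1)}
    total_labs = sum(lab_counts.values())
    assert total_labs == sum(at_least.values()), "at-least-k identity violated"
    return {
        "at_least_k": at_least,
        "total_lab_incentives": total_labs,
        "suppression_6m": supp[EventType.SUPPRESSION_6M],
        "suppression_12m": supp[EventType.SUPPRESSION_12M],
        "survey_baseline": survey[EventType.SURVEY_BASELINE],
        "survey_followup": survey[EventType.SURVEY_FOLLOWUP],
        "total_amount_usd": total_amount,
        "intervention_amount_usd": intervention_amount,
    }


def build_ledger(
    statuses,
    lab_tests,
    participants,
    schedule: IncentiveSchedule = IncentiveSchedule(),
    followup_survey_rate_cutoff: date | None = None,
) -> list[IncentiveEvent]:
    """Derive the full incentive ledger from cascade statuses and lab streams.

    Lab incentives accrue for post-enrollment tests (the enrollment-day
    baseline visit is study compensation, not a lab incentive) up to the
    yearly maximum; suppression incentives follow the 6- and 12-month
    cascade classifications.
    """
    enroll = {p.id: p.enrollment_date for p in participants}
    by_pid: dict[str, list] = {}
    for t in sorted(lab_tests, key=lambda t: (t.participant_id, t.test_date)):
        by_pid.setdefault(t.participant_id, []).append(t)
    supp_by_pid: dict[str, list[tuple]] = {}
    for s in statuses:
        if s.timepoint == "t1" and s.suppressed:
            supp_by_pid.setdefault(s.participant_id, []).append(
                (timedelta(days=180), "suppressed_6m"))
        elif s.timepoint == "t2" and s.suppressed:
            supp_by_pid.setdefault(s.participant_id, []).append(
                (timedelta(days=360), "suppressed_12m"))

    ledger: list[IncentiveEvent] = []
    for p in participants:
        anchor = p.enrollment_date
        mine: list[IncentiveEvent] = [
            IncentiveEvent(p.id, EventType.SURVEY_BASELINE, anchor, schedule.survey_baseline)
        ]
        triggers: list[tuple[date, str]] = [
            (t.test_date, "lab_completed")
            for t in by_pid.get(p.id, [])
            if anchor < t.test_date <= anchor + timedelta(days=390)
        ]
        triggers += [(anchor + offset, trig) for offset, trig in supp_by_pid.get(p.id, [])]
        for ev_date, trig in sorted(triggers):
            ev = accrue(mine, trig, p.id, ev_date, schedule)
            if ev is not None:
                mine.append(ev)
        ledger.extend(mine)
    return ledger
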