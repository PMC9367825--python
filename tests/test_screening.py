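"""Eligibility rules: clause examples, monotonicity, independent clause oracle."""

from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, strategies as st

from carecascade.screening import (
    RISK_FACTORS,
    ScreeningRecord,
    check_eligibility,
    screen_category_a,
    screen_category_b,
)
from carecascade.synthetic import LabTest

SCREEN = date(2019, 6, 1)


def make_record(**kw):
    defaults = dict(
        age_years=35, resident=True, plans_to_move=False, english_ok=True,
        confirmed_hiv=True, missed_visits_6mo=0, risk_factors=frozenset(),
        lab_history=(), diagnosis_date=SCREEN - timedelta(days=6 * 360),
        screening_date=SCREEN,
    )
    defaults.update(kw)
    return ScreeningRecord(**defaults)


def labs(*day_vl):
    return tuple(sorted(
        (LabTest("P", SCREEN + timedelta(days=d), v) for d, v in day_vl),
        key=lambda t: t.test_date))


# ------------------------------------------------------------- category A

def test_no_lab_in_eight_months_qualifies():
    rec = make_record(lab_history=labs((-270, 50)))  # last test 9 months ago
    ok, reasons = screen_category_a(rec)
    assert ok and reasons == ["NO_VL_8MO"]


def test_recent_lab_blocks_the_8_month_clause():
    rec = make_record(lab_history=labs((-60, 50)))
    ok, reasons = screen_category_a(rec)
    assert not ok


def test_two_consecutive_detectable_at_90_days_qualifies():
    rec = make_record(lab_history=labs((-150, 250), (-60, 300)))
    ok, reasons = screen_category_a(rec)
    assert ok and "TWO_DETECTABLE_90D" in reasons


def test_intervening_suppressed_test_breaks_consecutiveness():
    rec = make_record(lab_history=labs((-150, 250), (-100, 50), (-60, 300)))
    ok, reasons = screen_category_a(rec)
    assert "TWO_DETECTABLE_90D" not in reasons


def test_all_three_clauses_false():
    # detectable pair only 60 days apart, 1 missed visit, test 2 months ago
    rec = make_record(lab_history=labs((-120, 250), (-60, 300)),
                      missed_visits_6mo=1)
    ok, _ = screen_category_a(rec)
    assert not ok


def test_missed_visits_clause():
    rec = make_record(lab_history=labs((-30, 50)), missed_visits_6mo=2)
    ok, reasons = screen_category_a(rec)
    assert ok and reasons == ["MISSED_2_VISITS"]


# ------------------------------------------------------------- category B

def test_newly_diagnosed_not_in_care_qualifies():
    rec = make_record(diagnosis_date=SCREEN - timedelta(days=150), lab_history=())
    ok, reasons = screen_category_b(rec)
    assert ok and reasons == ["NEW_DX_NOT_IN_CARE"]


def test_longstanding_diagnosis_engaged_no_risk_is_not_category_b():
    rec = make_record(lab_history=labs((-30, 50)))
    ok, _ = screen_category_b(rec)
    assert not ok


def test_single_risk_factor_qualifies():
    rec = make_record(risk_factors=frozenset({"unstable_housing"}),
                      lab_history=labs((-30, 50)))
    ok, reasons = screen_category_b(rec)
    assert ok and reasons == ["RISK_FACTOR"]


def test_diagnosis_after_screening_is_a_data_error():
    rec = make_record(diagnosis_date=SCREEN + timedelta(days=1))
    with pytest.raises(ValueError, match="diagnosis_date"):
        screen_category_b(rec)


# ------------------------------------------------------- overall eligibility

def test_minor_is_ineligible_even_if_otherwise_qualifying():
    rec = make_record(age_years=17)  # no labs -> category A would hold
    assert not check_eligibility(rec).eligible


def test_category_a_record_is_eligible_as_a():
    res = check_eligibility(make_record())  # no labs at all -> NO_VL_8MO
    assert res.eligible and res.category == "A" and res.reasons


def test_category_b_only_record_is_eligible_as_b():
    rec = make_record(lab_history=labs((-30, 50)),
                      risk_factors=frozenset({"incarceration_history"}))
    res = check_eligibility(rec)
    assert res.eligible and res.category == "B"


def test_a_takes_precedence_over_b():
    rec = make_record(risk_factors=frozenset({"unstable_housing"}))  # A and B hold
    assert check_eligibility(rec).category == "A"


def test_exclusion_criteria_block_eligibility():
    assert not check_eligibility(make_record(in_other_study=True)).eligible
    assert not check_eligibility(make_record(institutionalized=True)).eligible


@given(st.sets(st.sampled_from(sorted(RISK_FACTORS))),
       st.sampled_from(sorted(RISK_FACTORS)))
def test_adding_a_risk_factor_never_revokes_eligibility(factors, extra):
    rec = make_record(lab_history=labs((-30, 50)), risk_factors=frozenset(factors))
    before = check_eligibility(rec)
    rec2 = make_record(lab_history=labs((-30, 50)),
                       risk_factors=frozenset(factors | {extra}))
    after = check_eligibility(rec2)
    assert after.eligible >= before.eligible


# ----------------------------------------------------- clause-by-clause oracle

def _oracle(rec: ScreeningRecord):
    """Independent truth-table evaluation of the eligibility rules."""
    base = (rec.confirmed_hiv and rec.resident and not rec.plans_to_move
            and rec.age_years >= 18 and rec.english_ok
            and not rec.in_other_study and not rec.institutionalized)
    a1 = not any(0 <= (rec.screening_date - t.test_date).days <= 240
                 for t in rec.lab_history)
    hist = list(rec.lab_history)
    a2 = any(p.viral_load >= 200 and q.viral_load >= 200
             and (q.test_date - p.test_date).days >= 90
             for p, q in zip(hist, hist[1:]))
    a3 = rec.missed_visits_6mo >= 2
    since = (rec.screening_date - rec.diagnosis_date).days
    b1 = (90 <= since <= 360 and not any(
        rec.diagnosis_date <= t.test_date <= rec.screening_date
        for t in rec.lab_history))
    b2 = len(rec.risk_factors) > 0
    if not base:
        return (False, "none")
    if a1 or a2 or a3:
        return (True, "A")
    if b1 or b2:
        return (True, "B")
    return (False, "none")


def test_screen_cohort_covers_every_participant(small_cohort):
    from carecascade.screening import screen_cohort

    people, tests = small_cohort
    result = screen_cohort(people, tests)
    assert len(result) == len(people)
    assert set(result["category"].unique()) <= {"A", "B", "none"}
    # eligible rows always carry at least one rule code
    assert (result.loc[result.eligible, "reasons"].str.len() > 0).all()


def test_predicates_match_clause_oracle_on_random_records(rng):
    factors = sorted(RISK_FACTORS)
    for _ in range(1000):
        n_labs = int(rng.integers(0, 6))
        days = sorted(int(d) for d in rng.integers(-500, 0, size=n_labs))
        vls = [int(v) for v in rng.choice([50, 250, 5000], size=n_labs)]
        rec = make_record(
            age_years=int(rng.integers(16, 70)),
            resident=bool(rng.random() < 0.9),
            plans_to_move=bool(rng.random() < 0.1),
            english_ok=bool(rng.random() < 0.95),
            confirmed_hiv=bool(rng.random() < 0.95),
            missed_visits_6mo=int(rng.integers(0, 4)),
            risk_factors=frozenset(
                f for f in factors if rng.random() < 0.2),
            lab_history=labs(*zip(days, vls)) if n_labs else (),
            diagnosis_date=SCREEN - timedelta(days=int(rng.integers(0, 3000))),
        )
        res = check_eligibility(rec)
        assert (res.eligible, res.category) == _oracle(rec)
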