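"""Trend and correlates regressions against an independent Newton MLE oracle."""

import numpy as np
import pandas as pd
import pytest

from carecascade.cascade import CascadeStatus
from carecascade.models import (
    build_correlates_frame,
    build_long_records,
    fit_add_one,
    fit_benchmark_correlates,
    fit_time_trend,
)
from carecascade.synthetic import CohortConfig, generate_cohort

from conftest import newton_logit_mle


def _long(records):
    """records: list of (pid, time, value)."""
    return pd.DataFrame(records, columns=["participant_id", "time", "y"]).assign(
        y=lambda d: d["y"].astype(int))


def test_flat_outcome_gives_zero_slope_and_constant_probs():
    recs = []
    for i in range(30):
        for t in (0, 1, 2):
            recs.append((f"P{i}", t, int(i < 12)))  # 40% positive at every time
    fit = fit_time_trend(_long(recs), "y")
    assert fit.coef_time == pytest.approx(0.0, abs=1e-8)
    for p in fit.predicted_probs:
        assert p == pytest.approx(0.4, abs=1e-8)


def test_tiny_dataset_matches_newton_oracle_to_1e6():
    # t=0: 1 of 3 positive; t=1: 2 of 3; t=2: 3 of 3
    recs = [("A", 0, 1), ("B", 0, 0), ("C", 0, 0),
            ("A", 1, 1), ("B", 1, 1), ("C", 1, 0),
            ("A", 2, 1), ("B", 2, 1), ("C", 2, 1)]
    df = _long(recs)
    fit = fit_time_trend(df, "y")
    X = np.column_stack([np.ones(len(df)), df["time"].to_numpy(float)])
    beta = newton_logit_mle(X, df["y"].to_numpy(float))
    assert fit.intercept == pytest.approx(beta[0], abs=1e-6)
    assert fit.coef_time == pytest.approx(beta[1], abs=1e-6)


def test_random_small_datasets_match_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(12, 50))
        t = rng.integers(0, 3, size=n)
        true = -0.3 + 0.6 * t
        y = (rng.random(n) < 1 / (1 + np.exp(-true))).astype(int)
        if len(np.unique(y)) < 2 or any(
                len(np.unique(y[t == v])) < 1 for v in np.unique(t)):
            continue
        df = _long([(f"P{i}", int(t[i]), int(y[i])) for i in range(n)])
        fit = fit_time_trend(df, "y")
        if fit.penalized:
            continue  # separated draw: MLE does not exist
        X = np.column_stack([np.ones(n), t.astype(float)])
        beta = newton_logit_mle(X, y.astype(float))
        if not np.all(np.abs(beta) < 12):
            continue
        assert fit.intercept == pytest.approx(beta[0], abs=1e-6)
        assert fit.coef_time == pytest.approx(beta[1], abs=1e-6)


def test_predicted_probs_monotone_with_slope_sign(rng):
    for _ in range(10):
        n = 60
        t = rng.integers(0, 3, size=n)
        y = (rng.random(n) < 0.3 + 0.2 * t).astype(int)
        df = _long([(f"P{i}", int(t[i]), int(y[i])) for i in range(n)])
        try:
            fit = fit_time_trend(df, "y")
        except ValueError:
            continue
        probs = fit.predicted_probs
        assert all(0.0 < p < 1.0 for p in probs)
        diffs = np.diff(probs)
        if fit.coef_time > 0:
            assert (diffs > 0).all()
        elif fit.coef_time < 0:
            assert (diffs < 0).all()


def test_single_time_value_is_an_error():
    df = _long([("A", 1, 0), ("B", 1, 1)])
    with pytest.raises(ValueError, match="two distinct time"):
        fit_time_trend(df, "y")


def test_gee_variant_agrees_in_sign():
    recs = []
    rng = np.random.default_rng(5)
    for i in range(120):
        for t in (0, 1, 2):
            recs.append((f"P{i}", t, int(rng.random() < 0.3 + 0.2 * t)))
    df = _long(recs)
    pooled = fit_time_trend(df, "y", method="pooled")
    gee = fit_time_trend(df, "y", method="gee")
    assert np.sign(pooled.coef_time) == np.sign(gee.coef_time)
    assert gee.coef_time == pytest.approx(pooled.coef_time, abs=0.3)


# ------------------------------------------------------------- correlates

@pytest.fixture(scope="module")
def cohort_frame():
    cfg = CohortConfig(n_participants=600, seed=31)
    people, tests = generate_cohort(cfg)
    from carecascade.cascade import classify_cohort
    statuses = classify_cohort(people, tests)
    return build_correlates_frame(people, statuses)


def test_benchmark_fit_returns_all_terms(cohort_frame):
    fits = fit_benchmark_correlates(cohort_frame, "retained")
    terms = {f.term for f in fits}
    assert any("site" in t for t in terms)
    assert any("race" in t for t in terms)
    assert "age" in terms and "category_a" in terms and "baseline" in terms
    for f in fits:
        assert f.se > 0 and 0.0 <= f.p_value <= 1.0
        assert f.n_obs <= len(cohort_frame)


def test_outcome_equal_to_baseline_makes_baseline_dominate(cohort_frame):
    df = cohort_frame.copy()
    df["retained"] = df["retained_t0"]  # perfect autocorrelation
    fits = {f.term: f for f in fit_benchmark_correlates(df, "retained")}
    base = fits["baseline"]
    others = [f for t, f in fits.items() if t != "baseline"]
    assert abs(base.coef) > 5  # quasi-separated: dominates the fit
    assert all(abs(f.coef) < abs(base.coef) for f in others)


def test_planted_age_effect_recovered():
    rng = np.random.default_rng(99)
    cfg = CohortConfig(n_participants=2000, seed=41)
    people, tests = generate_cohort(cfg)
    from carecascade.cascade import classify_cohort
    frame = build_correlates_frame(people, classify_cohort(people, tests))
    beta_age = 0.05
    eta = -2.0 + beta_age * frame["age"].to_numpy()
    frame["retained"] = (rng.random(len(frame)) < 1 / (1 + np.exp(-eta))).astype(int)
    frame["retained_t0"] = rng.integers(0, 2, size=len(frame))
    fits = {f.term: f for f in fit_benchmark_correlates(frame, "retained")}
    age = fits["age"]
    assert abs(age.coef - beta_age) < 3 * age.se
    assert age.p_value < 0.05


def test_separating_site_level_is_dropped():
    rng = np.random.default_rng(7)
    cfg = CohortConfig(n_participants=400, seed=51)
    people, tests = generate_cohort(cfg)
    from carecascade.cascade import classify_cohort
    frame = build_correlates_frame(people, classify_cohort(people, tests))
    frame.loc[frame["site"] == "D", "suppressed"] = 0  # nobody suppressed at D
    fits = fit_benchmark_correlates(frame, "suppressed")
    assert any("site=D" in d for f in fits for d in f.dropped_levels)
    assert not any("site, " in f.term and "[T.D]" in f.term for f in fits)


def test_add_one_reports_only_the_extra_term(cohort_frame):
    fits = fit_add_one(cohort_frame, "retained", "ever_incarcerated")
    assert len(fits) == 1 and fits[0].term == "ever_incarcerated"
    assert fits[0].model == "add_one"


def test_add_one_complete_case_n_shrinks_with_missingness(cohort_frame):
    # restrict to dense strata so no factor level separates and the
    # complete-case count is a pure row count
    df = cohort_frame[
        cohort_frame["race"].isin(["black", "white"])
        & cohort_frame["gender"].isin(["male", "female"])
        & cohort_frame["site"].isin(["A", "B", "C"])
    ].reset_index(drop=True).copy()
    df["extra"] = np.arange(len(df)) % 3 * 1.0
    full = fit_add_one(df, "retained", "extra")[0]
    assert full.dropped_levels == ()
    df.loc[df.index[:150], "extra"] = np.nan
    partial = fit_add_one(df, "retained", "extra")[0]
    assert partial.dropped_levels == ()
    assert partial.n_obs == full.n_obs - 150


def test_add_one_collinear_covariate_flagged(cohort_frame):
    df = cohort_frame.copy()
    df["dup_unemployed"] = df["unemployed"]
    with pytest.raises(ValueError, match="collinear"):
        fit_add_one(df, "retained", "dup_unemployed")


def test_add_one_all_missing_covariate_errors(cohort_frame):
    df = cohort_frame.copy()
    df["ghost"] = np.nan
    with pytest.raises(ValueError, match="complete cases"):
        fit_add_one(df, "retained", "ghost")


def test_long_records_shape(small_cohort):
    from carecascade.cascade import classify_cohort
    people, tests = small_cohort
    statuses = classify_cohort(people, tests)
    df = build_long_records(statuses)
    assert len(df) == 3 * len(people)
    assert set(df["time"].unique()) == {0, 1, 2}
    with pytest.raises(ValueError, match="duplicate"):
        build_long_records(statuses + statuses[:1])
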