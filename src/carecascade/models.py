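"""Longitudinal trend and baseline-correlates regressions for cascade outcomes.

Primary analysis: each binary care-continuum outcome (engagement, retention,
suppression) observed at t = 0, 1, 2 (enrollment, 6 months, 12 months) is
modeled as a pooled logistic regression on time treated as a continuous
0/1/2 counter, with standard errors robust to within-participant clustering.
Model-implied probabilities at each time value (average marginal predicted
probabilities) summarize the trend on the probability scale.

Secondary analysis: single-level logistic regressions of each 12-month
outcome on a benchmark covariate set (age, race, ethnicity, gender,
relationship, employment, housing, insurance, enrollment site, enrollment
category, and the baseline value of the outcome), plus "add-one" models that
append a single sparser covariate to the benchmark controls and report only
that covariate's coefficient on its complete-case subset.

Factor levels within which the outcome is constant (complete separation,
e.g. a site where nobody is suppressed at follow-up) are dropped from the
fit and recorded on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TrendFit",
    "CorrelateFit",
    "build_long_records",
    "build_correlates_frame",
    "fit_time_trend",
    "fit_benchmark_correlates",
    "fit_add_one",
    "BENCHMARK_FORMULA_TERMS",
]

OUTCOMES = ("engaged", "retained", "suppressed")


@dataclass(frozen=True)
class TrendFit:
    outcome: str
    coef_time: float
    se: float
    p_value: float
    intercept: float
    predicted_probs: tuple       # at t = 0, 1, 2
    n_obs: int
    n_participants: int
    method: str = "pooled"
    penalized: bool = False      # separation fallback used


@dataclass(frozen=True)
class CorrelateFit:
    outcome: str
    term: str
    coef: float
    se: float
    p_value: float
    model: str                   # "benchmark" or "add_one"
    n_obs: int
    dropped_levels: tuple = ()


def build_long_records(statuses) -> pd.DataFrame:
    """One row per participant per timepoint with all three binary outcomes."""
    tmap = {"t0": 0, "t1": 1, "t2": 2}
    rows = [{
        "participant_id": s.participant_id,
        "time": tmap[s.timepoint],
        "engaged": int(s.engaged),
        "retained": int(s.retained),
        "suppressed": int(s.suppressed),
    } for s in statuses]
    df = pd.DataFrame(rows)
    if df.duplicated(["participant_id", "time"]).any():
        raise ValueError("duplicate (participant, time) records")
    return df.sort_values(["participant_id", "time"]).reset_index(drop=True)


def fit_time_trend(
    long_records: pd.DataFrame,
    outcome: str,
    method: str = "pooled",
) -> TrendFit:
    """Logistic trend of a binary outcome on time 0/1/2.

    ``pooled`` fits one logit with cluster-robust (by participant) standard
    errors; ``gee`` uses an exchangeable working correlation;
    ``mixed`` adds a participant random intercept (variational fit).
    Predicted probabilities are the average marginal predictions with every
    record's time set to each value in turn.
    """
    if outcome not in long_records.columns:
        raise KeyError(f"outcome column {outcome!r} not in records")
    df = long_records.dropna(subset=[outcome, "time"]).copy()
    times = sorted(df["time"].unique())
    if len(times) < 2:
        raise ValueError("need at least two distinct time values for a trend")
    y = df[outcome].astype(float)
    if set(y.unique()) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    penalized = False
    if method == "pooled":
        model = smf.glm(f"{outcome} ~ time", data=df, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(cov_type="cluster",
                            cov_kwds={"groups": df["participant_id"]})
        params = res.params
        if not np.all(np.isfinite(params)) or np.abs(params["time"]) > 15:
            # complete separation in time: fall back to a light ridge penalty
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
            params = res.params
            penalized = True
        se = float("nan") if penalized else float(res.bse["time"])
        p = float("nan") if penalized else float(res.pvalues["time"])
    elif method == "gee":
        model = smf.gee(f"{outcome} ~ time", groups="participant_id", data=df,
                        family=sm.families.Binomial(),
                        cov_struct=sm.cov_struct.Exchangeable())
        res = model.fit()
        params = res.params
        se, p = float(res.bse["time"]), float(res.pvalues["time"])
    elif method == "mixed":
        model = sm.BinomialBayesMixedGLM.from_formula(
            f"{outcome} ~ time", {"participant": "0 + C(participant_id)"}, df)
        res = model.fit_vb()
        names = list(res.model.exog_names)
        params = pd.Series(res.fe_mean, index=names)
        se = float(res.fe_sd[names.index("time")])
        from scipy import stats
        p = float(2 * stats.norm.sf(abs(params["time"] / se)))
    else:
        raise ValueError(f"unknown method {method!r}")

    b0, b1 = float(params["Intercept"]), float(params["time"])
    probs = tuple(float(1.0 / (1.0 + np.exp(-(b0 + b1 * t)))) for t in (0, 1, 2))
    return TrendFit(
        outcome=outcome, coef_time=b1, se=se, p_value=p, intercept=b0,
        predicted_probs=probs, n_obs=len(df),
        n_participants=df["participant_id"].nunique(),
        method=method, penalized=penalized,
    )


# Benchmark covariates with their preferred reference levels; the 12-month
# outcome is regressed on these plus the baseline value of the same outcome.
BENCHMARK_FORMULA_TERMS = (
    "baseline",
    "age",
    "C(race, Treatment(reference='white'))",
    "hispanic",
    "C(gender, Treatment(reference='female'))",
    "primary_partner",
    "unemployed",
    "unstable_housing",
    "insured",
    "C(site, Treatment(reference='A'))",
    "category_a",
)

_BENCHMARK_COLS = ("baseline", "age", "race", "hispanic", "gender", "primary_partner",
                   "unemployed", "unstable_housing", "insured", "site", "category_a")
_CATEGORICAL_COLS = ("race", "gender", "site")
_PREFERRED_REF = {"race": "white", "gender": "female", "site": "A"}


def _cat_term(df: pd.DataFrame, col: str, preferred: str) -> str | None:
    """Treatment-coded term; falls back to the modal reference when the
    preferred level is absent, and drops constant factors entirely."""
    levels = df[col].unique()
    if len(levels) < 2:
        return None
    ref = preferred if preferred in levels else df[col].mode().iloc[0]
    return f"C({col}, Treatment(reference={ref!r}))"


def _benchmark_terms(df: pd.DataFrame) -> list[str]:
    terms: list[str | None] = ["baseline", "age",
                               _cat_term(df, "race", _PREFERRED_REF["race"]),
                               "hispanic",
                               _cat_term(df, "gender", _PREFERRED_REF["gender"]),
                               "primary_partner", "unemployed", "unstable_housing",
                               "insured",
                               _cat_term(df, "site", _PREFERRED_REF["site"]),
                               "category_a"]
    return [t for t in terms if t is not None]


def build_correlates_frame(participants, statuses, scores=None) -> pd.DataFrame:
    """Analysis frame for the 12-month correlates models.

    One row per participant: 12-month and baseline outcomes, the benchmark
    covariates, and the sparser add-one covariates (survey scores included
    when ``scores`` maps participant id -> InstrumentScores).
    """
    by_tp: dict[tuple, object] = {(s.participant_id, s.timepoint): s for s in statuses}
    rows = []
    for p in participants:
        s0, s2 = by_tp.get((p.id, "t0")), by_tp.get((p.id, "t2"))
        if s0 is None or s2 is None:
            continue
        years_with_hiv = (p.enrollment_date - p.diagnosis_date).days / 360.0
        row = {
            "participant_id": p.id,
            "engaged": int(s2.engaged), "retained": int(s2.retained),
            "suppressed": int(s2.suppressed),
            "engaged_t0": int(s0.engaged), "retained_t0": int(s0.retained),
            "suppressed_t0": int(s0.suppressed),
            "age": p.age_years,
            "race": p.race,
            "hispanic": int(p.ethnicity == "hispanic_latinx"),
            "gender": p.gender,
            "primary_partner": int(p.relationship == "primary_partner"),
            "unemployed": int(p.employment == "unemployed"),
            "unstable_housing": int(p.housing == "unstable"),
            "insured": int(p.insurance == "insured"),
            "site": p.site,
            "category_a": int(p.enrollment_category == "A"),
            # add-one covariates
            "heterosexual": int(p.sexual_orientation == "heterosexual"),
            "income_band": p.income_band,
            "education": p.education,
            "years_with_hiv_band": ("lt_1" if years_with_hiv < 1
                                    else "1_to_5" if years_with_hiv < 5 else "gt_5"),
            "ever_incarcerated": int(p.incarceration == "recent"),
        }
        if scores is not None and p.id in scores:
            sc = scores[p.id]
            row.update({
                "stigma_mean": sc.stigma_mean,
                "case_total": sc.case_total,
                "phq9_total": sc.phq9_total,
                "acceptability": sc.acceptability,
                "auditc": None if sc.hazardous_alcohol is None else int(sc.hazardous_alcohol),
            })
        rows.append(row)
    return pd.DataFrame(rows)


def _drop_separating_levels(df: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, list[str]]:
    """Drop rows in factor levels where the outcome is constant (separation)."""
    dropped = []
    for col in _CATEGORICAL_COLS:
        if col not in df.columns:
            continue
        for level, grp in df.groupby(col, observed=True):
            if grp[outcome].nunique() == 1 and df[col].nunique() > 1:
                df = df[df[col] != level]
                dropped.append(f"{col}={level}")
    return df, dropped


def _fit_logit(df: pd.DataFrame, formula: str):
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit()


def fit_benchmark_correlates(frame: pd.DataFrame, outcome: str) -> list[CorrelateFit]:
    """Benchmark logistic regression of a 12-month outcome; one fit per term."""
    if outcome not in ("engaged", "retained", "suppressed"):
        raise ValueError(f"unknown outcome {outcome!r}")
    df = frame.copy()
    df["baseline"] = df[f"{outcome}_t0"]
    cols = ["participant_id", outcome, *(_BENCHMARK_COLS)]
    df = df[cols].dropna()
    df, dropped = _drop_separating_levels(df, outcome)
    formula = f"{outcome} ~ " + " + ".join(_benchmark_terms(df))
    res = _fit_logit(df, formula)
    fits = []
    for term in res.params.index:
        if term == "Intercept":
            continue
        fits.append(CorrelateFit(
            outcome=outcome, term=term,
            coef=float(res.params[term]), se=float(res.bse[term]),
            p_value=float(res.pvalues[term]), model="benchmark",
            n_obs=int(res.nobs), dropped_levels=tuple(dropped),
        ))
    return fits


def fit_add_one(frame: pd.DataFrame, outcome: str, extra_covariate: str,
                categorical: bool = False, reference: str | None = None
                ) -> list[CorrelateFit]:
    """Benchmark controls plus one sparser covariate; report the extra term only.

    Fit on the complete-case subset of the extra covariate; raises on an
    all-missing or perfectly collinear extra covariate.
    """
    if extra_covariate not in frame.columns:
        raise KeyError(f"covariate {extra_covariate!r} not in frame")
    df = frame.copy()
    df["baseline"] = df[f"{outcome}_t0"]
    cols = ["participant_id", outcome, *(_BENCHMARK_COLS), extra_covariate]
    df = df[cols].dropna()
    if df.empty:
        raise ValueError(f"{extra_covariate!r} has no complete cases")
    df, dropped = _drop_separating_levels(df, outcome)
    if categorical:
        ref = f", Treatment(reference={reference!r})" if reference else ""
        extra_term = f"C({extra_covariate}{ref})"
    else:
        extra_term = extra_covariate
        # collinearity guard: extra must add rank beyond the benchmark design
        bench = pd.get_dummies(df[list(_BENCHMARK_COLS)], drop_first=True).astype(float)
        x = df[extra_covariate].astype(float).to_numpy()
        design = np.column_stack([np.ones(len(bench)), bench.to_numpy()])
        rank0 = np.linalg.matrix_rank(design)
        rank1 = np.linalg.matrix_rank(np.column_stack([design, x]))
        if rank1 == rank0:
            raise ValueError(
                f"{extra_covariate!r} is collinear with the benchmark covariates")
    formula = f"{outcome} ~ " + " + ".join((*_benchmark_terms(df), extra_term))
    res = _fit_logit(df, formula)
    fits = []
    for term in res.params.index:
        if extra_covariate not in term:
            continue
        fits.append(CorrelateFit(
            outcome=outcome, term=term,
            coef=float(res.params[term]), se=float(res.bse[term]),
            p_value=float(res.pvalues[term]), model="add_one",
            n_obs=int(res.nobs), dropped_levels=tuple(dropped),
        ))
    if not fits:
        raise RuntimeError(f"no coefficient estimated for {extra_covariate!r}")
    return fits
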