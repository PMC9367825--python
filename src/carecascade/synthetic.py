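"""Seeded synthetic cohorts for an incentive-program care-continuum evaluation.

No participant-level data from such programs are publicly depositable, so
every downstream stage (screening, cascade classification, incentive
accounting, regression, costing) is exercised on synthetic cohorts whose
statistical structure matches what the analysis assumes:

* categorical demographics drawn from configurable marginal distributions
  (defaults reproduce the realized baseline table of a four-clinic, n = 781
  urban Southern US cohort: 89% Black/African American, 53% male, 90%
  insured, 58% enrolled under the out-of-care Category A stratum, ...);
* a lab-visit event stream per participant spanning 12 months before
  enrollment through 13 months after, generated as a homogeneous event
  process with period-specific rates (pre-enrollment vs. post-enrollment,
  the latter multiplied by an incentive attendance boost);
* viral-load values placed clearly on either side of the 200 copies/mL
  suppression threshold, governed by per-timepoint suppression indicators;
* baseline survey instruments (incentive acceptability, AUDIT-C, PHQ-9,
  CASE adherence, internalized stigma) with realistic central tendency and
  item-level missingness;
* per-clinic cost inputs on the scale of a one-year micro-costing exercise.

Reproducibility: one master seed; each participant gets a deterministic
child stream (``numpy.random.SeedSequence.spawn``), so participant i's data
do not change when the cohort grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from decimal import Decimal

import numpy as np

__all__ = [
    "CohortConfig",
    "Participant",
    "LabTest",
    "SurveyResponse",
    "DEFAULT_MARGINALS",
    "generate_cohort",
    "generate_cost_inputs",
]

# Marginal distributions of the baseline characteristics the generator
# reproduces; shares are the realized ones from a 781-participant program.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "race": {"black": 0.892, "white": 0.082, "other": 0.016, "multiracial": 0.010},
    "ethnicity": {"hispanic_latinx": 0.016, "not_hispanic_latinx": 0.984},
    "gender": {"male": 0.532, "female": 0.447, "gender_minority": 0.021},
    "sexual_orientation": {"heterosexual": 0.678, "sexual_minority": 0.322},
    "relationship": {"primary_partner": 0.174, "no_primary_partner": 0.826},
    "education": {"less_than_hs": 0.328, "hs_or_some_college": 0.532, "postsecondary": 0.140},
    "employment": {"unemployed": 0.426, "employed": 0.373, "disabled": 0.156, "other": 0.045},
    "income_band": {
        "lt_5000": 0.425, "5000_9999": 0.154, "10000_14999": 0.118,
        "15000_19999": 0.070, "gte_20000": 0.233,
    },
    "housing": {"unstable": 0.135, "stable": 0.865},
    "incarceration": {"recent": 0.117, "none": 0.883},
    "insurance": {"insured": 0.897, "uninsured": 0.103},
    "site": {"A": 0.35, "B": 0.20, "C": 0.30, "D": 0.15},
    "years_with_hiv": {"lt_1": 0.085, "1_to_5": 0.245, "gt_5": 0.670},
}


@dataclass(frozen=True)
class SurveyResponse:
    """Raw baseline survey items; None encodes a skipped item."""

    acceptability_items: tuple  # 4 ints in [0,4] or None
    auditc_score: int | None
    phq9_items: tuple           # 9 ints in [0,3] or None
    case_total: int | None      # 3-16
    stigma_items: tuple         # ints in [1,5] or None
    gender: str = "male"


@dataclass(frozen=True)
class LabTest:
    participant_id: str
    test_date: date
    viral_load: int

    def __post_init__(self):
        if self.viral_load < 0:
            raise ValueError("viral_load must be non-negative")


@dataclass(frozen=True)
class Participant:
    id: str
    enrollment_date: date
    age_years: float
    race: str
    ethnicity: str
    gender: str
    sexual_orientation: str
    relationship: str
    education: str
    employment: str
    income_band: str
    housing: str
    incarceration: str
    insurance: str
    site: str
    enrollment_category: str   # "A" or "B"
    diagnosis_date: date
    survey: SurveyResponse | None = None

    def __post_init__(self):
        if self.age_years < 18:
            raise ValueError("participants are adults (age >= 18)")
        if self.diagnosis_date > self.enrollment_date:
            raise ValueError("diagnosis_date must not follow enrollment_date")


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the cohort generator; defaults encode the study conditions."""

    n_participants: int = 781
    seed: int = 0
    marginals: dict = field(default_factory=lambda: DEFAULT_MARGINALS)
    category_a_share: float = 0.58
    enforce_category_quota: bool = False  # protocol quota: >= 80% Category A
    visit_rate_base: float = 1.2          # expected lab visits / year, pre-enrollment
    incentive_visit_boost: float = 2.2    # multiplicative rate effect post-enrollment
    p_suppressed_given_visit: tuple = (0.62, 0.52, 0.40)
    suppressed_vl: int = 50
    detectable_vl: int = 10_000
    survey_missing_rate: float = 0.12
    enrollment_window: tuple = (date(2018, 8, 1), date(2019, 10, 31))

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 0.0 <= self.category_a_share <= 1.0:
            raise ValueError("category_a_share must be in [0, 1]")
        if self.visit_rate_base < 0 or self.incentive_visit_boost < 0:
            raise ValueError("visit rates must be non-negative")
        for var, dist in self.marginals.items():
            total = sum(dist.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"marginal for {var!r} sums to {total!r}, expected 1.0"
                )
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"marginal for {var!r} has a negative probability")
        if len(self.p_suppressed_given_visit) != 3:
            raise ValueError("p_suppressed_given_visit needs one value per timepoint")
        for p in self.p_suppressed_given_visit:
            if not 0.0 <= p <= 1.0:
                raise ValueError("suppression probabilities must be in [0, 1]")


def _draw_categorical(rng: np.random.Generator, dist: dict[str, float]) -> str:
    levels = list(dist)
    probs = np.asarray([dist[k] for k in levels], dtype=float)
    return levels[rng.choice(len(levels), p=probs / probs.sum())]


def _visit_dates(rng, rate_per_year: float, start_day: int, end_day: int) -> list[int]:
    """Homogeneous event process on [start_day, end_day] (days from enrollment)."""
    span = end_day - start_day + 1
    lam = rate_per_year * span / 360.0
    n = rng.poisson(lam)
    return sorted(int(d) for d in rng.integers(start_day, end_day + 1, size=n))


def _governing_timepoint(day: int) -> int:
    """Which timepoint's suppression indicator sets a test's viral load."""
    if day <= 0:
        return 0
    return 1 if day <= 270 else 2


def _make_survey(rng, gender: str, miss: float) -> SurveyResponse:
    def maybe(x):
        return None if rng.random() < miss else x

    accept = tuple(maybe(int(rng.integers(0, 5))) for _ in range(4))
    phq = tuple(maybe(int(np.clip(rng.poisson(0.8), 0, 3))) for _ in range(9))
    stigma = tuple(maybe(int(np.clip(round(rng.normal(4.6, 0.5)), 1, 5))) for _ in range(6))
    auditc = maybe(int(np.clip(rng.poisson(2.2), 0, 12)))
    case = maybe(int(np.clip(round(rng.normal(11.8, 3.6)), 3, 16)))
    return SurveyResponse(accept, auditc, phq, case, stigma, gender)


def generate_cohort(config: CohortConfig) -> tuple[list[Participant], list[LabTest]]:
    """Generate a seeded cohort of participants and their lab-test streams.

    Deterministic in ``config.seed``; lab streams span the 12 months before
    enrollment through 13 months after (day -360 to day +390).
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_participants + 1)  # streams[0] reserved

    window_start, window_end = config.enrollment_window
    window_days = (window_end - window_start).days

    if config.enforce_category_quota:
        a_share = max(config.category_a_share, 0.80)
    else:
        a_share = config.category_a_share

    participants: list[Participant] = []
    tests: list[LabTest] = []
    for i in range(config.n_participants):
        rng = np.random.default_rng(streams[i + 1])
        pid = f"P{i:05d}"
        enrollment = window_start + timedelta(days=int(rng.integers(0, window_days + 1)))
        cats = {var: _draw_categorical(rng, dist) for var, dist in config.marginals.items()}
        age = float(np.clip(rng.normal(42.4, 12.2), 18.0, 90.0))
        category = "A" if rng.random() < a_share else "B"
        years_band = cats.pop("years_with_hiv", "gt_5")
        years_back = {"lt_1": rng.uniform(0.3, 1.0),
                      "1_to_5": rng.uniform(1.0, 5.0),
                      "gt_5": rng.uniform(5.0, 20.0)}[years_band]
        diagnosis = enrollment - timedelta(days=int(years_back * 360))
        survey = _make_survey(rng, cats["gender"], config.survey_missing_rate)
        participants.append(Participant(
            id=pid, enrollment_date=enrollment, age_years=round(age, 1),
            race=cats["race"], ethnicity=cats["ethnicity"], gender=cats["gender"],
            sexual_orientation=cats["sexual_orientation"], relationship=cats["relationship"],
            education=cats["education"], employment=cats["employment"],
            income_band=cats["income_band"], housing=cats["housing"],
            incarceration=cats["incarceration"], insurance=cats["insurance"],
            site=cats["site"], enrollment_category=category,
            diagnosis_date=diagnosis, survey=survey,
        ))

        suppressed_at = [rng.random() < p for p in config.p_suppressed_given_visit]
        base, boost = config.visit_rate_base, config.incentive_visit_boost
        days = _visit_dates(rng, base, -360, -1)
        days += _visit_dates(rng, base * boost, 1, 180)
        days += _visit_dates(rng, base * boost, 181, 390)
        days.append(0)  # the enrollment-day baseline visit always happens
        for day in sorted(set(days)):
            governed = suppressed_at[_governing_timepoint(day)]
            vl = config.suppressed_vl if governed else config.detectable_vl
            tests.append(LabTest(pid, enrollment + timedelta(days=day), vl))

    tests.sort(key=lambda t: (t.participant_id, t.test_date))
    return participants, tests


def generate_cost_inputs(clinic_profiles, seed: int = 0):
    """Per-clinic cost inputs, exact or sampled.

    Each profile is a mapping with ``clinic_id``, ``n_clients``,
    ``n_contacts``; either exact component costs (``client_costs``,
    ``staff_costs``, ``materials_costs``) or per-client means
    (``client_cost_per_client``, ...) sampled with 20% lognormal spread.
    """
    from .econ import CostInputs  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    out = []
    for prof in clinic_profiles:
        if "client_costs" in prof:
            costs = {k: Decimal(str(prof[k]))
                     for k in ("client_costs", "staff_costs", "materials_costs")}
        else:
            n = prof["n_clients"]
            costs = {}
            for comp in ("client", "staff", "materials"):
                mean = float(prof.get(f"{comp}_cost_per_client", 0.0))
                if mean <= 0:
                    costs[f"{comp}_costs"] = Decimal("0")
                else:
                    sigma = 0.2
                    draw = rng.lognormal(math.log(mean) - sigma**2 / 2, sigma) * n
                    costs[f"{comp}_costs"] = Decimal(str(round(draw, 2)))
        out.append(CostInputs(
            clinic_id=str(prof["clinic_id"]),
            n_clients=int(prof["n_clients"]),
            n_contacts=int(prof["n_contacts"]),
            **costs,
        ))
    return out
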