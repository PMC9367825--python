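"""CSV schemas, validated readers/writers, and the end-to-end pipeline.

All tables are UTF-8 comma-separated CSV with a header row, ISO-8601 dates,
"." decimals, and money serialized to 2 decimals. ``run_pipeline`` chains
simulate -> cascade -> incentives -> surveys -> models -> econ and returns a
manifest (row counts + SHA-256 checksums), which is bit-reproducible for a
fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from decimal import Decimal, InvalidOperation
from pathlib import Path

import pandas as pd

from . import cascade as cascade_mod
from . import econ as econ_mod
from . import incentives as inc_mod
from . import models as models_mod
from . import surveys as surveys_mod
from .synthetic import CohortConfig, LabTest, Participant, SurveyResponse, generate_cohort

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "read_table",
    "write_table",
    "participants_to_frame",
    "frame_to_participants",
    "lab_tests_to_frame",
    "frame_to_lab_tests",
    "statuses_to_frame",
    "cost_inputs_to_frame",
    "frame_to_cost_inputs",
    "events_to_frame",
    "RunConfig",
    "RunReport",
    "run_pipeline",
]

log = logging.getLogger("carecascade")

# column -> value kind; kinds drive parsing and validation
SCHEMAS: dict[str, dict[str, str]] = {
    "participants": {
        "id": "str", "enrollment_date": "date", "age_years": "float",
        "race": "str", "ethnicity": "str", "gender": "str",
        "sexual_orientation": "str", "relationship": "str", "education": "str",
        "employment": "str", "income_band": "str", "housing": "str",
        "incarceration": "str", "insurance": "str", "site": "str",
        "enrollment_category": "str", "diagnosis_date": "date",
        **{f"accept_{i}": "opt_int" for i in range(1, 5)},
        "auditc": "opt_int",
        **{f"phq9_{i}": "opt_int" for i in range(1, 10)},
        "case_total": "opt_int",
        **{f"stigma_{i}": "opt_int" for i in range(1, 7)},
    },
    "lab_tests": {"participant_id": "str", "test_date": "date", "viral_load": "nonneg_int"},
    "cost_inputs": {
        "clinic_id": "str", "n_clients": "pos_int", "n_contacts": "pos_int",
        "client_costs_usd": "money", "staff_costs_usd": "money",
        "materials_costs_usd": "money",
    },
    "cascade": {
        "participant_id": "str", "timepoint": "str", "engaged": "bool",
        "retained": "bool", "suppressed": "bool", "n_tests_in_window": "nonneg_int",
    },
    "incentive_events": {
        "participant_id": "str", "event_type": "str", "date": "date",
        "amount_usd": "money",
    },
    "scores": {
        "participant_id": "str", "acceptability": "opt_float",
        "hazardous_alcohol": "opt_bool", "phq9_total": "opt_int",
        "case_total": "opt_int", "stigma_mean": "opt_float",
    },
}


class SchemaError(ValueError):
    pass


def _parse_cell(raw, kind: str, row: int, col: str):
    missing = raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == ""
    if kind.startswith("opt_"):
        if missing:
            return None
        kind = kind[4:]
    elif missing:
        raise SchemaError(f"row {row}, column {col!r}: missing value")
    try:
        if kind == "str":
            return str(raw)
        if kind == "date":
            return date.fromisoformat(str(raw))
        if kind == "float":
            return float(raw)
        if kind == "money":
            v = Decimal(str(raw))
            if v < 0:
                raise SchemaError(f"row {row}, column {col!r}: negative amount {raw}")
            return v
        if kind == "bool":
            if str(raw).lower() in ("true", "1"):
                return True
            if str(raw).lower() in ("false", "0"):
                return False
            raise ValueError(raw)
        if kind in ("int", "nonneg_int", "pos_int"):
            f = float(raw)  # tolerate "4.0" from float-promoted columns
            if f != int(f):
                raise ValueError(raw)
            v = int(f)
            if kind == "nonneg_int" and v < 0:
                raise SchemaError(f"row {row}, column {col!r}: negative value {v}")
            if kind == "pos_int" and v < 1:
                raise SchemaError(f"row {row}, column {col!r}: non-positive value {v}")
            return v
    except SchemaError:
        raise
    except (ValueError, InvalidOperation) as exc:
        raise SchemaError(f"row {row}, column {col!r}: cannot parse {raw!r} as {kind}") from exc
    raise SchemaError(f"unknown kind {kind!r} for column {col!r}")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one of the pipeline CSVs; errors name row and column."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    columns = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(columns) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    parsed = {}
    for col, kind in columns.items():
        parsed[col] = [
            _parse_cell(v, kind, i, col) for i, v in enumerate(df[col].tolist())
        ]
    return pd.DataFrame(parsed)


def _serialize(value):
    if isinstance(value, Decimal):
        return f"{value:.2f}"
    if isinstance(value, date):
        return value.isoformat()
    if isinstance(value, bool):
        return str(value).lower()
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return value


def write_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(_serialize)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------- converters

def participants_to_frame(participants) -> pd.DataFrame:
    rows = []
    for p in participants:
        s = p.survey
        row = {k: getattr(p, k) for k in (
            "id", "enrollment_date", "age_years", "race", "ethnicity", "gender",
            "sexual_orientation", "relationship", "education", "employment",
            "income_band", "housing", "incarceration", "insurance", "site",
            "enrollment_category", "diagnosis_date")}
        if s is not None:
            row.update({f"accept_{i+1}": s.acceptability_items[i] for i in range(4)})
            row["auditc"] = s.auditc_score
            row.update({f"phq9_{i+1}": s.phq9_items[i] for i in range(9)})
            row["case_total"] = s.case_total
            row.update({f"stigma_{i+1}": s.stigma_items[i] for i in range(6)})
        rows.append(row)
    return pd.DataFrame(rows)


def _opt_int(v):
    # None survives a DataFrame only as NaN, promoting the column to float
    return None if v is None or pd.isna(v) else int(v)


def frame_to_participants(df: pd.DataFrame) -> list[Participant]:
    out = []
    for _, r in df.iterrows():
        survey = SurveyResponse(
            acceptability_items=tuple(_opt_int(r.get(f"accept_{i}")) for i in range(1, 5)),
            auditc_score=_opt_int(r.get("auditc")),
            phq9_items=tuple(_opt_int(r.get(f"phq9_{i}")) for i in range(1, 10)),
            case_total=_opt_int(r.get("case_total")),
            stigma_items=tuple(_opt_int(r.get(f"stigma_{i}")) for i in range(1, 7)),
            gender=r["gender"],
        )
        out.append(Participant(
            id=r["id"], enrollment_date=r["enrollment_date"],
            age_years=r["age_years"], race=r["race"], ethnicity=r["ethnicity"],
            gender=r["gender"], sexual_orientation=r["sexual_orientation"],
            relationship=r["relationship"], education=r["education"],
            employment=r["employment"], income_band=r["income_band"],
            housing=r["housing"], incarceration=r["incarceration"],
            insurance=r["insurance"], site=r["site"],
            enrollment_category=r["enrollment_category"],
            diagnosis_date=r["diagnosis_date"], survey=survey,
        ))
    return out


def lab_tests_to_frame(tests) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in tests])


def frame_to_lab_tests(df: pd.DataFrame) -> list[LabTest]:
    return [LabTest(r["participant_id"], r["test_date"], r["viral_load"])
            for _, r in df.iterrows()]


def statuses_to_frame(statuses) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in statuses])


def frame_to_statuses(df: pd.DataFrame):
    return [cascade_mod.CascadeStatus(
        r["participant_id"], r["timepoint"], r["engaged"], r["retained"],
        r["suppressed"], r["n_tests_in_window"],
    ) for _, r in df.iterrows()]


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": e.participant_id, "event_type": e.event_type.value,
        "date": e.date, "amount_usd": e.amount,
    } for e in events])


def cost_inputs_to_frame(inputs) -> pd.DataFrame:
    return pd.DataFrame([{
        "clinic_id": c.clinic_id, "n_clients": c.n_clients, "n_contacts": c.n_contacts,
        "client_costs_usd": c.client_costs, "staff_costs_usd": c.staff_costs,
        "materials_costs_usd": c.materials_costs,
    } for c in inputs])


def frame_to_cost_inputs(df: pd.DataFrame):
    return [econ_mod.CostInputs(
        clinic_id=r["clinic_id"], n_clients=r["n_clients"], n_contacts=r["n_contacts"],
        client_costs=r["client_costs_usd"], staff_costs=r["staff_costs_usd"],
        materials_costs=r["materials_costs_usd"],
    ) for _, r in df.iterrows()]


# ------------------------------------------------------------------ pipeline

@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    cohort: CohortConfig | None = None
    cascade: cascade_mod.CascadeConfig = field(default_factory=cascade_mod.CascadeConfig)
    schedule: inc_mod.IncentiveSchedule = field(default_factory=inc_mod.IncentiveSchedule)
    constants: econ_mod.EconConstants = field(default_factory=econ_mod.EconConstants)
    convention: str = "missing_as_false"
    trend_method: str = "pooled"
    cost_inputs: list | None = None      # None -> bundled worked example
    net_suppressed: dict | None = None


@dataclass
class RunReport:
    manifest: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add(self, path: Path, rows: int) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.manifest.append({"file": str(path), "rows": rows, "sha256": digest})


def run_pipeline(config: RunConfig) -> RunReport:
    """Simulate a cohort and run every analysis stage, writing all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    cohort_cfg = config.cohort or CohortConfig(seed=config.seed)

    log.info("simulate: n=%d seed=%d", cohort_cfg.n_participants, cohort_cfg.seed)
    participants, tests = generate_cohort(cohort_cfg)
    p_path, t_path = outdir / "participants.csv", outdir / "lab_tests.csv"
    write_table(participants_to_frame(participants), p_path)
    write_table(lab_tests_to_frame(tests), t_path)
    report.add(p_path, len(participants))
    report.add(t_path, len(tests))

    from .screening import screen_cohort

    screening = screen_cohort(participants, tests)
    screening.to_csv(outdir / "screening.csv", index=False)
    report.add(outdir / "screening.csv", len(screening))

    statuses = cascade_mod.classify_cohort(participants, tests, config.cascade)
    c_path = outdir / "cascade.csv"
    write_table(statuses_to_frame(statuses), c_path)
    report.add(c_path, len(statuses))
    table = cascade_mod.cascade_table(statuses, convention=config.convention)
    table.to_csv(outdir / "cascade_table.csv", index=False)
    report.add(outdir / "cascade_table.csv", len(table))

    ledger = inc_mod.build_ledger(statuses, tests, participants, config.schedule)
    e_path = outdir / "incentive_events.csv"
    write_table(events_to_frame(ledger), e_path)
    report.add(e_path, len(ledger))
    summary = inc_mod.ledger_summary(ledger, config.schedule)
    summary_json = {k: (str(v) if isinstance(v, Decimal) else v)
                    for k, v in summary.items()}
    (outdir / "incentive_summary.json").write_text(json.dumps(summary_json, indent=2))
    report.add(outdir / "incentive_summary.json", 1)

    score_rows, scores_by_pid = [], {}
    for p in participants:
        if p.survey is None:
            continue
        sc = surveys_mod.scale_totals(p.survey)
        scores_by_pid[p.id] = sc
        score_rows.append({
            "participant_id": p.id, "acceptability": sc.acceptability,
            "hazardous_alcohol": sc.hazardous_alcohol, "phq9_total": sc.phq9_total,
            "case_total": sc.case_total, "stigma_mean": sc.stigma_mean,
        })
    s_path = outdir / "scores.csv"
    write_table(pd.DataFrame(score_rows), s_path)
    report.add(s_path, len(score_rows))

    long_df = models_mod.build_long_records(statuses)
    trend_rows = []
    for outcome in models_mod.OUTCOMES:
        fit = models_mod.fit_time_trend(long_df, outcome, method=config.trend_method)
        trend_rows.append({
            "outcome": outcome, "coef_time": fit.coef_time, "se": fit.se,
            "p_value": fit.p_value, "p_t0": fit.predicted_probs[0],
            "p_t1": fit.predicted_probs[1], "p_t2": fit.predicted_probs[2],
            "n_obs": fit.n_obs,
        })
    pd.DataFrame(trend_rows).to_csv(outdir / "trend_fits.csv", index=False)
    report.add(outdir / "trend_fits.csv", len(trend_rows))

    frame = models_mod.build_correlates_frame(participants, statuses, scores_by_pid)
    corr_rows = []
    for outcome in models_mod.OUTCOMES:
        fits = models_mod.fit_benchmark_correlates(frame, outcome)
        for fit in fits:
            corr_rows.append({
                "outcome": outcome, "term": fit.term, "coef": fit.coef,
                "se": fit.se, "p": fit.p_value, "model": fit.model, "n": fit.n_obs,
            })
        if fits and fits[0].dropped_levels:
            report.warnings.append(
                f"{outcome}: dropped separating levels {fits[0].dropped_levels}")
    pd.DataFrame(corr_rows).to_csv(outdir / "correlates.csv", index=False)
    report.add(outdir / "correlates.csv", len(corr_rows))

    cost_inputs = config.cost_inputs or econ_mod.example_cost_inputs()
    net = config.net_suppressed or econ_mod.example_net_suppressed()
    ci_path = outdir / "cost_inputs.csv"
    write_table(cost_inputs_to_frame(cost_inputs), ci_path)
    report.add(ci_path, len(cost_inputs))
    econ_results = [
        econ_mod.analyze_clinic(ci, net[ci.clinic_id], config.constants)
        for ci in cost_inputs
    ]
    econ_json = {r.clinic_id: {
        k: (str(v) if isinstance(v, Decimal) else v)
        for k, v in dataclasses.asdict(r).items() if k != "clinic_id"
    } for r in econ_results}
    (outdir / "econ_report.json").write_text(json.dumps(econ_json, indent=2))
    report.add(outdir / "econ_report.json", len(econ_results))

    (outdir / "run_report.json").write_text(json.dumps(
        {"manifest": report.manifest, "warnings": report.warnings}, indent=2))
    return report
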