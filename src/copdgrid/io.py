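"""Cohort file I/O and panel-level risk reports.

Cohorts travel as delimited text with a fixed, documented header; write
followed by read is the identity on the documented fields and unknown
columns round-trip through each record's ``extras``.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import pandas as pd

from .fhir import AlertConfig, detected_issue_rules
from .grid import enumerate_grid
from .model import DEFAULT_COEFFICIENTS, ModelCoefficients
from .phenotype import (
    GRID126,
    DomainBounds,
    ExacerbationHistory,
    Regimen,
    assign_expanded_phenotype,
    cap_inputs,
    classify_control,
    flag_pseudomonas_risk,
)
from .cohort import PatientRecord

__all__ = ["COHORT_COLUMNS", "SchemaError", "read_cohort", "write_cohort",
           "run_population_report"]

#: Documented cohort schema, one row per patient.
COHORT_COLUMNS = [
    "id", "age", "sex", "site", "a_raw", "b_raw",
    "moderate_exacerbations", "severe_exacerbations",
    "consultations", "inhalations_per_day",
    "eosinophils_current", "eosinophils_prior_max", "regimen",
]

_MANDATORY = ("id", "a_raw", "b_raw")


class SchemaError(ValueError):
    """A mandatory cohort column is absent."""


def _opt_int(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return int(v)


def _opt_float(v) -> Optional[float]:
    if v is None or v == "":
        return None
    v = float(v)
    return None if math.isnan(v) else v


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write patient records as comma-delimited text with the fixed header."""
    rows = []
    extra_cols: list[str] = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "site": r.site,
            "a_raw": r.a_raw,
            "b_raw": r.b_raw,
            "moderate_exacerbations":
                r.history.moderate_count if r.history else None,
            "severe_exacerbations":
                r.history.severe_count if r.history else None,
            "consultations": r.consultations,
            "inhalations_per_day": r.inhalations_per_day,
            "eosinophils_current": r.eosinophils_current,
            "eosinophils_prior_max": r.eosinophils_prior_max,
            "regimen": r.regimen.value if r.regimen else None,
        }
        for k, v in r.extras.items():
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS + extra_cols)
    df.to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read a delimited cohort file into patient records.

    Missing optional values stay missing; columns outside the documented
    schema are preserved in each record's ``extras``.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(col)
    extra_cols = [c for c in df.columns if c not in COHORT_COLUMNS]
    records = []
    for _, row in df.iterrows():
        mod = _opt_int(row.get("moderate_exacerbations"))
        sev = _opt_int(row.get("severe_exacerbations"))
        history = None
        if mod is not None or sev is not None:
            history = ExacerbationHistory(mod or 0, sev or 0)
        regimen = row.get("regimen")
        if isinstance(regimen, float) and math.isnan(regimen):
            regimen = None
        records.append(
            PatientRecord(
                id=str(row["id"]),
                a_raw=int(row["a_raw"]),
                b_raw=int(row["b_raw"]),
                history=history,
                age=_opt_float(row.get("age")),
                sex=None if pd.isna(row.get("sex")) else str(row.get("sex")),
                site=None if pd.isna(row.get("site")) else str(row.get("site")),
                consultations=_opt_int(row.get("consultations")),
                inhalations_per_day=_opt_int(row.get("inhalations_per_day")),
                eosinophils_current=_opt_float(row.get("eosinophils_current")),
                eosinophils_prior_max=_opt_float(row.get("eosinophils_prior_max")),
                regimen=Regimen(regimen) if regimen else None,
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def run_population_report(
    cohort: Sequence[PatientRecord],
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
    bounds: DomainBounds = GRID126,
    config: AlertConfig = AlertConfig(),
) -> pd.DataFrame:
    """Risk-stratified panel report, one row per patient.

    Columns: capped (a, b), predicted probability, basic and expanded
    phenotype, poor-control status, Pseudomonas flag and alert status.
    Rows are sorted by descending probability, ties by (b, a) descending
    then by id; an empty cohort yields an empty report.
    """
    grid = enumerate_grid(coeffs, bounds)
    rows = []
    for r in cohort:
        a, b, capped = cap_inputs(r.a_raw, r.b_raw, bounds)
        cell = grid.cell(a, b)
        phen = assign_expanded_phenotype(a, b=b, history=r.history)
        control = classify_control(r)
        from .phenotype import assign_basic_phenotype

        basic = assign_basic_phenotype(history=r.history, b=b)
        rules = detected_issue_rules(r.a_raw, r.b_raw, cell.pr, [], config)
        rows.append(
            {
                "id": r.id,
                "a": a,
                "b": b,
                "capped": capped,
                "pr": cell.pr,
                "basic_phenotype": basic.value,
                "expanded_phenotype": phen.label,
                "poorly_controlled": control.poorly_controlled,
                "pseudomonas_flag": flag_pseudomonas_risk(r.b_raw, cell.pr),
                "alert": bool(rules),
                "alert_rules": ";".join(rules),
            }
        )
    df = pd.DataFrame(rows, columns=[
        "id", "a", "b", "capped", "pr", "basic_phenotype",
        "expanded_phenotype", "poorly_controlled", "pseudomonas_flag",
        "alert", "alert_rules",
    ])
    if df.empty:
        return df
    df = df.sort_values(
        by=["pr", "b", "a", "id"], ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df
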