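"""Cohort, score and assessment CSV readers/writers.

The cohort schema is one row per patient with explicit unit columns for the
analytes whose formulas mix unit systems. Booleans are serialized as
``true``/``false``; missing values are empty fields. Schema violations are
reported with row and column coordinates.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .quality import AssessmentSheet, ITEM_KEYS
from .scores import SCORE_NAMES, ScoreConfig, ScorePanel, score_panel
from .units import LabPanel, PatientRecord

__all__ = [
    "COHORT_COLUMNS",
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "score_table",
    "read_assessments",
]

COHORT_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "weight_kg",
    "height_m",
    "dialysis_per_week",
    "growth_failure",
    "hu_status",
    "standard_exception",
    "indication",
    "retransplant",
    "days_on_list",
    "outcome",
    "died_90d",
    "creatinine",
    "creatinine_unit",
    "bilirubin",
    "bilirubin_unit",
    "inr",
    "sodium_mmol_l",
    "albumin",
    "albumin_unit",
    "ptt_s",
)


class SchemaError(ValueError):
    """A cohort file violates the expected schema."""


def _parse_bool(text: str, row: int, column: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise SchemaError(f"row {row}, column {column!r}: invalid boolean {text!r}")


def _parse_float(text: str, row: int, column: str) -> float | None:
    if text.strip() == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"row {row}, column {column!r}: invalid number {text!r}") from None


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV into patient records, enforcing the schema."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file (no header)")
        missing = [c for c in COHORT_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
        records: list[PatientRecord] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            pid = row["patient_id"].strip()
            if not pid:
                raise SchemaError(f"row {i}, column 'patient_id': empty")
            if pid in seen:
                raise SchemaError(f"row {i}: duplicate patient_id {pid!r}")
            seen.add(pid)
            labs = LabPanel(
                creatinine=_parse_float(row["creatinine"], i, "creatinine"),
                creatinine_unit=row["creatinine_unit"].strip() or "umol/l",
                bilirubin=_parse_float(row["bilirubin"], i, "bilirubin"),
                bilirubin_unit=row["bilirubin_unit"].strip() or "umol/l",
                inr=_parse_float(row["inr"], i, "inr"),
                sodium=_parse_float(row["sodium_mmol_l"], i, "sodium_mmol_l"),
                albumin=_parse_float(row["albumin"], i, "albumin"),
                albumin_unit=row["albumin_unit"].strip() or "g/l",
                ptt=_parse_float(row["ptt_s"], i, "ptt_s"),
            )
            try:
                records.append(
                    PatientRecord(
                        patient_id=pid,
                        age_at_listing=_parse_float(row["age_years"], i, "age_years"),
                        sex=row["sex"].strip(),
                        weight=_parse_float(row["weight_kg"], i, "weight_kg"),
                        height=_parse_float(row["height_m"], i, "height_m"),
                        labs=labs,
                        dialysis_sessions_per_week=int(row["dialysis_per_week"] or 0),
                        growth_failure=_parse_bool(row["growth_failure"], i, "growth_failure"),
                        hu_status=_parse_bool(row["hu_status"], i, "hu_status"),
                        standard_exception=_parse_bool(
                            row["standard_exception"], i, "standard_exception"
                        ),
                        indication=row["indication"].strip(),
                        retransplant=_parse_bool(row["retransplant"], i, "retransplant"),
                        days_on_list=int(row["days_on_list"] or 0),
                        outcome=row["outcome"].strip(),
                        died_within_90d=_parse_bool(row["died_90d"], i, "died_90d"),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"row {i}: {exc}") from None
    if not records:
        raise SchemaError(f"{path}: empty cohort (no data rows)")
    return records


import numpy as _np


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (bool, _np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, _np.floating)):
        return repr(float(value))
    return str(value)


def cohort_rows(records: Sequence[PatientRecord]) -> Iterable[dict]:
    for p in records:
        labs = p.labs
        yield {
            "patient_id": p.patient_id,
            "age_years": p.age_at_listing,
            "sex": p.sex,
            "weight_kg": p.weight,
            "height_m": p.height,
            "dialysis_per_week": p.dialysis_sessions_per_week,
            "growth_failure": p.growth_failure,
            "hu_status": p.hu_status,
            "standard_exception": p.standard_exception,
            "indication": p.indication,
            "retransplant": p.retransplant,
            "days_on_list": p.days_on_list,
            "outcome": p.outcome,
            "died_90d": p.died_within_90d,
            "creatinine": labs.creatinine,
            "creatinine_unit": labs.creatinine_unit,
            "bilirubin": labs.bilirubin,
            "bilirubin_unit": labs.bilirubin_unit,
            "inr": labs.inr,
            "sodium_mmol_l": labs.sodium,
            "albumin": labs.albumin,
            "albumin_unit": labs.albumin_unit,
            "ptt_s": labs.ptt,
        }


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort CSV (UTF-8, header, deterministic float formatting)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COHORT_COLUMNS)
        writer.writeheader()
        for row in cohort_rows(records):
            writer.writerow({k: _fmt(v) for k, v in row.items()})


def score_table(
    records: Sequence[PatientRecord],
    config: ScoreConfig | None = None,
    panels: Sequence[ScorePanel] | None = None,
) -> pd.DataFrame:
    """Cohort table with the nine score columns and an audit-trail column appended."""
    if panels is None:
        panels = [score_panel(p, config) for p in records]
    base = pd.DataFrame(cohort_rows(records))
    for name in SCORE_NAMES:
        base[name] = [getattr(panel, name) for panel in panels]
    base["applied_rules"] = ["; ".join(panel.applied_rules) for panel in panels]
    return base


def read_assessments(path: str | Path) -> dict[str, list[AssessmentSheet]]:
    """Read evaluator sheets from a long CSV: model,evaluator,item_key,mark."""
    table = pd.read_csv(path)
    required = {"model", "evaluator", "item_key", "mark"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(sorted(missing))}")
    sheets: dict[str, list[AssessmentSheet]] = {}
    for (model, evaluator), grp in table.groupby(["model", "evaluator"], sort=True):
        marks = dict(zip(grp["item_key"], grp["mark"].astype(int)))
        sheets.setdefault(str(model), []).append(
            AssessmentSheet(str(model), str(evaluator), marks)
        )
    return sheets
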