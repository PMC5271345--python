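"""End-to-end analysis pipeline on a loaded or simulated cohort.

Reproduces the full validation flow: score every patient, run the ROC
sub-cohort matrix, fit the two forward-LR regression model sets (clinical
covariates in set 1; non-component clinical covariates plus the nine scores
in set 2), and optionally aggregate evaluator quality sheets. All artifacts
are plain CSV/JSON and deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort
from .io import read_assessments, read_cohort, score_table
from .quality import cohort_quality_report, radar_export, summarize_model
from .regression import (
    RegressionResult,
    forward_lr_select,
    resolve_collinearity,
    univariable_screen,
    vif_report,
)
from .roc import auroc_matrix, default_subgroups, roc_results_frame
from .scores import SCORE_NAMES, ScoreConfig, score_panel
from .units import INDICATIONS, PatientRecord

__all__ = [
    "PipelineConfig",
    "build_covariate_table",
    "run_model_set",
    "run_pipeline",
    "COLLINEARITY_GROUPS",
    "SCORE_COMPONENT_COVARIATES",
]

#: declared collinear variable groups (anthropometry; age vs pediatric flags)
COLLINEARITY_GROUPS: tuple[tuple[str, ...], ...] = (
    ("weight_kg", "height_m", "bmi"),
    ("age_years", "pediatric_lt16", "pediatric_lt12"),
)

#: raw labs that are components of the nine scores; never co-entered with them
SCORE_COMPONENT_COVARIATES: tuple[str, ...] = (
    "creatinine_umol_l",
    "bilirubin_umol_l",
    "inr",
    "sodium_mmol_l",
    "albumin_g_l",
)

CLINICAL_CANDIDATES: tuple[str, ...] = (
    "age_years",
    "male",
    "creatinine_umol_l",
    "bilirubin_umol_l",
    "inr",
    "sodium_mmol_l",
    "ptt_s",
    "albumin_g_l",
    "dialysis_per_week",
    "weight_kg",
    "height_m",
    "bmi",
    "growth_failure",
    "pediatric_lt16",
    "pediatric_lt12",
    "hu_status",
    "standard_exception",
    "days_on_list",
) + tuple(f"ind_{c}" for c in INDICATIONS)


def build_covariate_table(records: Sequence[PatientRecord], panels=None) -> pd.DataFrame:
    """Patient-level covariate table: demographics, flags, labs, indication
    dummies, and (when panels are given) the nine scores."""
    rows = []
    for p in records:
        labs = p.labs
        row = {
            "age_years": p.age_at_listing,
            "male": float(p.sex == "male"),
            "creatinine_umol_l": labs.creatinine_umol_l(),
            "bilirubin_umol_l": labs.bilirubin_umol_l(),
            "inr": labs.inr,
            "sodium_mmol_l": labs.sodium,
            "ptt_s": labs.ptt,
            "albumin_g_l": labs.albumin_g_l(),
            "dialysis_per_week": float(p.dialysis_sessions_per_week),
            "weight_kg": p.weight,
            "height_m": p.height,
            "bmi": p.bmi,
            "growth_failure": float(p.growth_failure),
            "pediatric_lt16": float(p.age_at_listing < 16),
            "pediatric_lt12": float(p.age_at_listing < 12),
            "hu_status": float(p.hu_status),
            "standard_exception": float(p.standard_exception),
            "days_on_list": float(p.days_on_list),
            "died_90d": float(p.died_within_90d),
        }
        for cat in INDICATIONS:
            row[f"ind_{cat}"] = float(p.indication == cat)
        rows.append(row)
    table = pd.DataFrame(rows)
    if panels is not None:
        for name in SCORE_NAMES:
            table[name] = [
                np.nan if getattr(panel, name) is None else float(getattr(panel, name))
                for panel in panels
            ]
    return table


def run_model_set(
    table: pd.DataFrame,
    candidates: Sequence[str],
    model_id: str,
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
    collinearity_groups: Sequence[Sequence[str]] = COLLINEARITY_GROUPS,
) -> dict:
    """Screen → collinearity resolution → forward-LR selection (complete-case)."""
    cols = [c for c in candidates if c in table.columns]
    data = table[cols + ["died_90d"]].dropna()
    y = data["died_90d"].to_numpy(bool)
    design = data[cols]
    screen = univariable_screen(design, y, cols, alpha=entry_alpha)
    significant = [s.name for s in screen if s.significant]
    pvals = {s.name: s.p_value for s in screen if s.p_value is not None}
    retained = resolve_collinearity(significant, collinearity_groups, pvals)
    fit = forward_lr_select(
        design, y, retained, entry_alpha=entry_alpha, removal_alpha=removal_alpha,
        model_id=model_id,
    )
    estimable = [c for c in cols if np.ptp(design[c].to_numpy(float)) > 0]
    return {
        "model_id": model_id,
        "n": int(len(data)),
        "screen": screen,
        "candidates_after_collinearity": retained,
        "fit": fit,
        "vif": vif_report(design[estimable]).to_dict("records"),
    }


@dataclass
class PipelineConfig:
    """Everything one run needs: cohort source, options, output directory, seed."""

    cohort_path: str | None = None  # load this CSV; None = simulate
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    score_config: ScoreConfig = field(default_factory=ScoreConfig)
    ci_method: str = "delong"
    pediatric_cutoff: float = 16.0
    roc_threshold: float = 0.700
    entry_alpha: float = 0.05
    removal_alpha: float = 0.10
    qa_path: str | None = None
    output_dir: str = "meldkit_output"
    seed: int = 42


def _regression_json(result: dict) -> dict:
    fit: RegressionResult = result["fit"]
    return {
        "model_id": result["model_id"],
        "n": result["n"],
        "screen": [dataclasses.asdict(s) for s in result["screen"]],
        "candidates_after_collinearity": result["candidates_after_collinearity"],
        "terms": [dataclasses.asdict(t) for t in fit.terms],
        "log_likelihood": fit.log_likelihood,
        "selection_trace": [dataclasses.asdict(s) for s in fit.selection_trace],
        "vif": result["vif"],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate/load → score → ROC matrix → regressions → optional QA.

    Artifacts (scores.csv, roc.csv, regression.json, qa_report.json,
    run_log.json) are written to a temporary directory first and moved into
    ``config.output_dir`` only on success, so a failed run leaves no partial
    outputs behind.
    """
    if config.cohort_path is not None:
        records = read_cohort(config.cohort_path)
        source = {"type": "file", "path": str(config.cohort_path)}
    else:
        spec = dataclasses.replace(config.cohort_spec, seed=config.seed)
        records = generate_cohort(spec)
        source = {"type": "simulated", "n": spec.n, "seed": spec.seed}

    panels = [score_panel(p, config.score_config) for p in records]
    scores_frame = score_table(records, config.score_config, panels=panels)

    results = auroc_matrix(
        records,
        panels,
        subgroups=default_subgroups(config.pediatric_cutoff),
        ci_method=config.ci_method,
        threshold=config.roc_threshold,
        seed=config.seed,
    )
    roc_frame = roc_results_frame(results)

    table = build_covariate_table(records, panels)
    set1 = run_model_set(
        table, CLINICAL_CANDIDATES, "model_set_1", config.entry_alpha, config.removal_alpha
    )
    set2_clinical = [c for c in CLINICAL_CANDIDATES if c not in SCORE_COMPONENT_COVARIATES]
    set2 = run_model_set(
        table,
        tuple(set2_clinical) + SCORE_NAMES,
        "model_set_2",
        config.entry_alpha,
        config.removal_alpha,
    )

    qa_report = None
    if config.qa_path is not None:
        sheets = read_assessments(config.qa_path)
        summaries = [summarize_model(s) for s in sheets.values()]
        qa_report = cohort_quality_report(summaries)
        qa_report["radar"] = {
            s.model_name: radar_export(s) for s in summaries
        }

    rule_counts = Counter(
        r.split(":", 1)[0] for panel in panels for r in panel.applied_rules
    )
    run_log = {
        "meldkit_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "cohort_source": source,
        "n_patients": len(records),
        "n_events_90d": int(sum(p.died_within_90d for p in records)),
        "applied_rule_counts_by_score": dict(sorted(rule_counts.items())),
    }

    out_dir = Path(config.output_dir)
    tmp = Path(tempfile.mkdtemp(prefix="meldkit-run-"))
    try:
        scores_frame.to_csv(tmp / "scores.csv", index=False)
        roc_frame.to_csv(tmp / "roc.csv", index=False)
        with (tmp / "regression.json").open("w") as fh:
            json.dump([_regression_json(set1), _regression_json(set2)], fh, indent=2)
        if qa_report is not None:
            with (tmp / "qa_report.json").open("w") as fh:
                json.dump(qa_report, fh, indent=2)
        with (tmp / "run_log.json").open("w") as fh:
            json.dump(run_log, fh, indent=2)
        out_dir.mkdir(parents=True, exist_ok=True)
        for item in tmp.iterdir():
            shutil.move(str(item), out_dir / item.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)

    return {
        "records": records,
        "panels": panels,
        "scores": scores_frame,
        "roc": roc_frame,
        "model_set_1": set1,
        "model_set_2": set2,
        "qa_report": qa_report,
        "run_log": run_log,
    }
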