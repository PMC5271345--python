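"""Prognostic-model quality appraisal (Jacob-style 20-point instrument).

Eighteen subheadings in five categories — internal validity (4), external
validity (2), statistical validity (4), evaluation of the model (4),
practicality (4) — are each marked 0 or 1 by every evaluator. Per-item means
across evaluators are computed first; the two external-validity items are
then doubled so that every category has a weighted maximum of 4 and the
total runs from 0 to 20. A radar (spider-web) export normalizes each
category subtotal by that maximum.

A fixture with the published per-item means for the nine scores ships with
the package (``data/published_qa_means.csv``); its ``printed_total`` row
preserves the totals exactly as published, which for some models differ
from the sum of their own printed cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "ITEM_KEYS",
    "EXTERNAL_ITEMS",
    "AssessmentSheet",
    "QualitySummary",
    "summarize_model",
    "summary_from_item_means",
    "cohort_quality_report",
    "radar_export",
    "load_published_means",
]

CATEGORIES: dict[str, tuple[str, ...]] = {
    "internal_validity": (
        "inception_cohort_established",
        "inception_cohort_followed_up",
        "baseline_data_prospective",
        "candidate_factors_defined",
    ),
    "external_validity": (
        "multicentre_population",
        "adequate_description",
    ),
    "statistical_validity": (
        "continuous_variables",
        "sample_size_adequate",
        "collinearity_assessed",
        "missing_values",
    ),
    "evaluation_of_model": (
        "model_assumptions_tested",
        "sensitivity_influential_observations",
        "internal_validation",
        "external_validation",
    ),
    "practicality": (
        "factors_available_in_practice",
        "model_described_sufficiently",
        "prediction_precision",
        "wide_generalisability",
    ),
}

ITEM_KEYS: tuple[str, ...] = tuple(k for items in CATEGORIES.values() for k in items)
EXTERNAL_ITEMS: tuple[str, ...] = CATEGORIES["external_validity"]
EXTERNAL_WEIGHT = 2.0
MAX_TOTAL = 20.0
CATEGORY_MAX = 4.0


@dataclass(frozen=True)
class AssessmentSheet:
    """One evaluator's 18 binary marks for one prognostic model."""

    model_name: str
    evaluator_id: str
    marks: Mapping[str, int]

    def __post_init__(self) -> None:
        keys = set(self.marks)
        if keys != set(ITEM_KEYS):
            missing = set(ITEM_KEYS) - keys
            extra = keys - set(ITEM_KEYS)
            raise ValueError(f"marks must cover the 18 items; missing={missing}, extra={extra}")
        for k, v in self.marks.items():
            if v not in (0, 1):
                raise ValueError(f"mark for {k!r} must be 0 or 1, got {v!r}")


@dataclass
class QualitySummary:
    """Evaluator-averaged, externally-weighted quality profile of one model."""

    model_name: str
    per_item_means: dict[str, float]
    weighted_item_scores: dict[str, float]
    category_subtotals: dict[str, float]
    total: float
    n_evaluators: int


def _summarize(model_name: str, means: Mapping[str, float], n_evaluators: int) -> QualitySummary:
    weighted = {
        k: means[k] * (EXTERNAL_WEIGHT if k in EXTERNAL_ITEMS else 1.0) for k in ITEM_KEYS
    }
    subtotals = {cat: sum(weighted[k] for k in items) for cat, items in CATEGORIES.items()}
    return QualitySummary(
        model_name=model_name,
        per_item_means=dict(means),
        weighted_item_scores=weighted,
        category_subtotals=subtotals,
        total=sum(weighted.values()),
        n_evaluators=n_evaluators,
    )


def summarize_model(sheets: Sequence[AssessmentSheet]) -> QualitySummary:
    """Average binary sheets across evaluators, double external items, total out of 20."""
    if not sheets:
        raise ValueError("need at least one assessment sheet")
    names = {s.model_name for s in sheets}
    if len(names) > 1:
        raise ValueError(f"sheets mix model names: {sorted(names)}")
    n = len(sheets)
    means = {k: sum(s.marks[k] for s in sheets) / n for k in ITEM_KEYS}
    return _summarize(sheets[0].model_name, means, n)


def summary_from_item_means(
    model_name: str,
    means: Mapping[str, float],
    n_evaluators: int = 3,
    external_prescaled: bool = False,
) -> QualitySummary:
    """Build a summary directly from per-item means (e.g. published tables).

    ``external_prescaled`` marks inputs where the two external-validity items
    are already doubled (the convention of the published table); they are
    halved back to raw means before the standard weighting is applied.
    """
    raw = dict(means)
    if set(raw) != set(ITEM_KEYS):
        raise ValueError("means must cover exactly the 18 items")
    if external_prescaled:
        for k in EXTERNAL_ITEMS:
            raw[k] = raw[k] / EXTERNAL_WEIGHT
    for k, v in raw.items():
        if not 0.0 <= v <= 1.0 + 1e-9:
            raise ValueError(f"per-item mean for {k!r} outside [0, 1]: {v}")
    return _summarize(model_name, raw, n_evaluators)


def cohort_quality_report(summaries: Sequence[QualitySummary]) -> dict:
    """Cross-model aggregate: mean total, % of 20, category means, ranking."""
    if not summaries:
        raise ValueError("need at least one summary")
    totals = {s.model_name: s.total for s in summaries}
    mean_total = sum(totals.values()) / len(totals)
    per_category_weighted = {
        cat: sum(s.category_subtotals[cat] for s in summaries) / len(summaries)
        for cat in CATEGORIES
    }
    # per-item means averaged over models, per category (unweighted 0-1 scale)
    per_category_item_mean = {
        cat: sum(s.per_item_means[k] for s in summaries for k in items)
        / (len(summaries) * len(items))
        for cat, items in CATEGORIES.items()
    }
    ranking = sorted(totals, key=lambda m: (-totals[m], m))
    worst = sorted(per_category_item_mean, key=per_category_item_mean.get)[:2]
    return {
        "n_models": len(summaries),
        "mean_total": mean_total,
        "percent_of_max": 100.0 * mean_total / MAX_TOTAL,
        "totals": totals,
        "category_weighted_means": per_category_weighted,
        "category_item_means": per_category_item_mean,
        "ranking": ranking,
        "lowest_categories": worst,
    }


def report_from_totals(totals: Mapping[str, float]) -> dict:
    """Mean/percentage/ranking from bare model totals (e.g. published values)."""
    if not totals:
        raise ValueError("need at least one total")
    mean_total = sum(totals.values()) / len(totals)
    return {
        "n_models": len(totals),
        "mean_total": mean_total,
        "percent_of_max": 100.0 * mean_total / MAX_TOTAL,
        "totals": dict(totals),
        "ranking": sorted(totals, key=lambda m: (-totals[m], m)),
    }


def radar_export(summary: QualitySummary) -> list[tuple[str, float]]:
    """Five (category, score in [0,1]) pairs for a spider-web plot, fixed order."""
    return [
        (cat, summary.category_subtotals[cat] / CATEGORY_MAX) for cat in CATEGORIES
    ]


def load_published_means() -> tuple[pd.DataFrame, dict[str, float]]:
    """The published per-item quality means for the nine scores.

    Returns ``(means, printed_totals)``: a DataFrame indexed by item key with
    one column per model (external items carry their published doubled
    values), and the totals exactly as published. Some published totals do
    not equal the sum of their own published cells; both are available so
    either can be checked.
    """
    with resources.files("meldkit.data").joinpath("published_qa_means.csv").open() as fh:
        table = pd.read_csv(fh)
    totals_row = table[table["item"] == "printed_total"]
    items = table[table["item"] != "printed_total"].set_index("item")
    items = items.drop(columns=["category"])
    order = [k for k in ITEM_KEYS if k in items.index]
    if set(order) != set(ITEM_KEYS):
        raise ValueError("fixture does not cover the 18 items")
    printed_totals = {
        col: float(totals_row[col].iloc[0]) for col in items.columns
    }
    return items.loc[list(ITEM_KEYS)].astype(float), printed_totals


def published_summaries(external_prescaled: bool = True) -> list[QualitySummary]:
    """Summaries built from the published per-item means, one per model."""
    means, _ = load_published_means()
    return [
        summary_from_item_means(col, means[col].to_dict(), external_prescaled=external_prescaled)
        for col in means.columns
    ]
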