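"""ROC discrimination analysis for prognostic scores.

The AUROC here is the Mann–Whitney two-sample statistic with midrank tie
handling: the probability that a randomly chosen patient who died within 90
days outranks (has a higher score than) a randomly chosen survivor, counting
ties as 1/2. Confidence intervals use the DeLong structural-components
variance by default, with a seeded stratified bootstrap as an alternative.
AUROCs above 0.700 are flagged "acceptable" (strictly greater: a model at
0.699 just fails the threshold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .scores import SCORE_NAMES, ScorePanel
from .units import PatientRecord

__all__ = [
    "RocResult",
    "auroc",
    "roc_curve",
    "auroc_ci",
    "auroc_matrix",
    "default_subgroups",
    "ACCEPTABILITY_THRESHOLD",
]

ACCEPTABILITY_THRESHOLD = 0.700


def _validate(scores, events):
    s = np.asarray(scores, dtype=float)
    e = np.asarray(events, dtype=bool)
    if s.shape != e.shape or s.ndim != 1:
        raise ValueError("scores and events must be 1-d and equal length")
    if np.isnan(s).any():
        raise ValueError("scores must not contain NaN")
    n1 = int(e.sum())
    if n1 == 0 or n1 == e.size:
        raise ValueError("need at least one event and one non-event")
    return s, e


def auroc(scores: Sequence[float], events: Sequence[bool]) -> float:
    """Area under the ROC curve via midranks (Mann–Whitney statistic).

    Orientation is fixed: higher score means higher mortality risk.
    """
    s, e = _validate(scores, events)
    ranks = rankdata(s)  # midranks
    n1 = int(e.sum())
    n0 = e.size - n1
    u = ranks[e].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(scores: Sequence[float], events: Sequence[bool]) -> list[tuple[float, float, float]]:
    """ROC curve points as (fpr, tpr, threshold) with thresholds descending.

    The first point is (0, 0) at threshold +inf and the last is (1, 1); one
    point per distinct score value. The trapezoidal area under the returned
    polyline equals :func:`auroc` (ties produce the diagonal segments that
    the midrank convention integrates).
    """
    s, e = _validate(scores, events)
    order = np.argsort(-s, kind="mergesort")
    s, e = s[order], e[order]
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tps = np.cumsum(e)[distinct]
    fps = np.cumsum(~e)[distinct]
    n1, n0 = tps[-1], fps[-1]
    curve = [(0.0, 0.0, math.inf)]
    curve.extend(
        (float(fp / n0), float(tp / n1), float(s[i])) for i, tp, fp in zip(distinct, tps, fps)
    )
    return curve


def _delong_variance(s: np.ndarray, e: np.ndarray) -> tuple[float, float]:
    """AUROC and its DeLong variance from structural components."""
    x, y = s[e], s[~e]  # events, non-events
    m, n = x.size, y.size
    # psi(x_i, y_j) = 1[x>y] + 0.5*1[x==y], computed via midranks
    all_ranks = rankdata(np.r_[x, y])
    rx = rankdata(x)
    ry = rankdata(y)
    v10 = (all_ranks[:m] - rx) / n  # per-event component
    v01 = 1.0 - (all_ranks[m:] - ry) / m  # per-non-event component
    theta = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(theta), float(s10 / m + s01 / n)


def auroc_ci(
    scores: Sequence[float],
    events: Sequence[bool],
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Confidence interval for the AUROC, truncated to [0, 1].

    ``delong`` (default) builds a normal interval on the structural-components
    variance; ``bootstrap`` is a percentile interval over ``n_boot`` seeded
    stratified resamples.
    """
    s, e = _validate(scores, events)
    if method == "delong":
        if e.sum() < 2 or (~e).sum() < 2:
            raise ValueError("delong interval needs >= 2 events and >= 2 non-events")
        theta, var = _delong_variance(s, e)
        if var <= 0.0:
            warnings.warn("degenerate DeLong variance 0; interval collapses to a point")
            return theta, theta
        z = norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(var)
        return max(0.0, theta - half), min(1.0, theta + half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        x, y = s[e], s[~e]
        stats = np.empty(n_boot)
        for b in range(n_boot):
            xb = rng.choice(x, x.size, replace=True)
            yb = rng.choice(y, y.size, replace=True)
            stats[b] = auroc(np.r_[xb, yb], np.r_[np.ones(x.size, bool), np.zeros(y.size, bool)])
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
        return float(max(0.0, lo)), float(min(1.0, hi))
    raise ValueError(f"unknown CI method {method!r}")


@dataclass
class RocResult:
    """AUROC of one score in one sub-cohort with CI and acceptability flag."""

    score_name: str
    subgroup: str
    n: int
    n_events: int
    auroc: float | None
    ci_low: float | None
    ci_high: float | None
    acceptable: bool
    estimable: bool = True
    curve: list[tuple[float, float, float]] = field(default_factory=list)


def default_subgroups(pediatric_cutoff: float = 16.0) -> dict[str, Callable[[PatientRecord], bool]]:
    """The standard sub-cohort filters: age, retransplant status, indications.

    Children are defined by ``age < pediatric_cutoff`` (16 years by default,
    matching the cohort's operational definition; 12 is the usual PELD
    allocation cut-off and is available by passing 12).
    """

    def indication_is(cat):
        return lambda p, c=cat: p.indication == c

    def indication_not(cat):
        return lambda p, c=cat: p.indication != c

    return {
        "all": lambda p: True,
        "children": lambda p: p.age_at_listing < pediatric_cutoff,
        "adults": lambda p: p.age_at_listing >= pediatric_cutoff,
        "no_previous_tx": lambda p: not p.retransplant,
        "retransplant": lambda p: p.retransplant,
        "no_cirrhosis": indication_not("cirrhosis"),
        "cirrhosis": indication_is("cirrhosis"),
        "no_cancer": indication_not("cancer"),
        "cancer": indication_is("cancer"),
        "no_metabolic": indication_not("metabolic"),
        "metabolic": indication_is("metabolic"),
        "no_acute_failure": indication_not("acute_hepatic_failure"),
        "acute_failure": indication_is("acute_hepatic_failure"),
        "no_cholestatic": indication_not("cholestatic"),
        "cholestatic": indication_is("cholestatic"),
    }


def auroc_matrix(
    cohort: Sequence[PatientRecord],
    panels: Sequence[ScorePanel],
    subgroups: Mapping[str, Callable[[PatientRecord], bool]] | None = None,
    score_names: Iterable[str] = SCORE_NAMES,
    ci_method: str = "delong",
    level: float = 0.95,
    threshold: float = ACCEPTABILITY_THRESHOLD,
    seed: int | None = None,
    keep_curves: bool = False,
) -> list[RocResult]:
    """AUROC of every score in every sub-cohort (complete-case per score).

    A (score, subgroup) cell with fewer than 2 events or 2 non-events among
    patients with that score available is returned flagged not-estimable
    rather than raising.
    """
    if len(cohort) != len(panels):
        raise ValueError("cohort and panels must be aligned")
    subgroups = subgroups if subgroups is not None else default_subgroups()
    results: list[RocResult] = []
    for sub_name, predicate in subgroups.items():
        mask = [predicate(p) for p in cohort]
        for score in score_names:
            vals, evts = [], []
            for keep, patient, panel in zip(mask, cohort, panels):
                if not keep:
                    continue
                v = getattr(panel, score)
                if v is None:
                    continue
                vals.append(float(v))
                evts.append(patient.died_within_90d)
            n = len(vals)
            n_events = sum(evts)
            if n_events < 2 or n - n_events < 2:
                results.append(
                    RocResult(score, sub_name, n, n_events, None, None, None, False, False)
                )
                continue
            a = auroc(vals, evts)
            lo, hi = auroc_ci(vals, evts, level=level, method=ci_method, seed=seed)
            results.append(
                RocResult(
                    score,
                    sub_name,
                    n,
                    n_events,
                    a,
                    lo,
                    hi,
                    a > threshold,
                    True,
                    roc_curve(vals, evts) if keep_curves else [],
                )
            )
    return results


def roc_results_frame(results: Sequence[RocResult]) -> pd.DataFrame:
    """Tabular view of :func:`auroc_matrix` output (one row per score × subgroup)."""
    return pd.DataFrame(
        {
            "score": r.score_name,
            "subgroup": r.subgroup,
            "n": r.n,
            "n_events": r.n_events,
            "auroc": r.auroc,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "acceptable": r.acceptable,
            "estimable": r.estimable,
        }
        for r in results
    )
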