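"""Binary logistic regression with forward likelihood-ratio selection.

The workflow mirrors a classic risk-factor analysis for 90-day waiting-list
mortality:

1. univariable screen of every candidate covariate (Wald p, odds ratio, CI);
2. collinearity resolution over declared variable groups (keep the member
   with the smallest univariable p), with the score-vs-component collinearity
   handled architecturally by running two separate model sets;
3. forward likelihood-ratio selection: at each step enter the candidate with
   the smallest LR-test p below the entry threshold (default 0.05), then
   remove any included term whose LR removal p exceeds the removal threshold
   (default 0.10, the conventional stepwise default).

The maximum-likelihood fit is Newton–Raphson / IRLS with step-halving,
converged when the score (gradient) sup-norm drops below 1e-8. Wald standard
errors come from the observed information; 95% CIs are exp(coef ± z·se).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

__all__ = [
    "PerfectSeparationError",
    "ConvergenceError",
    "TermResult",
    "SelectionStep",
    "RegressionResult",
    "ScreenResult",
    "fit_logistic",
    "univariable_screen",
    "resolve_collinearity",
    "forward_lr_select",
    "vif_report",
]

_Z95 = norm.ppf(0.975)


def _exp(v: float) -> float:
    """exp() that saturates to inf instead of overflowing (huge Wald CIs)."""
    return math.exp(v) if v < 700.0 else math.inf


class PerfectSeparationError(RuntimeError):
    """The likelihood is unbounded: a covariate separates events from non-events."""


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class TermResult:
    name: str
    coefficient: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    std_error: float


@dataclass(frozen=True)
class SelectionStep:
    step: int
    action: str  # "enter" | "remove"
    term: str
    lr_statistic: float
    p_value: float


@dataclass
class RegressionResult:
    model_id: str
    terms: list[TermResult]
    log_likelihood: float
    n: int
    converged: bool = True
    selection_trace: list[SelectionStep] = field(default_factory=list)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms if t.name != "intercept"]


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(design))] + [design[c].to_numpy(float) for c in design])
    return X, ["intercept"] + list(design.columns)


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # ll = sum y*eta - log(1+exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    design: pd.DataFrame,
    outcome: Sequence[bool],
    model_id: str = "logit",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RegressionResult:
    """Maximum-likelihood logistic fit of ``outcome`` on ``design`` columns.

    An intercept is always included. Raises :class:`PerfectSeparationError`
    when the fitted probabilities saturate (naming the covariate with the
    steepest standardized slope) and :class:`ConvergenceError` when the
    gradient tolerance is not reached within ``max_iter`` iterations.
    """
    y = np.asarray(outcome, dtype=float)
    if len(design) != y.size:
        raise ValueError("design and outcome lengths differ")
    if y.size <= design.shape[1] + 1:
        raise ValueError("need n greater than the number of terms")
    for col in design.columns:
        if np.ptp(design[col].to_numpy(float)) == 0.0:
            raise ValueError(f"constant covariate: {col}")
    X, names = _design_matrix(design)
    beta = np.zeros(X.shape[1])
    ll = _log_likelihood(y, X @ beta)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError(f"singular information matrix for model {model_id!r}")
        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _h in range(30):
            candidate = beta + factor * step
            ll_new = _log_likelihood(y, X @ candidate)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        ll = _log_likelihood(y, X @ beta)
        _check_separation(X, y, beta, names, design)
    if not converged:
        eta = X @ beta
        grad = X.T @ (y - expit(eta))
        _check_separation(X, y, beta, names, design, force=True)
        raise ConvergenceError(
            f"model {model_id!r}: gradient sup-norm {np.max(np.abs(grad)):.3g} "
            f"after {max_iter} iterations (ll={ll:.6g}, max|beta|={np.max(np.abs(beta)):.3g})"
        )
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    terms = []
    for name, b, s in zip(names, beta, se):
        z = b / s if s > 0 else math.inf
        p = 2.0 * norm.sf(abs(z))
        terms.append(
            TermResult(name, float(b), _exp(b), _exp(b - _Z95 * s), _exp(b + _Z95 * s), float(p), float(s))
        )
    return RegressionResult(model_id, terms, ll, int(y.size), True)


def _check_separation(X, y, beta, names, design, force: bool = False) -> None:
    eta = X @ beta
    mu = expit(eta)
    saturated = np.all(mu[y == 1] > 1 - 1e-9) and np.all(mu[y == 0] < 1e-9)
    if saturated or (force and np.max(np.abs(beta)) > 25.0):
        # name the covariate with the largest standardized slope
        scales = [np.std(design[c].to_numpy(float)) for c in design.columns]
        slopes = np.abs(beta[1:]) * np.asarray(scales)
        worst = design.columns[int(np.argmax(slopes))] if len(design.columns) else "intercept"
        raise PerfectSeparationError(f"perfect separation detected; offending covariate: {worst}")


@dataclass
class ScreenResult:
    name: str
    p_value: float | None
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    significant: bool
    estimable: bool
    note: str = ""


def univariable_screen(
    design: pd.DataFrame,
    outcome: Sequence[bool],
    candidates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[ScreenResult]:
    """One single-covariate logistic fit per candidate.

    Constant or separating candidates are flagged not-estimable instead of
    raising, so a whole screening table is always produced.
    """
    candidates = list(candidates) if candidates is not None else list(design.columns)
    out: list[ScreenResult] = []
    for name in candidates:
        if name not in design.columns:
            raise KeyError(f"candidate {name!r} not in design table")
        col = design[[name]]
        if np.ptp(col[name].to_numpy(float)) == 0.0:
            out.append(ScreenResult(name, None, None, None, None, False, False, "constant"))
            continue
        try:
            fit = fit_logistic(col, outcome, model_id=f"uni:{name}")
        except PerfectSeparationError:
            out.append(
                ScreenResult(name, None, None, None, None, False, False, "perfect separation")
            )
            continue
        except ConvergenceError:
            out.append(ScreenResult(name, None, None, None, None, False, False, "no convergence"))
            continue
        t = fit.term(name)
        out.append(
            ScreenResult(
                name, t.p_value, t.odds_ratio, t.ci_low, t.ci_high, t.p_value < alpha, True
            )
        )
    return out


def resolve_collinearity(
    significant: Sequence[str],
    groups: Sequence[Sequence[str]],
    univariable_p: Mapping[str, float],
    keep: Mapping[int, str] | None = None,
) -> list[str]:
    """Drop all but one member of each declared collinear group.

    The retained member is the one with the smallest univariable p (ties
    broken by declaration order); ``keep`` may force a named member per group
    index (judgment override). Input order of the surviving covariates is
    preserved.
    """
    keep = keep or {}
    drop: set[str] = set()
    for gi, group in enumerate(groups):
        members = [g for g in group if g in significant]
        if len(members) < 2 and gi not in keep:
            continue
        if gi in keep:
            chosen = keep[gi]
            if chosen not in group:
                raise ValueError(f"keep override {chosen!r} not a member of group {gi}")
        else:
            chosen = min(members, key=lambda m: (univariable_p.get(m, math.inf), group.index(m)))
        drop.update(m for m in group if m != chosen)
    return [name for name in significant if name not in drop]


def _lr_test(ll_full: float, ll_reduced: float, df: int = 1) -> tuple[float, float]:
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return stat, float(chi2.sf(stat, df))


def forward_lr_select(
    design: pd.DataFrame,
    outcome: Sequence[bool],
    candidates: Sequence[str],
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
    model_id: str = "forward_lr",
) -> RegressionResult:
    """Forward stepwise selection by likelihood-ratio tests.

    Starts from the intercept-only model; each step enters the candidate
    with the smallest LR p below ``entry_alpha``, then re-checks every
    included term for removal at ``removal_alpha``. The full enter/remove
    trace is recorded on the returned result.
    """
    y = np.asarray(outcome, dtype=float)
    included: list[str] = []
    trace: list[SelectionStep] = []
    p1 = y.mean()
    ll_current = float(y.size * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))) if 0 < p1 < 1 else 0.0
    step_no = 0
    remaining = list(candidates)
    while True:
        best: tuple[float, float, str, float] | None = None  # (p, stat, name, ll)
        for name in remaining:
            try:
                fit = fit_logistic(design[included + [name]], outcome, model_id="trial")
            except (PerfectSeparationError, ConvergenceError, ValueError):
                continue
            stat, p = _lr_test(fit.log_likelihood, ll_current)
            if p < entry_alpha and (best is None or p < best[0]):
                best = (p, stat, name, fit.log_likelihood)
        if best is None:
            break
        step_no += 1
        p, stat, name, ll_current = best
        included.append(name)
        remaining.remove(name)
        trace.append(SelectionStep(step_no, "enter", name, stat, p))
        # backward removal sweep
        changed = True
        while changed and len(included) > 1:
            changed = False
            for name in list(included):
                reduced = [t for t in included if t != name]
                fit_red = fit_logistic(design[reduced], outcome, model_id="trial")
                stat, p_rm = _lr_test(ll_current, fit_red.log_likelihood)
                if p_rm > removal_alpha:
                    step_no += 1
                    included.remove(name)
                    remaining.append(name)
                    ll_current = fit_red.log_likelihood
                    trace.append(SelectionStep(step_no, "remove", name, stat, p_rm))
                    changed = True
                    break
    if included:
        final = fit_logistic(design[included], outcome, model_id=model_id)
    else:
        final = _intercept_only(y, model_id)
    final.selection_trace = trace
    return final


def _intercept_only(y: np.ndarray, model_id: str) -> RegressionResult:
    p1 = float(y.mean())
    if not 0 < p1 < 1:
        raise ValueError("degenerate outcome: all events or all non-events")
    b0 = math.log(p1 / (1 - p1))
    se = math.sqrt(1.0 / (y.size * p1 * (1 - p1)))
    ll = y.size * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))
    z = b0 / se
    term = TermResult(
        "intercept", b0, _exp(b0), _exp(b0 - _Z95 * se), _exp(b0 + _Z95 * se),
        2.0 * norm.sf(abs(z)), se,
    )
    return RegressionResult(model_id, [term], float(ll), int(y.size), True)


def vif_report(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors (transparency only; selection is judgment-based)."""
    X = design.to_numpy(float)
    out = []
    for j, name in enumerate(design.columns):
        others = np.column_stack([np.ones(len(design)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out.append({"covariate": name, "vif": math.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)})
    return pd.DataFrame(out)
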