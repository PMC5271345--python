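"""The nine end-stage liver disease prognostic scores.

MELD, MESO index, MELD-Na, UKELD, iMELD, refitMELD, refitMELD-Na, upMELD and
PELD, each with its published floors, caps, dialysis substitutions and
rounding rules applied exactly as printed in the source formulas:

* MELD: 10·(0.957 ln cr + 0.378 ln bili + 1.120 ln INR + 0.643), labs floored
  at 1.0, creatinine capped at 4.0 mg/dl (forced to 4.0 on dialysis), rounded
  to the nearest integer, capped at 40. The analytic floor after rounding is 6.
* MESO: MELD / serum sodium × 10 (integer MELD by default; no sodium clamp).
* MELD-Na: MELD − Na − 0.025·MELD·(140 − Na) + 140 with sodium clamped to
  125–140 mmol/l, rounded to the nearest integer.
* UKELD: SI-unit score with creatinine clamped to 1–400 μmol/l and sodium to
  112–150 mmol/l.
* iMELD: MELD + 0.3·age − 0.7·Na + 100 (no sodium clamp).
* refitMELD / refitMELD-Na: re-estimated coefficients; creatinine clamped to
  0.8–3.0 mg/dl (3.0 on dialysis), INR to 1.0–3.0; refitMELD-Na adds a
  sodium term (clamped 125–140) and an untransformed bilirubin interaction
  capped at 20 mg/dl (BiliCC).
* upMELD: ln(1+x) re-estimation; creatinine capped at 4.0 mg/dl with or
  without renal replacement therapy (dialysis does NOT substitute here).
* PELD: pediatric score on albumin, bilirubin, INR plus age-under-1-year and
  growth-failure indicators; growth failure is forced to 0 above 219 months.

Each calculator optionally records the handling rules that actually changed
an input into a caller-supplied audit list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import LabPanel, MissingLabError, PatientRecord, clamp

__all__ = [
    "ScoreConfig",
    "ScorePanel",
    "SCORE_NAMES",
    "meld",
    "meso",
    "meld_na",
    "ukeld",
    "imeld",
    "refit_meld",
    "refit_meld_na",
    "up_meld",
    "peld",
    "score_panel",
]

SCORE_NAMES = (
    "meld",
    "meso",
    "meld_na",
    "ukeld",
    "imeld",
    "refit_meld",
    "refit_meld_na",
    "up_meld",
    "peld",
)

#: growth-failure indicator forced to 0 above this age (months)
PELD_GROWTH_FAILURE_MAX_MONTHS = 219


def _round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero on the positive axis."""
    return int(math.floor(x + 0.5))


def _require(name: str, value: float | None) -> float:
    if value is None:
        raise MissingLabError(f"missing required lab: {name}")
    return value


def _note(rules: list[str] | None, message: str) -> None:
    if rules is not None:
        rules.append(message)


def _floored(name: str, value: float, floor: float, rules: list[str] | None) -> float:
    if value < floor:
        _note(rules, f"{name} {value:g} floored to {floor:g}")
        return floor
    return value


def _capped(name: str, value: float, cap: float, rules: list[str] | None) -> float:
    if value > cap:
        _note(rules, f"{name} {value:g} capped to {cap:g}")
        return cap
    return value


def _meld_inputs(labs: LabPanel, on_dialysis: bool, rules: list[str] | None):
    cr = _require("creatinine", labs.creatinine_mg_dl())
    bili = _require("bilirubin", labs.bilirubin_mg_dl())
    inr = _require("inr", labs.inr)
    if on_dialysis:
        if cr != 4.0:
            _note(rules, f"creatinine {cr:g} set to 4.0 (dialysis)")
        cr = 4.0
    cr = _floored("creatinine", cr, 1.0, rules)
    cr = _capped("creatinine", cr, 4.0, rules)
    bili = _floored("bilirubin", bili, 1.0, rules)
    inr = _floored("inr", inr, 1.0, rules)
    return cr, bili, inr


def meld(labs: LabPanel, on_dialysis: bool = False, rules: list[str] | None = None) -> int:
    """MELD score in integer points (range 6–40)."""
    cr, bili, inr = _meld_inputs(labs, on_dialysis, rules)
    raw = 10.0 * (0.957 * math.log(cr) + 0.378 * math.log(bili) + 1.120 * math.log(inr) + 0.643)
    points = _round_half_up(raw)
    if points > 40:
        _note(rules, f"meld {points} capped to 40")
        points = 40
    return points


def meso(
    labs: LabPanel,
    on_dialysis: bool = False,
    rules: list[str] | None = None,
    *,
    integer_meld: bool = True,
    sodium_clamp: bool = False,
) -> float:
    """MESO index: MELD / serum sodium × 10.

    ``integer_meld`` uses the rounded MELD (the published reading of
    "MELD as above"); ``sodium_clamp`` optionally borrows the 125–140
    MELD-Na clamp for sensitivity analyses (off by default — the published
    rule states none).
    """
    na = _require("sodium", labs.sodium)
    if na <= 0:
        raise ValueError(f"sodium must be positive, got {na}")
    if sodium_clamp:
        clamped = clamp(na, 125.0, 140.0)
        if clamped != na:
            _note(rules, f"sodium {na:g} clamped to {clamped:g}")
        na = clamped
    if integer_meld:
        m: float = meld(labs, on_dialysis, rules)
    else:
        cr, bili, inr = _meld_inputs(labs, on_dialysis, rules)
        m = 10.0 * (0.957 * math.log(cr) + 0.378 * math.log(bili) + 1.120 * math.log(inr) + 0.643)
    return m / na * 10.0


def meld_na(labs: LabPanel, on_dialysis: bool = False, rules: list[str] | None = None) -> int:
    """MELD-Na in integer points; sodium clamped to 125–140 mmol/l."""
    na = _require("sodium", labs.sodium)
    clamped = clamp(na, 125.0, 140.0)
    if clamped != na:
        _note(rules, f"sodium {na:g} clamped to {clamped:g}")
    na = clamped
    m = meld(labs, on_dialysis, rules)
    value = m - na - 0.025 * m * (140.0 - na) + 140.0
    return _round_half_up(value)


def ukeld(labs: LabPanel, rules: list[str] | None = None) -> float:
    """UKELD score (SI units); no dialysis substitution is published for it."""
    cr = _require("creatinine", labs.creatinine_umol_l())
    bili = _require("bilirubin", labs.bilirubin_umol_l())
    inr = _require("inr", labs.inr)
    na = _require("sodium", labs.sodium)
    cr = _floored("creatinine", cr, 1.0, rules)
    cr = _capped("creatinine", cr, 400.0, rules)
    na_c = clamp(na, 112.0, 150.0)
    if na_c != na:
        _note(rules, f"sodium {na:g} clamped to {na_c:g}")
    na = na_c
    bili = _floored("bilirubin", bili, 1.0, rules)
    inr = _floored("inr", inr, 1.0, rules)
    return (
        1.485 * math.log(cr)
        + 3.13 * math.log(bili)
        + 5.395 * math.log(inr)
        - 81.565 * math.log(na)
        + 435.0
    )


def imeld(
    labs: LabPanel,
    on_dialysis: bool = False,
    age_years: float | None = None,
    rules: list[str] | None = None,
) -> float:
    """iMELD: MELD + 0.3·age − 0.7·sodium + 100 (no sodium clamp published)."""
    if age_years is None:
        raise MissingLabError("missing required covariate: age_years")
    na = _require("sodium", labs.sodium)
    m = meld(labs, on_dialysis, rules)
    return m + 0.3 * age_years - 0.7 * na + 100.0


def _refit_inputs(labs: LabPanel, on_dialysis: bool, rules: list[str] | None):
    cr = _require("creatinine", labs.creatinine_mg_dl())
    bili = _require("bilirubin", labs.bilirubin_mg_dl())
    inr = _require("inr", labs.inr)
    if on_dialysis:
        if cr != 3.0:
            _note(rules, f"creatinine {cr:g} set to 3.0 (dialysis)")
        cr = 3.0
    cr = _floored("creatinine", cr, 0.8, rules)
    cr = _capped("creatinine", cr, 3.0, rules)
    bili = _floored("bilirubin", bili, 1.0, rules)
    inr = _floored("inr", inr, 1.0, rules)
    inr = _capped("inr", inr, 3.0, rules)
    return cr, bili, inr


def refit_meld(labs: LabPanel, on_dialysis: bool = False, rules: list[str] | None = None) -> float:
    """refitMELD with re-estimated coefficients; creatinine clamped to 0.8–3.0 mg/dl."""
    cr, bili, inr = _refit_inputs(labs, on_dialysis, rules)
    return 8.485 * math.log(cr) + 4.082 * math.log(bili) + 10.671 * math.log(inr) + 7.432


def refit_meld_na(
    labs: LabPanel, on_dialysis: bool = False, rules: list[str] | None = None
) -> float:
    """refitMELD-Na: adds a sodium term and an untransformed BiliCC interaction.

    BiliCC is bilirubin (after the 1.0 floor) capped at 20 mg/dl and enters
    the sodium interaction without a log transform, exactly as published here.
    """
    na = _require("sodium", labs.sodium)
    cr, bili, inr = _refit_inputs(labs, on_dialysis, rules)
    na_c = clamp(na, 125.0, 140.0)
    if na_c != na:
        _note(rules, f"sodium {na:g} clamped to {na_c:g}")
    na = na_c
    bili_cc = _capped("bilirubin (BiliCC)", bili, 20.0, rules)
    return (
        6.792 * math.log(cr)
        + 4.258 * math.log(bili)
        + 8.29 * math.log(inr)
        + 0.652 * (140.0 - na)
        - 0.194 * (140.0 - na) * bili_cc
        + 6.327
    )


def up_meld(labs: LabPanel, on_dialysis: bool = False, rules: list[str] | None = None) -> float:
    """upMELD: ln(1+x) formulation; dialysis does not substitute creatinine.

    The published handling caps creatinine at 4.0 mg/dl "with or without
    renal replacement therapy", so ``on_dialysis`` is accepted for interface
    symmetry but never alters the inputs.
    """
    cr = _require("creatinine", labs.creatinine_mg_dl())
    bili = _require("bilirubin", labs.bilirubin_mg_dl())
    inr = _require("inr", labs.inr)
    cr = _floored("creatinine", cr, 1.0, rules)
    cr = _capped("creatinine", cr, 4.0, rules)
    bili = _floored("bilirubin", bili, 1.0, rules)
    inr = _floored("inr", inr, 1.0, rules)
    return 1.266 * math.log1p(cr) + 0.939 * math.log1p(bili) + 1.658 * math.log1p(inr)


def peld(
    labs: LabPanel,
    age_at_listing_years: float,
    growth_failure: bool = False,
    rules: list[str] | None = None,
) -> float:
    """PELD score ×10, unrounded (may be negative).

    Age indicator is 1 below 1 year of age at listing; the growth-failure
    indicator is forced to 0 for patients older than 219 months.
    """
    alb = _require("albumin", labs.albumin_g_dl())
    bili = _require("bilirubin", labs.bilirubin_mg_dl())
    inr = _require("inr", labs.inr)
    if alb <= 0:
        raise ValueError(f"albumin must be positive, got {alb}")
    age_ind = 1.0 if age_at_listing_years < 1.0 else 0.0
    gf = 1.0 if growth_failure else 0.0
    if growth_failure and age_at_listing_years * 12.0 > PELD_GROWTH_FAILURE_MAX_MONTHS:
        _note(rules, "growth failure set to 0 (age > 219 months)")
        gf = 0.0
    return (
        0.436 * age_ind
        - 0.687 * math.log(alb)
        + 0.480 * math.log(bili)
        + 1.857 * math.log(inr)
        + 0.667 * gf
    ) * 10.0


@dataclass(frozen=True)
class ScoreConfig:
    """Options for the panel driver.

    peld_max_age
        Age ceiling (years) above which PELD is reported missing; ``None``
        computes PELD for all age groups (the default here, since the score
        is validated cohort-wide as a covariate).
    meso_integer_meld
        Use the rounded integer MELD inside MESO (published reading) rather
        than the raw continuous value.
    meso_imeld_sodium_clamp
        Borrow the MELD-Na 125–140 sodium clamp for MESO (sensitivity
        analysis switch; the published rules state no clamp).
    """

    peld_max_age: float | None = None
    meso_integer_meld: bool = True
    meso_imeld_sodium_clamp: bool = False


@dataclass
class ScorePanel:
    """All nine scores for one patient plus an audit trail of applied rules.

    A score is ``None`` when a required input is missing (or the patient is
    PELD-age-ineligible under the configuration); the reason is recorded in
    ``applied_rules``.
    """

    patient_id: str
    meld: int | None = None
    meso: float | None = None
    meld_na: int | None = None
    ukeld: float | None = None
    imeld: float | None = None
    refit_meld: float | None = None
    refit_meld_na: float | None = None
    up_meld: float | None = None
    peld: float | None = None
    applied_rules: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float | int | None]:
        return {name: getattr(self, name) for name in SCORE_NAMES}


def score_panel(patient: PatientRecord, config: ScoreConfig | None = None) -> ScorePanel:
    """Compute every computable score for one patient, recording applied rules."""
    config = config or ScoreConfig()
    labs = patient.labs
    dial = patient.is_on_dialysis
    panel = ScorePanel(patient_id=patient.patient_id)

    def compute(name: str, fn):
        rules: list[str] = []
        try:
            value = fn(rules)
        except MissingLabError as exc:
            panel.applied_rules.append(f"{name}: missing ({exc})")
            return
        setattr(panel, name, value)
        panel.applied_rules.extend(f"{name}: {r}" for r in rules)

    compute("meld", lambda r: meld(labs, dial, r))
    compute(
        "meso",
        lambda r: meso(
            labs,
            dial,
            r,
            integer_meld=config.meso_integer_meld,
            sodium_clamp=config.meso_imeld_sodium_clamp,
        ),
    )
    compute("meld_na", lambda r: meld_na(labs, dial, r))
    compute("ukeld", lambda r: ukeld(labs, r))
    compute("imeld", lambda r: imeld(labs, dial, patient.age_at_listing, r))
    compute("refit_meld", lambda r: refit_meld(labs, dial, r))
    compute("refit_meld_na", lambda r: refit_meld_na(labs, dial, r))
    compute("up_meld", lambda r: up_meld(labs, dial, r))
    if config.peld_max_age is not None and patient.age_at_listing >= config.peld_max_age:
        panel.applied_rules.append(
            f"peld: not computed (age {patient.age_at_listing:g} >= limit {config.peld_max_age:g})"
        )
    else:
        compute("peld", lambda r: peld(labs, patient.age_at_listing, patient.growth_failure, r))
    return panel
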