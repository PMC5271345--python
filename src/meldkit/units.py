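"""Laboratory values, unit conversion and clamping primitives.

Every prognostic score in this package consumes a :class:`LabPanel`. Formulas
in the MELD family mix conventional (mg/dl, g/dl) and SI (μmol/l, g/l) units,
so each concentration carries an explicit unit tag and is converted on demand
with the standard clinical-chemistry factors. Missing values are represented
as ``None`` — never 0 — and propagate as explicit missing results downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ConversionError",
    "MissingLabError",
    "LabPanel",
    "PatientRecord",
    "INDICATIONS",
    "convert_concentration",
    "clamp",
    "normalize_unit",
]

#: molar mass based factors: creatinine 113.12 g/mol, bilirubin 584.66 g/mol
CREATININE_MGDL_TO_UMOLL = 88.42
BILIRUBIN_MGDL_TO_UMOLL = 17.104
ALBUMIN_GDL_TO_GL = 10.0

#: ELTR-style indication groups carried as a fixed enumeration.
INDICATIONS = (
    "acute_hepatic_failure",
    "cholestatic",
    "congenital_biliary",
    "cirrhosis",
    "cancer",
    "metabolic",
    "budd_chiari",
    "benign_polycystic",
    "retransplant",
    "other",
)

_UNIT_ALIASES = {
    "umol/l": "umol/l",
    "μmol/l": "umol/l",  # μmol/l
    "µmol/l": "umol/l",
    "mg/dl": "mg/dl",
    "g/dl": "g/dl",
    "g/l": "g/l",
}

# (analyte, from, to) -> multiplicative factor
_FACTORS = {
    ("creatinine", "mg/dl", "umol/l"): CREATININE_MGDL_TO_UMOLL,
    ("bilirubin", "mg/dl", "umol/l"): BILIRUBIN_MGDL_TO_UMOLL,
    ("albumin", "g/dl", "g/l"): ALBUMIN_GDL_TO_GL,
}
for (_a, _f, _t), _k in list(_FACTORS.items()):
    _FACTORS[(_a, _t, _f)] = 1.0 / _k


class ConversionError(ValueError):
    """Unsupported analyte/unit combination."""


class MissingLabError(ValueError):
    """A score was asked for a laboratory value that is absent."""


def normalize_unit(unit: str) -> str:
    """Map unit spellings (``μmol/l``, ``umol/l``, case variants) to a canonical tag."""
    key = unit.strip().lower()
    if key not in _UNIT_ALIASES:
        raise ConversionError(f"unrecognised unit {unit!r}")
    return _UNIT_ALIASES[key]


def convert_concentration(value: float, from_unit: str, to_unit: str, analyte: str) -> float:
    """Convert a concentration between conventional and SI units.

    Parameters
    ----------
    value
        Strictly positive concentration.
    from_unit, to_unit
        Unit tags; creatinine/bilirubin support ``mg/dl`` and ``umol/l``,
        albumin supports ``g/dl`` and ``g/l``.
    analyte
        One of ``creatinine``, ``bilirubin``, ``albumin``.
    """
    if value is None or not value > 0:
        raise ValueError(f"concentration must be strictly positive, got {value!r}")
    fu, tu = normalize_unit(from_unit), normalize_unit(to_unit)
    if fu == tu:
        return value
    try:
        return value * _FACTORS[(analyte, fu, tu)]
    except KeyError:
        raise ConversionError(
            f"no conversion for analyte {analyte!r} from {from_unit!r} to {to_unit!r}"
        ) from None


def clamp(value: float, lower: float | None = None, upper: float | None = None) -> float:
    """Clamp ``value`` into ``[lower, upper]``; absent bounds are ignored."""
    if lower is not None and upper is not None and lower > upper:
        raise ValueError(f"lower bound {lower} exceeds upper bound {upper}")
    if lower is not None and value < lower:
        return lower
    if upper is not None and value > upper:
        return upper
    return value


def _check_positive(name: str, value: float | None) -> None:
    if value is None:
        return
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class LabPanel:
    """One patient's laboratory measurements with explicit units.

    ``None`` marks a missing measurement. Unit tags are mandatory for the
    analytes whose formulas mix unit systems (creatinine, bilirubin, albumin);
    INR is dimensionless, sodium is always mmol/l, PTT is seconds and is a
    regression covariate only.
    """

    creatinine: float | None = None
    creatinine_unit: str = "umol/l"
    bilirubin: float | None = None
    bilirubin_unit: str = "umol/l"
    inr: float | None = None
    sodium: float | None = None
    albumin: float | None = None
    albumin_unit: str = "g/l"
    ptt: float | None = None

    def __post_init__(self) -> None:
        for name in ("creatinine", "bilirubin", "inr", "sodium", "albumin", "ptt"):
            _check_positive(name, getattr(self, name))
        object.__setattr__(self, "creatinine_unit", normalize_unit(self.creatinine_unit))
        object.__setattr__(self, "bilirubin_unit", normalize_unit(self.bilirubin_unit))
        object.__setattr__(self, "albumin_unit", normalize_unit(self.albumin_unit))

    def _get(self, analyte: str, unit: str) -> float | None:
        value = getattr(self, analyte)
        if value is None:
            return None
        return convert_concentration(value, getattr(self, f"{analyte}_unit"), unit, analyte)

    def creatinine_mg_dl(self) -> float | None:
        return self._get("creatinine", "mg/dl")

    def creatinine_umol_l(self) -> float | None:
        return self._get("creatinine", "umol/l")

    def bilirubin_mg_dl(self) -> float | None:
        return self._get("bilirubin", "mg/dl")

    def bilirubin_umol_l(self) -> float | None:
        return self._get("bilirubin", "umol/l")

    def albumin_g_dl(self) -> float | None:
        return self._get("albumin", "g/dl")

    def albumin_g_l(self) -> float | None:
        return self._get("albumin", "g/l")


@dataclass(frozen=True)
class PatientRecord:
    """A waiting-list candidate: demographics, clinical flags, labs, outcome.

    ``on_dialysis`` of ``None`` means "derive from dialysis_sessions_per_week
    >= 1"; an explicit boolean overrides the derivation.
    """

    patient_id: str
    age_at_listing: float
    sex: str
    weight: float
    height: float
    labs: LabPanel = field(default_factory=LabPanel)
    dialysis_sessions_per_week: int = 0
    on_dialysis: bool | None = None
    growth_failure: bool = False
    hu_status: bool = False
    standard_exception: bool = False
    indication: str = "other"
    retransplant: bool = False
    days_on_list: int = 0
    outcome: str = "transplanted"
    died_within_90d: bool = False

    def __post_init__(self) -> None:
        if self.age_at_listing < 0:
            raise ValueError(f"age_at_listing must be >= 0, got {self.age_at_listing}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.indication not in INDICATIONS:
            raise ValueError(f"unknown indication {self.indication!r}")
        if self.outcome not in ("transplanted", "died", "delisted"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not (0 <= self.dialysis_sessions_per_week <= 7):
            raise ValueError("dialysis_sessions_per_week must be in 0..7")
        if self.days_on_list < 0:
            raise ValueError("days_on_list must be >= 0")
        if self.died_within_90d and self.days_on_list > 90:
            raise ValueError("died_within_90d requires days_on_list <= 90")
        for name in ("weight", "height"):
            _check_positive(name, getattr(self, name))

    @property
    def bmi(self) -> float:
        """Body mass index in kg/m², derived from weight and height."""
        return self.weight / self.height**2

    @property
    def is_on_dialysis(self) -> bool:
        if self.on_dialysis is not None:
            return self.on_dialysis
        return self.dialysis_sessions_per_week >= 1

    def with_labs(self, labs: LabPanel) -> "PatientRecord":
        return replace(self, labs=labs)
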