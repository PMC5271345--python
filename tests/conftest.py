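import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from meldkit.units import LabPanel, PatientRecord


def make_labs(
    cr=None,
    bili=None,
    inr=None,
    na=None,
    alb=None,
    ptt=None,
    cr_unit="mg/dl",
    bili_unit="mg/dl",
    alb_unit="g/dl",
):
    """LabPanel builder with conventional-unit defaults (test convenience)."""
    return LabPanel(
        creatinine=cr,
        creatinine_unit=cr_unit,
        bilirubin=bili,
        bilirubin_unit=bili_unit,
        inr=inr,
        sodium=na,
        albumin=alb,
        albumin_unit=alb_unit,
        ptt=ptt,
    )


@pytest.fixture
def floor_labs():
    """All score inputs at their 1.0 floors, sodium 140, albumin 1 g/dl."""
    return make_labs(cr=1.0, bili=1.0, inr=1.0, na=140.0, alb=1.0)


@pytest.fixture
def typical_patient():
    return PatientRecord(
        patient_id="P001",
        age_at_listing=50.0,
        sex="female",
        weight=70.0,
        height=1.70,
        labs=make_labs(cr=1.2, bili=2.5, inr=1.5, na=135.0, alb=3.0, ptt=40.0),
        days_on_list=120,
        outcome="transplanted",
    )
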