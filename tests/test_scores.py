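"""Score calculators against hand-derived values, literal-formula oracles and
their published handling rules (floors, caps, dialysis substitutions)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import make_labs
from meldkit.scores import (
    ScoreConfig,
    imeld,
    meld,
    meld_na,
    meso,
    peld,
    refit_meld,
    refit_meld_na,
    score_panel,
    up_meld,
    ukeld,
)
from meldkit.units import MissingLabError


class TestMeld:
    @pytest.mark.parametrize(
        "cr,bili,inr,dialysis,expected",
        [
            (1.0, 1.0, 1.0, False, 6),  # analytic floor: 10*0.643 rounds to 6
            (1.2, 2.5, 1.5, False, 16),
            (10.0, 50.0, 12.0, False, 40),  # ceiling fires
            (0.5, 2.5, 1.5, True, 28),  # dialysis forces creatinine to 4.0
            (0.5, 0.5, 0.5, False, 6),  # all floors fire
        ],
    )
    def test_hand_examples(self, cr, bili, inr, dialysis, expected):
        assert meld(make_labs(cr=cr, bili=bili, inr=inr), dialysis) == expected

    def test_bounds_on_grid(self):
        """6 <= MELD <= 40 over an exhaustive positive input grid."""
        grid = [0.1, 0.5, 1.0, 2.0, 4.0, 10.0, 50.0]
        for cr in grid:
            for bili in grid:
                for inr in grid:
                    m = meld(make_labs(cr=cr, bili=bili, inr=inr))
                    assert 6 <= m <= 40

    def test_missing_lab_raises(self):
        with pytest.raises(MissingLabError, match="bilirubin"):
            meld(make_labs(cr=1.0, inr=1.0))

    def test_audit_trail_records_fired_rules(self):
        rules = []
        meld(make_labs(cr=5.0, bili=0.5, inr=1.5), rules=rules)
        assert any("capped" in r for r in rules)
        assert any("floored" in r for r in rules)


class TestSodiumScores:
    def test_meso_examples(self):
        assert meso(make_labs(cr=1.0, bili=1.0, inr=1.0, na=140)) == pytest.approx(6 / 140 * 10)
        assert meso(make_labs(cr=1.2, bili=2.5, inr=1.5, na=140)) == pytest.approx(16 / 140 * 10)

    def test_meso_uses_integer_meld_by_default(self):
        labs = make_labs(cr=1.2, bili=2.5, inr=1.5, na=140)
        continuous = meso(labs, integer_meld=False)
        assert meso(labs) == pytest.approx(16 / 140 * 10)
        assert continuous != pytest.approx(meso(labs))

    def test_meld_na_identity_at_140(self):
        labs = make_labs(cr=1.2, bili=2.5, inr=1.5, na=140)
        assert meld_na(labs) == meld(labs) == 16

    @pytest.mark.parametrize("na,expected", [(130.0, 22), (120.0, 25), (125.0, 25)])
    def test_meld_na_hand_examples(self, na, expected):
        assert meld_na(make_labs(cr=1.2, bili=2.5, inr=1.5, na=na)) == expected

    def test_imeld_hand_examples(self):
        assert imeld(
            make_labs(cr=1.2, bili=2.5, inr=1.5, na=135), False, 50
        ) == pytest.approx(36.5)
        assert imeld(
            make_labs(cr=1.0, bili=1.0, inr=1.0, na=140), False, 0
        ) == pytest.approx(8.0)


class TestUkeld:
    def test_hand_example(self):
        labs = make_labs(cr=100, bili=50, inr=1.5, na=135, cr_unit="umol/l", bili_unit="umol/l")
        expected = 1.485 * math.log(100) + 3.13 * math.log(50) + 5.395 * math.log(1.5)
        expected += -81.565 * math.log(135) + 435
        assert ukeld(labs) == pytest.approx(expected, abs=1e-9)
        assert round(ukeld(labs), 2) == 56.17

    def test_analytic_minimum(self):
        labs = make_labs(cr=1, bili=1, inr=1, na=150, cr_unit="umol/l", bili_unit="umol/l")
        assert ukeld(labs) == pytest.approx(435 - 81.565 * math.log(150))

    def test_creatinine_cap_equivalence(self):
        at_cap = make_labs(cr=400, bili=30, inr=1.2, na=138, cr_unit="umol/l", bili_unit="umol/l")
        beyond = make_labs(cr=500, bili=30, inr=1.2, na=138, cr_unit="umol/l", bili_unit="umol/l")
        assert ukeld(beyond) == ukeld(at_cap)


class TestRefitScores:
    def test_refit_meld_examples(self):
        assert refit_meld(make_labs(cr=0.8, bili=1.0, inr=1.0)) == pytest.approx(
            8.485 * math.log(0.8) + 7.432
        )
        assert refit_meld(make_labs(cr=1.5, bili=3.0, inr=2.0)) == pytest.approx(22.75, abs=0.005)
        # dialysis substitutes creatinine 3.0 even from below the floor
        assert refit_meld(make_labs(cr=0.5, bili=1.0, inr=1.0), True) == pytest.approx(
            8.485 * math.log(3.0) + 7.432
        )

    def test_refit_meld_na_vanishing_case(self):
        assert refit_meld_na(make_labs(cr=1, bili=1, inr=1, na=140)) == pytest.approx(6.327)

    def test_refit_meld_na_bilicc_interaction(self):
        # bilirubin 25 enters the log term uncapped but the interaction at 20
        got = refit_meld_na(make_labs(cr=1, bili=25, inr=1, na=130))
        expected = 4.258 * math.log(25) + 0.652 * 10 - 0.194 * 10 * 20 + 6.327
        assert got == pytest.approx(expected, abs=1e-9)
        assert round(got, 3) == -12.247

    def test_refit_meld_na_sodium_clamp_equivalence(self):
        low = refit_meld_na(make_labs(cr=1, bili=1, inr=1, na=120))
        at = refit_meld_na(make_labs(cr=1, bili=1, inr=1, na=125))
        assert low == at


class TestUpMeld:
    def test_analytic_floor(self):
        got = up_meld(make_labs(cr=1, bili=1, inr=1))
        assert got == pytest.approx((1.266 + 0.939 + 1.658) * math.log(2))
        assert round(got, 2) == 2.68

    def test_hand_example(self):
        got = up_meld(make_labs(cr=2, bili=5, inr=1.5))
        assert got == pytest.approx(
            1.266 * math.log(3) + 0.939 * math.log(6) + 1.658 * math.log(2.5)
        )

    def test_cap_equivalence_and_no_dialysis_substitution(self):
        beyond = make_labs(cr=8, bili=1, inr=1)
        at_cap = make_labs(cr=4, bili=1, inr=1)
        assert up_meld(beyond) == up_meld(at_cap)
        # renal replacement does not alter creatinine for this score
        low_cr = make_labs(cr=1.5, bili=1, inr=1)
        assert up_meld(low_cr, True) == up_meld(low_cr, False)


class TestPeld:
    def test_all_terms_vanish(self):
        assert peld(make_labs(bili=1, inr=1, alb=1), 5.0, False) == pytest.approx(0.0)

    def test_infant_with_growth_failure(self):
        got = peld(make_labs(bili=3, inr=2, alb=3.0), 0.5, True)
        expected = (
            0.436 - 0.687 * math.log(3) + 0.480 * math.log(3) + 1.857 * math.log(2) + 0.667
        ) * 10
        assert got == pytest.approx(expected)
        assert round(got, 2) == 21.63

    def test_growth_failure_zeroed_above_219_months(self):
        with_flag = peld(make_labs(bili=3, inr=2, alb=3.0), 20.0, True)
        without = peld(make_labs(bili=3, inr=2, alb=3.0), 20.0, False)
        assert with_flag == without

    def test_may_be_negative(self):
        assert peld(make_labs(bili=1, inr=1, alb=4.5), 5.0, False) < 0


class TestOracleEquivalence:
    """Each calculator matches an independent literal transcription of its
    published formula on 1000 random inputs."""

    def test_all_scores_match_literal_formulas(self):
        rng = np.random.default_rng(20170127)
        for _ in range(1000):
            cr = float(rng.lognormal(0, 1))
            bili = float(rng.lognormal(0.5, 1.2))
            inr = float(rng.lognormal(0.3, 0.5))
            na = float(rng.normal(137, 8))
            alb = float(rng.uniform(0.5, 5.5))
            age = float(rng.uniform(0, 75))
            dial = bool(rng.random() < 0.1)
            gf = bool(rng.random() < 0.2)
            labs = make_labs(cr=cr, bili=bili, inr=inr, na=na, alb=alb)
            cr_si = cr * 88.42
            bili_si = bili * 17.104
            labs_si = make_labs(
                cr=cr_si, bili=bili_si, inr=inr, na=na, cr_unit="umol/l", bili_unit="umol/l"
            )
            assert meld(labs, dial) == oracles.meld_oracle(cr, bili, inr, dial)
            assert meso(labs, dial) == pytest.approx(
                oracles.meso_oracle(cr, bili, inr, na, dial), abs=1e-9
            )
            assert meld_na(labs, dial) == oracles.meld_na_oracle(cr, bili, inr, na, dial)
            assert ukeld(labs_si) == pytest.approx(
                oracles.ukeld_oracle(cr_si, bili_si, inr, na), abs=1e-9
            )
            assert imeld(labs, dial, age) == pytest.approx(
                oracles.imeld_oracle(cr, bili, inr, na, age, dial), abs=1e-9
            )
            assert refit_meld(labs, dial) == pytest.approx(
                oracles.refit_meld_oracle(cr, bili, inr, dial), abs=1e-9
            )
            assert refit_meld_na(labs, dial) == pytest.approx(
                oracles.refit_meld_na_oracle(cr, bili, inr, na, dial), abs=1e-9
            )
            assert up_meld(labs, dial) == pytest.approx(
                oracles.up_meld_oracle(cr, bili, inr, dial), abs=1e-9
            )
            assert peld(labs, age, gf) == pytest.approx(
                oracles.peld_oracle(alb, bili, inr, age, gf), abs=1e-9
            )


@st.composite
def lab_values(draw):
    return dict(
        cr=draw(st.floats(0.2, 12.0)),
        bili=draw(st.floats(0.2, 60.0)),
        inr=draw(st.floats(0.5, 20.0)),
        na=draw(st.floats(115.0, 155.0)),
    )


class TestMonotonicity:
    @settings(max_examples=150, derandomize=True)
    @given(v=lab_values(), bump=st.floats(0.01, 5.0))
    def test_nondecreasing_in_bilirubin_and_inr(self, v, bump):
        base = make_labs(**v)
        more_bili = make_labs(**{**v, "bili": v["bili"] + bump})
        more_inr = make_labs(**{**v, "inr": v["inr"] + bump})
        for fn in (meld, refit_meld, up_meld):
            assert fn(more_bili) >= fn(base)
            assert fn(more_inr) >= fn(base)
        assert ukeld(more_bili) >= ukeld(base)
        assert meld_na(more_bili) >= meld_na(base)

    @settings(max_examples=150, derandomize=True)
    @given(v=lab_values(), bump=st.floats(0.01, 5.0))
    def test_nondecreasing_in_creatinine(self, v, bump):
        base = make_labs(**v)
        more = make_labs(**{**v, "cr": v["cr"] + bump})
        for fn in (meld, refit_meld, up_meld):
            assert fn(more) >= fn(base)

    @settings(max_examples=150, derandomize=True)
    @given(v=lab_values(), bump=st.floats(0.01, 5.0))
    def test_sodium_scores_nonincreasing_in_sodium(self, v, bump):
        v["na"] = min(v["na"], 148.0)
        base = make_labs(**v)
        more = make_labs(**{**v, "na": v["na"] + bump})
        assert meld_na(more) <= meld_na(base)
        assert ukeld(more) <= ukeld(base)
        assert imeld(more, False, 40) <= imeld(base, False, 40)
        # refitMELD-Na's sodium effect is 0.652 - 0.194*BiliCC per mmol/l: the
        # printed interaction reverses its sign once bilirubin exceeds ~3.36
        # mg/dl, so monotonicity in sodium only holds below that point.
        if max(v["bili"], 1.0) < 0.652 / 0.194:
            assert refit_meld_na(more) <= refit_meld_na(base)

    @settings(max_examples=100, derandomize=True)
    @given(v=lab_values())
    def test_meld_na_equals_meld_at_140(self, v):
        labs = make_labs(**{**v, "na": 140.0})
        assert meld_na(labs) == meld(labs)


class TestClampEquivalence:
    """For every published bound, an input beyond it scores exactly as an
    input at it."""

    CASES = [
        (meld, {"cr": (4.0, 9.0)}, {"bili": 2.0, "inr": 1.5}),
        (meld, {"cr": (1.0, 0.3)}, {"bili": 2.0, "inr": 1.5}),
        (meld, {"bili": (1.0, 0.2)}, {"cr": 2.0, "inr": 1.5}),
        (meld, {"inr": (1.0, 0.6)}, {"cr": 2.0, "bili": 2.0}),
        (refit_meld, {"cr": (3.0, 7.0)}, {"bili": 2.0, "inr": 1.5}),
        (refit_meld, {"cr": (0.8, 0.4)}, {"bili": 2.0, "inr": 1.5}),
        (refit_meld, {"inr": (3.0, 8.0)}, {"cr": 1.5, "bili": 2.0}),
        (refit_meld, {"bili": (1.0, 0.3)}, {"cr": 1.5, "inr": 1.5}),
        (up_meld, {"cr": (4.0, 6.0)}, {"bili": 2.0, "inr": 1.5}),
        (up_meld, {"bili": (1.0, 0.5)}, {"cr": 2.0, "inr": 1.5}),
    ]

    @pytest.mark.parametrize("fn,varying,fixed", CASES)
    def test_beyond_bound_equals_at_bound(self, fn, varying, fixed):
        (name, (bound, beyond)), = varying.items()
        at = make_labs(**{**fixed, name: bound, "na": 138.0})
        past = make_labs(**{**fixed, name: beyond, "na": 138.0})
        assert fn(past) == fn(at)

    @pytest.mark.parametrize("na_pair", [(125.0, 118.0), (140.0, 149.0)])
    def test_meld_na_sodium_bounds(self, na_pair):
        at, beyond = na_pair
        fixed = {"cr": 2.0, "bili": 2.0, "inr": 1.5}
        assert meld_na(make_labs(**fixed, na=beyond)) == meld_na(make_labs(**fixed, na=at))

    @pytest.mark.parametrize("na_pair", [(112.0, 100.0), (150.0, 160.0)])
    def test_ukeld_sodium_bounds(self, na_pair):
        at, beyond = na_pair
        fixed = dict(cr=100.0, bili=30.0, inr=1.5, cr_unit="umol/l", bili_unit="umol/l")
        assert ukeld(make_labs(**fixed, na=beyond)) == ukeld(make_labs(**fixed, na=at))


class TestScorePanel:
    def test_sodium_140_identity(self, typical_patient):
        import dataclasses

        p = dataclasses.replace(
            typical_patient, labs=make_labs(cr=1.2, bili=2.5, inr=1.5, na=140, alb=3.0)
        )
        panel = score_panel(p)
        assert panel.meld_na == panel.meld

    def test_floor_composition(self, typical_patient):
        import dataclasses

        p = dataclasses.replace(
            typical_patient, labs=make_labs(cr=1.0, bili=1.0, inr=1.0, na=140, alb=3.0)
        )
        panel = score_panel(p)
        assert panel.meld == 6
        assert panel.meso == pytest.approx(6 / 140 * 10)
        assert round(panel.up_meld, 2) == 2.68

    def test_missing_albumin_only_drops_peld(self, typical_patient):
        import dataclasses

        p = dataclasses.replace(typical_patient, labs=make_labs(cr=1.2, bili=2.5, inr=1.5, na=135))
        panel = score_panel(p)
        assert panel.peld is None
        assert all(
            getattr(panel, s) is not None
            for s in ("meld", "meso", "meld_na", "ukeld", "imeld", "refit_meld", "up_meld")
        )
        assert any(r.startswith("peld: missing") for r in panel.applied_rules)

    def test_peld_age_restriction_config(self, typical_patient):
        panel = score_panel(typical_patient, ScoreConfig(peld_max_age=12.0))
        assert panel.peld is None
        assert score_panel(typical_patient).peld is not None
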