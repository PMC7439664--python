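"""Cockcroft-Gault, Hume LBM, Child-Pugh and the two-tier hepatic state."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlicdss.core_model import Ascites, ChildPughInputs, Encephalopathy, Sex
from dlicdss.physiology import (HepaticTier, child_pugh, creatinine_clearance,
                                hepatic_state, lean_body_mass)

from conftest import AS_OF, lab


class TestCreatinineClearance:
    def test_published_reference_case(self):
        assert creatinine_clearance(40, 72, Sex.male, 1.0) == pytest.approx(100.0)

    def test_female_factor_is_0_85(self):
        male = creatinine_clearance(40, 72, Sex.male, 1.0)
        female = creatinine_clearance(40, 72, Sex.female, 1.0)
        assert female == pytest.approx(0.85 * male)
        assert female == pytest.approx(85.0)

    @pytest.mark.parametrize("kwargs", [
        dict(age=140, weight=72, sex=Sex.male, serum_cr=1.0),
        dict(age=16, weight=72, sex=Sex.male, serum_cr=1.0),
        dict(age=40, weight=0, sex=Sex.male, serum_cr=1.0),
        dict(age=40, weight=72, sex=Sex.male, serum_cr=0.0),
        dict(age=40, weight=72, sex=Sex.male, serum_cr=-1.0),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            creatinine_clearance(**kwargs)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(age=st.floats(18, 100), weight=st.floats(40, 150),
           cr=st.floats(0.3, 10), bump=st.floats(0.01, 5))
    def test_monotonicity(self, age, weight, cr, bump):
        base = creatinine_clearance(age, weight, Sex.male, cr)
        assert creatinine_clearance(age, weight, Sex.male, cr + bump) < base
        assert creatinine_clearance(min(age + bump, 139.9), weight,
                                    Sex.male, cr) < base
        assert creatinine_clearance(age, weight + bump, Sex.male, cr) > base

    def test_bsa_normalisation_toggle(self):
        raw = creatinine_clearance(40, 72, Sex.male, 1.0)
        scaled = creatinine_clearance(40, 72, Sex.male, 1.0,
                                      bsa_normalize=True, height=170)
        assert scaled != raw
        with pytest.raises(ValueError):
            creatinine_clearance(40, 72, Sex.male, 1.0, bsa_normalize=True)


class TestLeanBodyMass:
    def test_hume_reference_cases(self):
        assert lean_body_mass(Sex.male, 72, 170).lbm == pytest.approx(51.77, abs=0.01)
        # 0.29569*72 + 0.41813*170 - 43.2933 = 49.07848 by hand
        assert lean_body_mass(Sex.female, 72, 170).lbm == pytest.approx(49.078, abs=0.01)

    def test_linearity_in_weight(self):
        a = lean_body_mass(Sex.male, 80, 175).lbm
        b = lean_body_mass(Sex.male, 81, 175).lbm
        assert b - a == pytest.approx(0.32810)

    def test_missing_height_is_unusable(self):
        with pytest.raises(ValueError):
            lean_body_mass(Sex.male, 72, None)


_CP_BEST = ChildPughInputs(bilirubin_total=1.0, albumin=4.0, inr=1.0,
                           ascites=Ascites.none, encephalopathy=Encephalopathy.none)
_CP_WORST = ChildPughInputs(bilirubin_total=5.0, albumin=2.0, inr=3.0,
                            ascites=Ascites.moderate_severe,
                            encephalopathy=Encephalopathy.grade3_4)


class TestChildPugh:
    def test_extremes(self):
        assert child_pugh(_CP_BEST) == (5, "A")
        assert child_pugh(_CP_WORST) == (15, "C")

    def test_mid_range_case_against_hand_tally(self):
        # 2 (bili 2.5) + 2 (alb 3.0) + 2 (INR 1.9) + 2 (mild ascites) + 1 = 9
        cp = ChildPughInputs(bilirubin_total=2.5, albumin=3.0, inr=1.9,
                             ascites=Ascites.mild,
                             encephalopathy=Encephalopathy.none)
        assert child_pugh(cp) == (9, "B")

    def test_missing_inputs_are_unavailable_not_zero(self):
        with pytest.raises(ValueError):
            child_pugh(None)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(bili=st.floats(0.1, 10), alb=st.floats(1, 6), inr=st.floats(0.8, 5),
           asc=st.sampled_from(list(Ascites)),
           enc=st.sampled_from(list(Encephalopathy)))
    def test_score_range_and_class_partition(self, bili, alb, inr, asc, enc):
        score, cls = child_pugh(ChildPughInputs(
            bilirubin_total=bili, albumin=alb, inr=inr,
            ascites=asc, encephalopathy=enc))
        assert 5 <= score <= 15
        assert cls == ("A" if score <= 6 else "B" if score <= 9 else "C")


def _liver(alt=20.0, ast=20.0, bili=1.0, days_ago=30):
    return [lab("ALT", alt, "U/L", days_ago=days_ago),
            lab("AST", ast, "U/L", days_ago=days_ago),
            lab("Bili_total", bili, "mg/dl", days_ago=days_ago)]


class TestHepaticState:
    def test_alt_just_over_40_is_impaired_with_evidence(self):
        state = hepatic_state(_liver(alt=41), False, None, AS_OF)
        assert state.tier is HepaticTier.impaired
        assert ("ALT", 41.0, "> 40 U/L") in state.evidence

    def test_all_below_thresholds_is_normal(self):
        state = hepatic_state(_liver(), False, None, AS_OF)
        assert state.tier is HepaticTier.normal
        assert state.evidence == []
        assert not state.no_data

    def test_exactly_at_threshold_does_not_trigger(self):
        # comparisons are strict, as printed in the rule source
        assert hepatic_state(_liver(alt=40, ast=40, bili=1.5), False, None,
                             AS_OF).tier is HepaticTier.normal

    def test_alt_130_is_severe(self):
        state = hepatic_state(_liver(alt=130), False, None, AS_OF)
        assert state.tier is HepaticTier.severe

    def test_cirrhosis_history_alone_is_severe(self):
        state = hepatic_state(_liver(), True, None, AS_OF)
        assert state.tier is HepaticTier.severe
        assert any(c == "cirrhosis_history" for c, _, _ in state.evidence)

    def test_child_pugh_class_c_is_severe_and_configurable(self):
        state = hepatic_state(_liver(), False, _CP_WORST, AS_OF)
        assert state.tier is HepaticTier.severe
        relaxed = hepatic_state(_liver(), False, _CP_WORST, AS_OF,
                                child_pugh_c_implies_severe=False)
        assert relaxed.tier is HepaticTier.normal

    def test_no_data_distinct_from_data_normal(self):
        state = hepatic_state([], False, None, AS_OF)
        assert state.tier is HepaticTier.normal and state.no_data

    def test_stale_labs_outside_window_are_ignored(self):
        state = hepatic_state(_liver(alt=300, days_ago=220), False, None, AS_OF)
        assert state.tier is HepaticTier.normal and state.no_data

    @pytest.mark.parametrize("alt", [39.0, 40.0, 41.0, 119.0, 120.0, 121.0])
    @pytest.mark.parametrize("bili", [1.4, 1.5, 1.6, 2.9, 3.0, 3.1])
    @pytest.mark.parametrize("cirrhosis", [False, True])
    def test_tier_grid_matches_direct_boolean_formulas(self, alt, bili, cirrhosis):
        """Brute-force re-evaluation of the two tier formulas around every
        threshold must agree with the classifier."""
        ast = 20.0
        state = hepatic_state(_liver(alt=alt, ast=ast, bili=bili), cirrhosis,
                              None, AS_OF)
        severe = ast > 120 or alt > 120 or bili > 3 or cirrhosis
        impaired = (alt > 40 or ast > 40 or bili > 1.5) and not severe
        expected = (HepaticTier.severe if severe
                    else HepaticTier.impaired if impaired else HepaticTier.normal)
        assert state.tier is expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(alt=st.floats(1, 200), ast=st.floats(1, 200), bili=st.floats(0.1, 6),
           bump=st.floats(0.1, 100))
    def test_raising_any_analyte_never_lowers_the_tier(self, alt, ast, bili, bump):
        base = hepatic_state(_liver(alt=alt, ast=ast, bili=bili), False, None,
                             AS_OF).tier
        for kwargs in (dict(alt=alt + bump, ast=ast, bili=bili),
                       dict(alt=alt, ast=ast + bump, bili=bili),
                       dict(alt=alt, ast=ast, bili=bili + bump)):
            assert hepatic_state(_liver(**kwargs), False, None, AS_OF).tier >= base
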