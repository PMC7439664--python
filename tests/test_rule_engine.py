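"""Engine behaviour: windowing, evaluation, rendering, display contract."""

import dataclasses
import datetime as dt

import pytest

from dlicdss.knowledgebase import (Action, Category, KnowledgeBase, LabCmp,
                                   Medication, Rule)
from dlicdss.rule_engine import (Alert, EngineConfigurationError, RenderingError,
                                 classify_display, evaluate, group_by_medication,
                                 latest_lab, missing_baseline_alerts)
from dlicdss._dates import add_months

from conftest import AS_OF, lab, make_patient, pregnant_record, rx


class TestLatestLab:
    def test_five_months_old_is_inside_the_window(self):
        labs = [lab("Cr", 1.0, "mg/dl", days_ago=150)]
        assert latest_lab(labs, "Cr", AS_OF) is not None

    def test_seven_months_old_is_outside(self):
        labs = [lab("Cr", 1.0, "mg/dl", days_ago=213)]
        assert latest_lab(labs, "Cr", AS_OF) is None

    def test_exactly_six_months_is_excluded_half_open(self):
        stale = lab("Cr", 1.0, "mg/dl")
        stale = stale.model_copy(update={"observed_at": add_months(AS_OF, -6)})
        assert latest_lab([stale], "Cr", AS_OF) is None

    def test_most_recent_of_two_wins(self):
        older = lab("Cr", 2.0, "mg/dl", days_ago=90)
        newer = lab("Cr", 1.0, "mg/dl", days_ago=30)
        assert latest_lab([older, newer], "Cr", AS_OF).value == 1.0


class TestEvaluate:
    def test_crcl_15_on_allopurinol_fires_band_plus_monitoring(self, kb):
        # age 50, 72 kg male, Cr 6.0 -> CrCl = 90/6 = 15 ml/min
        alerts = evaluate(make_patient(), [lab("Cr", 6.0, "mg/dl")],
                          [rx("allopurinol")], kb, AS_OF)
        by_id = {a.rule_id: a for a in alerts}
        assert set(by_id) == {"allopurinol-renal-crcl-10-20",
                              "allopurinol-monitor-uric-acid"}
        renal = by_id["allopurinol-renal-crcl-10-20"]
        assert renal.severity_level == 1
        assert renal.display_mode == "interruptive"
        assert "200 mg/day" in renal.recommendation

    def test_normal_labs_on_cyclosporine_yield_only_monitoring(self, kb):
        labs = [lab("Cr", 1.0, "mg/dl"), lab("ALT", 20, "U/L"),
                lab("AST", 20, "U/L"), lab("Bili_total", 1.0, "mg/dl")]
        alerts = evaluate(make_patient(), labs, [rx("cyclosporine")], kb, AS_OF)
        assert [a.rule_id for a in alerts] == ["cyclosporine-monitor-uric-acid-k-mg"]
        assert alerts[0].severity_level == 3
        assert alerts[0].display_mode == "informational"

    def test_pregnant_patient_on_mycophenolate(self, kb):
        patient = make_patient("female", pregnancy=pregnant_record())
        alerts = evaluate(patient, [], [rx("mycophenolate")], kb, AS_OF)
        by_id = {a.rule_id: a for a in alerts}
        assert set(by_id) == {"mycophenolate-pregnancy-discontinue",
                              "mycophenolate-monitor-bhcg"}
        stop = by_id["mycophenolate-pregnancy-discontinue"]
        assert stop.display_mode == "interruptive" and stop.color == "red"
        assert stop.recommendation == "Discontinue"

    def test_empty_prescriptions_yield_no_alerts(self, kb):
        assert evaluate(make_patient(), [lab("Cr", 6.0, "mg/dl")], [], kb, AS_OF) == []

    def test_no_serum_cr_in_window_silences_renal_rules(self, kb):
        alerts = evaluate(make_patient(), [lab("Cr", 6.0, "mg/dl", days_ago=213)],
                          [rx("hydrochlorothiazide")], kb, AS_OF)
        assert all(a.category != "renal" for a in alerts)

    def test_alerts_are_deterministic_and_ordered(self, kb):
        labs = [lab("Cr", 6.0, "mg/dl"), lab("ALT", 50, "U/L")]
        rxs = [rx("allopurinol"), rx("losartan"), rx("captopril")]
        patient = make_patient("female", pregnancy=pregnant_record())
        a1 = evaluate(patient, labs, rxs, kb, AS_OF)
        a2 = evaluate(patient, labs, rxs, kb, AS_OF)
        assert a1 == a2
        keys = [(a.medication, a.severity_level, a.rule_id) for a in a1]
        assert keys == sorted(keys)

    def test_grouping_collects_all_alerts_per_medication(self, kb):
        labs = [lab("Cr", 6.0, "mg/dl"), lab("ALT", 50, "U/L")]
        alerts = evaluate(make_patient(), labs, [rx("allopurinol")], kb, AS_OF)
        groups = group_by_medication(alerts)
        assert list(groups) == ["Allopurinol"]
        assert len(groups["Allopurinol"]) == 3  # renal + hepatic + monitoring

    def test_underivable_analyte_raises_configuration_error(self):
        kbx = KnowledgeBase(kb_version="x", medication_catalog=[
            Medication("m", "A01", "CAT", "M")],
            rules=[Rule("bad-rule", "m", Category.monitoring,
                        LabCmp("NotAnAnalyte", ">", 1.0, "U/L"),
                        Action("caution", "careful"), 2)])
        with pytest.raises(EngineConfigurationError, match="bad-rule"):
            evaluate(make_patient(), [], [rx("m")], kbx, AS_OF)


class TestRendering:
    def test_captopril_alert_embeds_drug_dose_and_lab_date(self, kb):
        # Cr 11.25 -> CrCl = 90/11.25 = 8 -> "reduce by 50%" band
        cr = lab("Cr", 11.25, "mg/dl", days_ago=30)
        alerts = evaluate(make_patient(), [cr], [rx("captopril")], kb, AS_OF)
        msg = next(a for a in alerts if a.rule_id == "captopril-renal-crcl-lt-10").message
        assert "Captopril" in msg
        assert "50%" in msg
        assert cr.observed_at.date().isoformat() in msg

    def test_monitoring_without_labs_uses_baseline_phrasing(self, kb):
        alerts = evaluate(make_patient("female"), [], [rx("captopril")], kb, AS_OF)
        msg = next(a for a in alerts if a.category == "monitoring").message
        assert "baseline" in msg.lower()
        assert "{" not in msg  # no unexpanded placeholders, ever

    def test_unknown_placeholder_is_a_rendering_error(self, kb):
        rule = kb.rule("captopril-monitor-na-k")
        broken = dataclasses.replace(rule, message_template="{bogus}")
        kbx = KnowledgeBase(kb_version="x", medication_catalog=kb.medication_catalog,
                            rules=[broken])
        with pytest.raises(RenderingError, match="bogus"):
            evaluate(make_patient(), [], [rx("captopril")], kbx, AS_OF)

    def test_hepatic_alert_cites_the_offending_lab(self, kb):
        alt = lab("ALT", 130, "U/L", days_ago=10)
        alerts = evaluate(make_patient(), [alt], [rx("omeprazole")], kb, AS_OF)
        severe = next(a for a in alerts if a.rule_id == "omeprazole-hepatic-severe-reduce")
        assert severe.lab_analyte == "ALT"
        assert severe.lab_value == 130
        assert alt.observed_at.date().isoformat() in severe.message


class TestDisplayContract:
    @pytest.mark.parametrize("severity, expected", [
        (1, "interruptive"), (2, "informational"), (3, "informational")])
    def test_severity_to_display(self, severity, expected):
        assert classify_display(severity) == expected

    def test_out_of_range_severity(self):
        with pytest.raises(ValueError):
            classify_display(4)

    def test_color_law_holds_on_real_evaluations(self, kb):
        labs = [lab("Cr", 30.1, "mg/dl"), lab("ALT", 130, "U/L")]
        patient = make_patient("female", pregnancy=pregnant_record())
        rxs = [rx(m) for m in kb.medications()]
        alerts = evaluate(patient, labs, rxs, kb, AS_OF)
        assert alerts, "scenario should fire alerts of every severity"
        for a in alerts:
            assert a.color == {1: "red", 2: "orange", 3: "yellow"}[a.severity_level]
            assert (a.display_mode == "interruptive") == (a.severity_level == 1)


class TestMissingBaseline:
    def test_new_captopril_without_na_k_prompts_baseline(self, kb):
        alerts = missing_baseline_alerts(
            make_patient(), [], [rx("captopril", start=dt.date(2020, 6, 10))],
            kb, AS_OF)
        assert [a.rule_id for a in alerts] == ["captopril-monitor-na-k"]
        assert alerts[0].severity_level == 3
        assert "baseline" in alerts[0].reason

    def test_bhcg_repeat_due_after_three_months(self, kb):
        start = (AS_OF - dt.timedelta(days=122)).date()  # ~4 months on drug
        old_bhcg = lab("bHCG", 1.0, "mIU/mL", days_ago=107)  # ~3.5 months old
        alerts = missing_baseline_alerts(
            make_patient("female"), [old_bhcg],
            [rx("mycophenolate", start=start)], kb, AS_OF)
        assert [a.rule_id for a in alerts] == ["mycophenolate-monitor-bhcg"]
        assert "overdue" in alerts[0].reason

    def test_fresh_monitored_labs_raise_no_prompts(self, kb):
        start = (AS_OF - dt.timedelta(days=122)).date()
        fresh = lab("bHCG", 1.0, "mIU/mL", days_ago=20)
        alerts = missing_baseline_alerts(
            make_patient("female"), [fresh],
            [rx("mycophenolate", start=start)], kb, AS_OF)
        assert alerts == []

    def test_repeat_not_due_before_first_interval_elapses(self, kb):
        # on allopurinol for one month; 6-month uric-acid repeat not yet due
        alerts = missing_baseline_alerts(
            make_patient(), [], [rx("allopurinol", start=dt.date(2020, 5, 15))],
            kb, AS_OF)
        assert alerts == []


class TestLabFreshnessLaw:
    def test_no_alert_cites_a_lab_outside_the_window(self, kb):
        scenarios = [
            ([lab("Cr", 6.0, "mg/dl", days_ago=100), lab("ALT", 130, "U/L", days_ago=60)],
             [rx("allopurinol"), rx("omeprazole")]),
            ([lab("Cr", 6.0, "mg/dl", days_ago=213)], [rx("captopril")]),
        ]
        window_start = add_months(AS_OF, -6)
        for labs, rxs in scenarios:
            for alert in evaluate(make_patient(), labs, rxs, kb, AS_OF):
                if alert.lab_date is not None:
                    assert dt.date.fromisoformat(alert.lab_date) > window_start.date()
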