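"""Alert lifecycle: reactions, append-only audit, reappearance, expiry."""

import datetime as dt
import json

import pytest

from dlicdss.lifecycle_audit import (AuditLog, Reaction, pregnancy_alert_active,
                                     prescription_event_complete, record_reaction,
                                     should_reappear, summarize)
from dlicdss.rule_engine import evaluate
from dlicdss._dates import add_months

from conftest import AS_OF, lab, make_patient, pregnant_record, rx


def _fire_one(kb, log, *, cr=6.0):
    """Fire the allopurinol CrCl band alert and register it."""
    patient = make_patient()
    alerts = evaluate(patient, [lab("Cr", cr, "mg/dl")], [rx("allopurinol")],
                      kb, AS_OF)
    for a in alerts:
        log.record_firing(a, patient_id=patient.patient_id)
    return patient, alerts


class TestRecordReaction:
    def test_override_on_level1_alert(self, kb):
        log = AuditLog()
        _, alerts = _fire_one(kb, log)
        level1 = next(a for a in alerts if a.severity_level == 1)
        entry = record_reaction(log, level1, "override", "dr-a",
                               AS_OF + dt.timedelta(hours=1))
        assert entry.reaction is Reaction.override
        assert entry.reacted_at >= entry.fired_at

    def test_reaction_on_unknown_alert_is_an_error(self, kb):
        log = AuditLog()
        _, alerts = _fire_one(kb, log)
        ghost = alerts[0].__class__(**{**alerts[0].__dict__, "alert_id": "nope"})
        with pytest.raises(KeyError):
            record_reaction(log, ghost, "override", "dr-a", AS_OF)

    def test_reaction_before_firing_is_an_error(self, kb):
        log = AuditLog()
        _, alerts = _fire_one(kb, log)
        with pytest.raises(ValueError):
            record_reaction(log, alerts[0], "override", "dr-a",
                            AS_OF - dt.timedelta(days=1))

    def test_only_level1_blocks_prescription_completion(self, kb):
        log = AuditLog()
        _, alerts = _fire_one(kb, log)
        assert not prescription_event_complete(log, alerts)  # level-1 unreacted
        level1 = next(a for a in alerts if a.severity_level == 1)
        record_reaction(log, level1, "override", "dr-a", AS_OF)
        # level-3 monitoring alert still has reaction=none; that is fine
        assert prescription_event_complete(log, alerts)


class TestAppendOnly:
    def test_entries_accumulate_and_prior_entries_are_untouched(self, kb):
        log = AuditLog()
        _, alerts = _fire_one(kb, log)
        before = log.entries
        record_reaction(log, alerts[0], "stop_medication", "dr-b", AS_OF)
        assert log.entries[:len(before)] == before
        assert len(log.entries) == len(before) + 1

    def test_jsonl_replay_reconstructs_history(self, kb, tmp_path):
        path = tmp_path / "audit.jsonl"
        log = AuditLog(path)
        _, alerts = _fire_one(kb, log)
        record_reaction(log, alerts[0], "override", "dr-c", AS_OF)
        lines = path.read_text().splitlines()
        assert len(lines) == len(log.entries)
        assert all(json.loads(line) for line in lines)
        replayed = AuditLog(path)
        assert replayed.entries == log.entries

    def test_summary_counts_firings_and_override_rate(self, kb):
        log = AuditLog()
        _, alerts = _fire_one(kb, log)
        level1 = next(a for a in alerts if a.severity_level == 1)
        record_reaction(log, level1, "override", "dr-a", AS_OF)
        rows = {r["rule_id"]: r for r in summarize(log)}
        row = rows[level1.rule_id]
        assert row["firings"] == 1
        assert row["reaction_override"] == 1
        assert row["override_rate"] == 1.0


class TestReappearance:
    def test_override_never_suppresses_refills(self, kb):
        log = AuditLog()
        patient, alerts = _fire_one(kb, log)
        level1 = next(a for a in alerts if a.severity_level == 1)
        record_reaction(log, level1, "override", "dr-a", AS_OF)
        refill = rx("allopurinol", start=dt.date(2020, 6, 1), event="refill")
        assert should_reappear(log, level1.rule_id, patient.patient_id, refill,
                               patient=patient, labs=[lab("Cr", 6.0, "mg/dl")],
                               kb=kb, as_of=AS_OF + dt.timedelta(days=30))

    def test_resolved_condition_does_not_reappear(self, kb):
        log = AuditLog()
        patient, alerts = _fire_one(kb, log)
        level1 = next(a for a in alerts if a.severity_level == 1)
        refill = rx("allopurinol", start=dt.date(2020, 6, 1), event="refill")
        # CrCl recovered to 90/1.0 = 90 ml/min: band no longer holds
        assert not should_reappear(log, level1.rule_id, patient.patient_id, refill,
                                   patient=patient,
                                   labs=[lab("Cr", 1.0, "mg/dl", days_ago=5)],
                                   kb=kb, as_of=AS_OF)

    def test_first_ever_prescription_fires_when_trigger_holds(self, kb):
        patient = make_patient()
        first = rx("allopurinol", event="new")
        assert should_reappear(AuditLog(), "allopurinol-renal-crcl-10-20",
                               patient.patient_id, first, patient=patient,
                               labs=[lab("Cr", 6.0, "mg/dl")], kb=kb, as_of=AS_OF)


class TestPregnancyExpiry:
    def test_active_at_eight_months(self):
        preg = pregnant_record(months_ago=0)
        as_of = add_months(preg.detected_date, 8)
        assert pregnancy_alert_active(preg, as_of)

    def test_expired_at_ten_months(self):
        preg = pregnant_record(months_ago=0)
        assert not pregnancy_alert_active(preg, add_months(preg.detected_date, 10))

    def test_boundary_exclusive_at_exactly_nine_months(self):
        preg = pregnant_record(months_ago=0)
        nine = add_months(preg.detected_date, 9)
        assert not pregnancy_alert_active(preg, nine)
        assert pregnancy_alert_active(preg, nine - dt.timedelta(seconds=1))

    def test_termination_yesterday_deactivates_today(self):
        preg = pregnant_record(months_ago=2, terminated_days_ago=1)
        assert not pregnancy_alert_active(preg, AS_OF)

    def test_expiry_silences_engine_pregnancy_rules(self, kb):
        patient = make_patient("female", pregnancy=pregnant_record(months_ago=10))
        alerts = evaluate(patient, [], [rx("mycophenolate")], kb, AS_OF)
        assert all(a.category != "pregnancy" for a in alerts)
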