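"""Alert lifecycle and the append-only audit trail.

Every rule firing and every clinician reaction is registered as an
immutable entry; the log is persisted as JSON Lines (one entry per line,
ISO-8601 timestamps) so histories stay greppable and diff-friendly.
Overriding an alert never suppresses it: as long as the trigger still
holds, the alert reappears with every subsequent prescription event,
including refills.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import uuid
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from ._dates import add_months, as_datetime
from .core_model import PregnancyRecord, Prescription


class Reaction(str, enum.Enum):
    none = "none"
    override = "override"  # the source workflow's "keep"
    stop_medication = "stop_medication"
    revise_medication = "revise_medication"
    order_lab = "order_lab"


@dataclass(frozen=True)
class AuditEntry:
    entry_id: str
    alert_id: str
    rule_id: str
    patient_id: str
    fired_at: dt.datetime
    reaction: Reaction = Reaction.none
    reacted_at: Optional[dt.datetime] = None
    actor: str = ""
    severity_level: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id, "alert_id": self.alert_id,
            "rule_id": self.rule_id, "patient_id": self.patient_id,
            "fired_at": self.fired_at.isoformat(),
            "reaction": self.reaction.value,
            "reacted_at": self.reacted_at.isoformat() if self.reacted_at else None,
            "actor": self.actor, "severity_level": self.severity_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AuditEntry":
        return cls(entry_id=d["entry_id"], alert_id=d["alert_id"],
                   rule_id=d["rule_id"], patient_id=d["patient_id"],
                   fired_at=dt.datetime.fromisoformat(d["fired_at"]),
                   reaction=Reaction(d.get("reaction", "none")),
                   reacted_at=(dt.datetime.fromisoformat(d["reacted_at"])
                               if d.get("reacted_at") else None),
                   actor=d.get("actor", ""),
                   severity_level=d.get("severity_level"))


class AuditLog:
    """Append-only in-memory log, optionally mirrored to a JSONL file."""

    def __init__(self, path: Optional[str | Path] = None):
        self._entries: list[AuditEntry] = []
        self._path = Path(path) if path is not None else None
        if self._path is not None and self._path.exists():
            for line in self._path.read_text(encoding="utf-8").splitlines():
                if line.strip():
                    self._entries.append(AuditEntry.from_dict(json.loads(line)))

    @property
    def entries(self) -> tuple[AuditEntry, ...]:
        return tuple(self._entries)

    def _append(self, entry: AuditEntry) -> AuditEntry:
        self._entries.append(entry)
        if self._path is not None:
            with self._path.open("a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry.to_dict()) + "\n")
        return entry

    def record_firing(self, alert, patient_id: Optional[str] = None) -> AuditEntry:
        """Register that an alert was shown (reaction still pending)."""
        pid = patient_id if patient_id is not None else alert.alert_id.split("|")[0]
        return self._append(AuditEntry(
            entry_id=uuid.uuid4().hex, alert_id=alert.alert_id,
            rule_id=alert.rule_id, patient_id=pid,
            fired_at=alert.evaluated_at, severity_level=alert.severity_level))

    def fired_alert_ids(self) -> set[str]:
        return {e.alert_id for e in self._entries if e.reaction is Reaction.none}

    def has_fired(self, alert_id: str) -> bool:
        return any(e.alert_id == alert_id for e in self._entries)


def record_reaction(log: AuditLog, alert, reaction: Reaction | str, actor: str,
                    at: dt.datetime) -> AuditEntry:
    """Append a clinician's reaction to a previously fired alert.

    Prior entries are never mutated.  Severity-1 alerts require a
    reaction before the prescription event can be marked complete
    (see :func:`prescription_event_complete`); lower severities may
    legitimately pass with ``reaction='none'``.
    """
    reaction = Reaction(reaction)
    if not log.has_fired(alert.alert_id):
        raise KeyError(f"alert {alert.alert_id!r} was never fired in this log")
    fired = next(e for e in log.entries if e.alert_id == alert.alert_id)
    if as_datetime(at) < fired.fired_at:
        raise ValueError(f"reaction at {at} precedes firing at {fired.fired_at}")
    return log._append(AuditEntry(
        entry_id=uuid.uuid4().hex, alert_id=alert.alert_id,
        rule_id=alert.rule_id, patient_id=fired.patient_id,
        fired_at=fired.fired_at, reaction=reaction,
        reacted_at=as_datetime(at), actor=actor,
        severity_level=alert.severity_level))


def prescription_event_complete(log: AuditLog, alerts) -> bool:
    """True when every severity-1 alert in the batch has a recorded reaction.

    Informational alerts (levels 2-3) never block completion.
    """
    reacted = {e.alert_id for e in log.entries if e.reaction is not Reaction.none}
    return all(a.alert_id in reacted for a in alerts if a.severity_level == 1)


def should_reappear(log: AuditLog, rule_id: str, patient_id: str,
                    new_event: Prescription, *, patient, labs, kb, as_of,
                    config=None) -> bool:
    """Does the rule fire again at a new prescription event?

    Prior overrides in the log are deliberately ignored — an override
    acknowledges one firing, it does not disable the rule.  The answer
    depends only on whether the trigger still holds at re-evaluation.
    """
    from .rule_engine import evaluate  # local import to avoid a cycle

    del log  # overrides never suppress future firings
    alerts = evaluate(patient, labs, [new_event], kb, as_of, config)
    return any(a.rule_id == rule_id for a in alerts)


def pregnancy_alert_active(preg: PregnancyRecord, as_of: dt.datetime | dt.date,
                           expiry_months: int = 9) -> bool:
    """Pregnancy-triggered alerts expire 9 calendar months after detection,
    or immediately once a termination is recorded (boundaries exclusive)."""
    t = as_datetime(as_of)
    if t >= add_months(preg.detected_date, expiry_months):
        return False
    if preg.termination_date is not None and t >= as_datetime(preg.termination_date):
        return False
    return True


def summarize(log: AuditLog) -> list[dict]:
    """Per-rule firing counts, reaction mix and override rate.

    Supports retrospective review of alert relevancy: a rule with a high
    override rate is a candidate for curation.
    """
    by_rule: dict[str, dict] = {}
    for e in log.entries:
        row = by_rule.setdefault(e.rule_id, {
            "rule_id": e.rule_id, "firings": 0,
            **{f"reaction_{r.value}": 0 for r in Reaction}})
        if e.reaction is Reaction.none:
            row["firings"] += 1
        else:
            row[f"reaction_{e.reaction.value}"] += 1
    out = []
    for rid in sorted(by_rule):
        row = by_rule[rid]
        reacted = sum(row[f"reaction_{r.value}"] for r in Reaction if r is not Reaction.none)
        row["override_rate"] = (row["reaction_override"] / reacted) if reacted else 0.0
        out.append(row)
    return out
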