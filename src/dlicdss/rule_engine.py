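"""Alert evaluation: match patient state + prescriptions against the KB.

The engine derives physiologic state as of an explicit instant (renal
clearance from the latest in-window serum creatinine, the hepatic tier,
pregnancy status, latest per-analyte lab values), evaluates every rule
attached to each actively prescribed medication, and renders one fully
formed alert per firing rule.

Display contract (alert-fatigue aware): only severity-1 alerts — those
that stop a medication or change its dose — are interruptive pop-ups;
severities 2 and 3 are informational visual cues.  Colors map 1/2/3 to
red/orange/yellow.  Alerts for one medication are grouped together and
ordering is fully deterministic: (medication, severity, rule_id).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from string import Formatter
from typing import Optional

from ._dates import add_months, as_datetime, within_window
from .config import EngineConfig
from .core_model import (CANONICAL_UNITS, LabResult, PatientRecord, Prescription, Sex)
from .knowledgebase import (Category, KnowledgeBase, LabCmp, LabMissing, Rule)
from .lifecycle_audit import pregnancy_alert_active
from .physiology import (HepaticState, RenalState, creatinine_clearance,
                         hepatic_state, latest_per_analyte, lean_body_mass)

SEVERITY_COLORS = {1: "red", 2: "orange", 3: "yellow"}


class EngineConfigurationError(Exception):
    """A KB rule references state the engine cannot derive."""


class RenderingError(Exception):
    """A message template placeholder had no bound value."""


@dataclass(frozen=True)
class Alert:
    alert_id: str
    rule_id: str
    medication: str  # display name
    medication_key: str
    category: str
    severity_level: int
    color: str
    display_mode: str  # "interruptive" | "informational"
    recommendation: str
    reason: str
    message: str
    evaluated_at: dt.datetime
    lab_analyte: Optional[str] = None
    lab_value: Optional[float] = None
    lab_unit: Optional[str] = None
    lab_date: Optional[str] = None  # ISO date

    def to_dict(self) -> dict:
        return {
            "alert_id": self.alert_id, "rule_id": self.rule_id,
            "medication": self.medication, "medication_key": self.medication_key,
            "category": self.category, "severity_level": self.severity_level,
            "color": self.color, "display_mode": self.display_mode,
            "recommendation": self.recommendation, "reason": self.reason,
            "message": self.message, "evaluated_at": self.evaluated_at.isoformat(),
            "lab_analyte": self.lab_analyte, "lab_value": self.lab_value,
            "lab_unit": self.lab_unit, "lab_date": self.lab_date,
        }


@dataclass
class EvalContext:
    """Derived patient state shared by every predicate evaluation."""

    patient: PatientRecord
    sex: Sex
    pregnant: bool
    renal: Optional[RenalState]
    hepatic: HepaticState
    latest: dict  # analyte -> latest in-window LabResult
    labs: list = field(default_factory=list)
    as_of: dt.datetime = dt.datetime(1970, 1, 1)
    window_months: int = 6

    def has_recent(self, analyte: str, months: int) -> bool:
        return any(lab.analyte == analyte
                   and within_window(lab.observed_at, self.as_of, months)
                   for lab in self.labs)


def classify_display(severity: int) -> str:
    """Severity 1 interrupts the prescribing workflow; 2 and 3 never do."""
    if severity == 1:
        return "interruptive"
    if severity in (2, 3):
        return "informational"
    raise ValueError(f"severity must be 1, 2 or 3, got {severity}")


def latest_lab(labs: list[LabResult], analyte: str, as_of: dt.datetime,
               window_months: int = 6) -> Optional[LabResult]:
    """Most recent result for ``analyte`` in (as_of - window, as_of]."""
    return latest_per_analyte(labs, as_of, window_months, {analyte}).get(analyte)


def _is_pregnant(patient: PatientRecord, latest: dict, as_of: dt.datetime,
                 config: EngineConfig) -> bool:
    if patient.pregnancy is not None and pregnancy_alert_active(
            patient.pregnancy, as_of, expiry_months=config.pregnancy_expiry_months):
        return True
    bhcg = latest.get("bHCG")
    if bhcg is not None:
        if bhcg.positive:
            return True
        if (config.bhcg_positive_threshold is not None
                and bhcg.value > config.bhcg_positive_threshold):
            return True
    return False


def build_context(patient: PatientRecord, labs: list[LabResult],
                  as_of: dt.datetime | dt.date,
                  config: Optional[EngineConfig] = None) -> EvalContext:
    config = config or EngineConfig()
    as_of = as_datetime(as_of)
    latest = latest_per_analyte(labs, as_of, config.lab_window_months)

    renal: Optional[RenalState] = None
    cr = latest.get("Cr")
    if cr is not None and cr.value > 0:
        weight = patient.weight
        if config.crcl_weight == "lbm" and patient.height is not None:
            weight = lean_body_mass(patient.sex, patient.weight, patient.height).lbm
        crcl = creatinine_clearance(
            patient.age(as_of), weight, patient.sex, cr.value,
            bsa_normalize=config.bsa_normalize, height=patient.height)
        renal = RenalState(crcl=crcl, serum_cr_used=cr.value,
                           cr_observed_at=cr.observed_at)

    hepatic = hepatic_state(
        labs, patient.cirrhosis_history, patient.child_pugh_inputs, as_of,
        window_months=config.lab_window_months,
        cirrhosis_implies_severe=config.cirrhosis_implies_severe,
        child_pugh_c_implies_severe=config.child_pugh_c_implies_severe)

    pregnant = _is_pregnant(patient, latest, as_of, config)
    return EvalContext(patient=patient, sex=patient.sex, pregnant=pregnant,
                       renal=renal, hepatic=hepatic, latest=latest, labs=labs,
                       as_of=as_of, window_months=config.lab_window_months)


def _check_rule_derivable(rule: Rule) -> None:
    for atom in rule.trigger.atoms():
        if isinstance(atom, (LabCmp, LabMissing)) and atom.analyte not in CANONICAL_UNITS:
            raise EngineConfigurationError(
                f"rule {rule.rule_id!r} references analyte {atom.analyte!r} "
                "which the engine cannot derive")


def _triggering_lab(rule: Rule, ctx: EvalContext) -> Optional[LabResult]:
    """The latest rule-associated lab result cited in the alert reason."""
    if rule.category is Category.renal:
        return ctx.latest.get("Cr")
    if rule.category is Category.hepatic:
        for criterion, _value, _desc in ctx.hepatic.evidence:
            lab = ctx.hepatic.latest_labs.get(criterion)
            if lab is not None:
                return lab
        return None
    if rule.category is Category.pregnancy:
        bhcg = ctx.latest.get("bHCG")
        # cite the lab only when the pregnancy evidence is lab-borne
        if bhcg is not None and bhcg.positive:
            return bhcg
        return None
    # monitoring: cite the freshest monitored analyte if any
    if rule.action.analytes:
        candidates = [ctx.latest[a] for a in rule.action.analytes if a in ctx.latest]
        if candidates:
            return max(candidates, key=lambda lab: lab.observed_at)
    return None


def _reason_text(rule: Rule, ctx: EvalContext, lab: Optional[LabResult]) -> str:
    if rule.category is Category.renal and ctx.renal is not None:
        return (f"CrCl {ctx.renal.crcl:.1f} ml/min from Cr "
                f"{ctx.renal.serum_cr_used:g} mg/dl on "
                f"{ctx.renal.cr_observed_at.date().isoformat()}")
    if rule.category is Category.hepatic:
        parts = []
        for criterion, value, desc in ctx.hepatic.evidence:
            found = ctx.hepatic.latest_labs.get(criterion)
            if found is not None:
                parts.append(f"{criterion} {found.value:g} {found.unit} "
                             f"({desc}) on {found.observed_at.date().isoformat()}")
            elif criterion == "cirrhosis_history":
                parts.append("documented cirrhotic liver disease")
            elif criterion == "child_pugh":
                parts.append(f"Child-Pugh score {value} ({desc})")
        return "; ".join(parts) if parts else "hepatic impairment on record"
    if rule.category is Category.pregnancy:
        if lab is not None:
            return (f"positive pregnancy test: bHCG {lab.value:g} {lab.unit} on "
                    f"{lab.observed_at.date().isoformat()}")
        preg = ctx.patient.pregnancy
        if preg is not None:
            return f"pregnancy recorded on {preg.detected_date.isoformat()}"
        return "pregnancy on record"
    # monitoring
    if lab is not None:
        return (f"latest {lab.analyte} {lab.value:g} {lab.unit} on "
                f"{lab.observed_at.date().isoformat()}")
    wanted = ", ".join(rule.action.analytes) or "the monitored test"
    return f"no recent {wanted} result on file; baseline measurement needed"


def render_alert_message(rule: Rule, patient: PatientRecord,
                         triggering_lab: Optional[LabResult],
                         action_text: str, *, medication_name: str,
                         reason: str) -> str:
    """Fill the rule's message template; unbound placeholders are an error."""
    values = {
        "medication": medication_name,
        "recommendation": action_text,
        "reason": reason,
        "lab_name": triggering_lab.analyte if triggering_lab else None,
        "lab_value": (f"{triggering_lab.value:g} {triggering_lab.unit}"
                      if triggering_lab else None),
        "lab_date": (triggering_lab.observed_at.date().isoformat()
                     if triggering_lab else None),
    }
    out = []
    for literal, field_name, fmt, conv in Formatter().parse(rule.message_template):
        out.append(literal)
        if field_name is None:
            continue
        if field_name not in values:
            raise RenderingError(
                f"rule {rule.rule_id!r}: unknown placeholder {{{field_name}}}")
        bound = values[field_name]
        if bound is None:
            raise RenderingError(
                f"rule {rule.rule_id!r}: placeholder {{{field_name}}} has no value "
                "for this patient")
        out.append(format(bound, fmt or ""))
    return "".join(out)


def _make_alert(rule: Rule, ctx: EvalContext, kb: KnowledgeBase,
                suffix: str = "", reason: Optional[str] = None) -> Alert:
    med = next(m for m in kb.medication_catalog if m.key == rule.medication)
    lab = _triggering_lab(rule, ctx)
    reason = reason if reason is not None else _reason_text(rule, ctx, lab)
    message = render_alert_message(rule, ctx.patient, lab, rule.action.text,
                                   medication_name=med.name, reason=reason)
    severity = rule.severity_level
    return Alert(
        alert_id=f"{ctx.patient.patient_id}|{rule.rule_id}|"
                 f"{ctx.as_of.date().isoformat()}{suffix}",
        rule_id=rule.rule_id, medication=med.name, medication_key=med.key,
        category=rule.category.value, severity_level=severity,
        color=SEVERITY_COLORS[severity], display_mode=classify_display(severity),
        recommendation=rule.action.text, reason=reason, message=message,
        evaluated_at=ctx.as_of,
        lab_analyte=lab.analyte if lab else None,
        lab_value=lab.value if lab else None,
        lab_unit=lab.unit if lab else None,
        lab_date=lab.observed_at.date().isoformat() if lab else None)


def _sorted(alerts: list[Alert]) -> list[Alert]:
    return sorted(alerts, key=lambda a: (a.medication, a.severity_level, a.rule_id))


def evaluate(patient: PatientRecord, labs: list[LabResult],
             prescriptions: list[Prescription], kb: KnowledgeBase,
             as_of: dt.datetime | dt.date,
             config: Optional[EngineConfig] = None) -> list[Alert]:
    """Evaluate every KB rule for every actively prescribed medication.

    Returns one alert per firing rule, deterministically ordered by
    (medication, severity ascending, rule_id).  Unknown medications are
    skipped silently; renal rules never fire without an in-window serum
    creatinine.
    """
    config = config or EngineConfig()
    ctx = build_context(patient, labs, as_of, config)
    known = kb.medications()
    active = sorted({rx.medication_id for rx in prescriptions} & known)
    alerts: list[Alert] = []
    for med_key in active:
        for rule in kb.rules_for(med_key):
            _check_rule_derivable(rule)
            if rule.trigger.evaluate(ctx):
                alerts.append(_make_alert(rule, ctx, kb))
    return _sorted(alerts)


def group_by_medication(alerts: list[Alert]) -> dict[str, list[Alert]]:
    """Single-screen grouping: all of one medication's alerts together."""
    grouped: dict[str, list[Alert]] = {}
    for alert in _sorted(alerts):
        grouped.setdefault(alert.medication, []).append(alert)
    return grouped


def _monitor_due(rule: Rule, ctx: EvalContext, start: dt.date) -> Optional[str]:
    """Why the rule's monitoring is due now, or None if all tests are fresh."""
    sched = rule.action.schedule
    if sched is None:
        return None
    start_dt = as_datetime(start)
    as_of = ctx.as_of
    for analyte in rule.action.analytes:
        lab = ctx.latest.get(analyte)
        latest_t = lab.observed_at if lab is not None else None
        if sched.baseline and (latest_t is None or latest_t < start_dt):
            return f"baseline {analyte} measurement needed"
        if sched.offset_days is not None:
            due_at = start_dt + dt.timedelta(days=sched.offset_days)
            if as_of >= due_at and (latest_t is None or latest_t < start_dt):
                return (f"initial {analyte} measurement due "
                        f"{sched.offset_days} days after the start")
        for phase in sched.phases:
            if phase.until_months is not None and as_of >= add_months(
                    start_dt, phase.until_months):
                continue  # a later phase governs now
            if phase.every_days is not None:
                cutoff = as_of - dt.timedelta(days=phase.every_days)
            else:
                cutoff = add_months(as_of, -(phase.every_months or 0))
            if cutoff <= start_dt:
                break  # first repeat interval has not elapsed yet
            if latest_t is None or latest_t <= cutoff:
                return f"repeat {analyte} measurement overdue"
            break  # only the currently governing phase applies
    return None


def missing_baseline_alerts(patient: PatientRecord, labs: list[LabResult],
                            prescriptions: list[Prescription], kb: KnowledgeBase,
                            as_of: dt.datetime | dt.date,
                            config: Optional[EngineConfig] = None) -> list[Alert]:
    """Level-3 prompts for monitoring tests that are missing or overdue.

    Due-date arithmetic follows each rule's schedule: a baseline draw is
    due from the prescription start, an initial draw after the stated
    offset, and repeats once the governing interval has elapsed since the
    latest in-window result.  Schedules anchor at the earliest
    prescription start for the medication.
    """
    config = config or EngineConfig()
    ctx = build_context(patient, labs, as_of, config)
    starts: dict[str, dt.date] = {}
    for rx in prescriptions:
        if rx.medication_id in kb.medications():
            prev = starts.get(rx.medication_id)
            if prev is None or rx.start_date < prev:
                starts[rx.medication_id] = rx.start_date
    alerts: list[Alert] = []
    for med_key in sorted(starts):
        for rule in kb.rules_for(med_key):
            if rule.action.kind != "monitor":
                continue
            if not rule.trigger.evaluate(ctx):
                continue
            why = _monitor_due(rule, ctx, starts[med_key])
            if why is not None:
                alerts.append(_make_alert(rule, ctx, kb, suffix="#due", reason=why))
    return _sorted(alerts)
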