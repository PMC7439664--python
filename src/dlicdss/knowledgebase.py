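"""Declarative drug-laboratory-interaction knowledge base.

A knowledge base is a flat list of IF/THEN rules.  Each rule binds one
medication to a trigger predicate (a boolean expression over derived
patient state: creatinine clearance, hepatic tier, pregnancy status,
individual lab comparisons), an action (what the clinician should do),
a category and a severity level.  Rules are data, not code: they load
from YAML/JSON, round-trip losslessly, and are validated structurally
before the engine will run them.

Severity convention (stored explicitly per rule so curators can
override): actions that stop a medication or change its dose
(avoid / discontinue / adjust_*) are level 1 — the only level rendered
interruptively; dose-initiation advice and cautions are level 2;
monitoring and supplementation reminders are level 3.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterator, Optional

import yaml

from .core_model import CANONICAL_UNITS, Finding, Sex
from .physiology import HepaticTier

KB_VERSION = "table1-v1"

#: Action kinds allowed to carry severity level 1 (interruptive display).
SEVERITY1_KINDS = {
    "avoid", "discontinue", "adjust_exact", "adjust_percent",
    "adjust_interval", "adjust_cap", "adjust_exact_table",
}

ACTION_KINDS = SEVERITY1_KINDS | {"initiate_dose", "caution", "monitor", "supplement"}


class Category(str, enum.Enum):
    renal = "renal"
    hepatic = "hepatic"
    pregnancy = "pregnancy"
    monitoring = "monitoring"


# --------------------------------------------------------------------------
# Predicates
# --------------------------------------------------------------------------

class Predicate:
    """Base of the boolean expression tree a rule trigger is made of."""

    def evaluate(self, ctx) -> bool:  # ctx: rule_engine.EvalContext
        raise NotImplementedError

    def atoms(self) -> Iterator["Predicate"]:
        yield self

    def to_dict(self) -> dict:
        raise NotImplementedError

    def __eq__(self, other):
        return type(self) is type(other) and self.to_dict() == other.to_dict()

    def __repr__(self):
        return f"{type(self).__name__}({self.to_dict()})"


@dataclass(repr=False, eq=False)
class Always(Predicate):
    """Unconditional trigger; used by monitoring rules that apply to
    everyone on the medication."""

    def evaluate(self, ctx) -> bool:
        return True

    def to_dict(self) -> dict:
        return {"atom": "always"}


@dataclass(repr=False, eq=False)
class CrClIn(Predicate):
    """Creatinine-clearance band, ml/min.  ``lo``/``hi`` bounds with
    explicit inclusivity; does not fire when no in-window serum Cr exists."""

    lo: float
    hi: Optional[float]  # None = unbounded above
    lo_inclusive: bool = True
    hi_inclusive: bool = False

    def evaluate(self, ctx) -> bool:
        if ctx.renal is None:
            return False
        v = ctx.renal.crcl
        if self.lo_inclusive:
            if v < self.lo:
                return False
        elif v <= self.lo:
            return False
        if self.hi is not None:
            if self.hi_inclusive:
                if v > self.hi:
                    return False
            elif v >= self.hi:
                return False
        return True

    def to_dict(self) -> dict:
        return {"atom": "crcl_in", "lo": self.lo, "hi": self.hi,
                "lo_inclusive": self.lo_inclusive, "hi_inclusive": self.hi_inclusive}


@dataclass(repr=False, eq=False)
class HepaticTierAtLeast(Predicate):
    tier: str  # "impaired" | "severe"

    def evaluate(self, ctx) -> bool:
        return ctx.hepatic.tier >= HepaticTier[self.tier]

    def to_dict(self) -> dict:
        return {"atom": "hepatic_tier_at_least", "tier": self.tier}


@dataclass(repr=False, eq=False)
class Pregnant(Predicate):
    def evaluate(self, ctx) -> bool:
        return ctx.pregnant

    def to_dict(self) -> dict:
        return {"atom": "pregnant"}


_OPS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


@dataclass(repr=False, eq=False)
class LabCmp(Predicate):
    """Compare the latest in-window value of one analyte to a threshold."""

    analyte: str
    op: str  # one of < <= > >=
    threshold: float
    unit: str

    def evaluate(self, ctx) -> bool:
        lab = ctx.latest.get(self.analyte)
        if lab is None:
            return False
        return _OPS[self.op](lab.value, self.threshold)

    def to_dict(self) -> dict:
        return {"atom": "lab_cmp", "analyte": self.analyte, "op": self.op,
                "threshold": self.threshold, "unit": self.unit}


@dataclass(repr=False, eq=False)
class SexIs(Predicate):
    sex: str

    def evaluate(self, ctx) -> bool:
        return ctx.sex is Sex(self.sex)

    def to_dict(self) -> dict:
        return {"atom": "sex_is", "sex": self.sex}


@dataclass(repr=False, eq=False)
class LabMissing(Predicate):
    analyte: str
    within_months: int

    def evaluate(self, ctx) -> bool:
        return not ctx.has_recent(self.analyte, self.within_months)

    def to_dict(self) -> dict:
        return {"atom": "lab_missing", "analyte": self.analyte,
                "within_months": self.within_months}


@dataclass(repr=False, eq=False)
class And(Predicate):
    children: list

    def evaluate(self, ctx) -> bool:
        return all(c.evaluate(ctx) for c in self.children)

    def atoms(self):
        for c in self.children:
            yield from c.atoms()

    def to_dict(self) -> dict:
        return {"all": [c.to_dict() for c in self.children]}


@dataclass(repr=False, eq=False)
class Or(Predicate):
    children: list

    def evaluate(self, ctx) -> bool:
        return any(c.evaluate(ctx) for c in self.children)

    def atoms(self):
        for c in self.children:
            yield from c.atoms()

    def to_dict(self) -> dict:
        return {"any": [c.to_dict() for c in self.children]}


@dataclass(repr=False, eq=False)
class Not(Predicate):
    child: Predicate

    def evaluate(self, ctx) -> bool:
        return not self.child.evaluate(ctx)

    def atoms(self):
        yield from self.child.atoms()

    def to_dict(self) -> dict:
        return {"not": self.child.to_dict()}


_ATOM_CLASSES = {
    "always": Always, "crcl_in": CrClIn, "hepatic_tier_at_least": HepaticTierAtLeast,
    "pregnant": Pregnant, "lab_cmp": LabCmp, "sex_is": SexIs, "lab_missing": LabMissing,
}


def predicate_from_dict(d: dict) -> Predicate:
    if "all" in d:
        return And([predicate_from_dict(c) for c in d["all"]])
    if "any" in d:
        return Or([predicate_from_dict(c) for c in d["any"]])
    if "not" in d:
        return Not(predicate_from_dict(d["not"]))
    kind = d.get("atom")
    cls = _ATOM_CLASSES.get(kind)
    if cls is None:
        raise KBLoadError([Finding("<predicate>", "known_atom", "error",
                                   f"unknown predicate atom {kind!r}")])
    kwargs = {k: v for k, v in d.items() if k != "atom"}
    return cls(**kwargs)


# --------------------------------------------------------------------------
# Actions and monitoring schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Phase:
    """One repeat-interval phase of a monitoring schedule; exactly one of
    ``every_days``/``every_months`` is set.  ``until_months`` bounds the
    phase relative to the prescription start (None = open-ended)."""

    every_days: Optional[int] = None
    every_months: Optional[int] = None
    until_months: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in
                (("every_days", self.every_days), ("every_months", self.every_months),
                 ("until_months", self.until_months)) if v is not None}


@dataclass(frozen=True)
class MonitorSchedule:
    baseline: bool = False
    offset_days: Optional[int] = None  # first draw, days after the start
    phases: tuple = ()

    def to_dict(self) -> dict:
        d: dict = {"baseline": self.baseline}
        if self.offset_days is not None:
            d["offset_days"] = self.offset_days
        if self.phases:
            d["phases"] = [p.to_dict() for p in self.phases]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MonitorSchedule":
        return cls(baseline=bool(d.get("baseline", False)),
                   offset_days=d.get("offset_days"),
                   phases=tuple(Phase(**p) for p in d.get("phases", [])))


@dataclass(frozen=True)
class Action:
    """What the alert tells the clinician to do.

    ``text`` carries the recommendation exactly as curated (numerals kept
    as printed in the source reference); structured parameters allow
    downstream tooling to act on the recommendation programmatically.
    """

    kind: str
    text: str
    percent: Optional[float] = None  # adjust_percent
    analytes: tuple = ()  # monitor
    schedule: Optional[MonitorSchedule] = None  # monitor
    supplement: Optional[str] = None  # supplement

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "text": self.text}
        if self.percent is not None:
            d["percent"] = self.percent
        if self.analytes:
            d["analytes"] = list(self.analytes)
        if self.schedule is not None:
            d["schedule"] = self.schedule.to_dict()
        if self.supplement is not None:
            d["supplement"] = self.supplement
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Action":
        return cls(kind=d["kind"], text=d["text"], percent=d.get("percent"),
                   analytes=tuple(d.get("analytes", ())),
                   schedule=MonitorSchedule.from_dict(d["schedule"]) if "schedule" in d else None,
                   supplement=d.get("supplement"))


# --------------------------------------------------------------------------
# Rules and the knowledge base container
# --------------------------------------------------------------------------

DEFAULT_TEMPLATE = "{medication}: {recommendation} — {reason}"


@dataclass(frozen=True)
class Medication:
    key: str
    atc_code: str
    atc_category: str
    name: str

    def to_dict(self) -> dict:
        return {"key": self.key, "atc_code": self.atc_code,
                "atc_category": self.atc_category, "name": self.name}


@dataclass(frozen=True)
class Rule:
    rule_id: str
    medication: str  # Medication.key
    category: Category
    trigger: Predicate
    action: Action
    severity_level: int
    message_template: str = DEFAULT_TEMPLATE

    def to_dict(self) -> dict:
        return {"rule_id": self.rule_id, "medication": self.medication,
                "category": self.category.value, "trigger": self.trigger.to_dict(),
                "action": self.action.to_dict(), "severity_level": self.severity_level,
                "message_template": self.message_template}

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(rule_id=d["rule_id"], medication=d["medication"],
                   category=Category(d["category"]),
                   trigger=predicate_from_dict(d["trigger"]),
                   action=Action.from_dict(d["action"]),
                   severity_level=int(d["severity_level"]),
                   message_template=d.get("message_template", DEFAULT_TEMPLATE))


@dataclass
class KnowledgeBase:
    kb_version: str
    medication_catalog: list = dc_field(default_factory=list)
    rules: list = dc_field(default_factory=list)

    def medications(self) -> set[str]:
        return {m.key for m in self.medication_catalog}

    def rules_for(self, medication_key: str) -> list:
        return [r for r in self.rules if r.medication == medication_key]

    def rule(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def to_dict(self) -> dict:
        return {"kb_version": self.kb_version,
                "medication_catalog": [m.to_dict() for m in self.medication_catalog],
                "rules": [r.to_dict() for r in self.rules]}

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgeBase":
        return cls(kb_version=str(d.get("kb_version", "unversioned")),
                   medication_catalog=[Medication(**m) for m in d.get("medication_catalog", [])],
                   rules=[Rule.from_dict(r) for r in d.get("rules", [])])


class KBLoadError(Exception):
    """Raised when a knowledge-base file violates the schema; carries every
    finding so a curator sees all problems at once."""

    def __init__(self, findings: list[Finding]):
        self.findings = findings
        super().__init__("; ".join(f"{f.record}: {f.message}" for f in findings))


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and fully validate a YAML (or JSON) knowledge-base file.

    Loading is total: any invariant violation raises :class:`KBLoadError`
    naming the offending rule and field — nothing is silently dropped.
    """
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:
        raise KBLoadError([Finding(str(path), "parse", "error", str(exc))]) from exc
    if not isinstance(data, dict):
        raise KBLoadError([Finding(str(path), "schema", "error",
                                   "top level must be a mapping")])
    try:
        kb = KnowledgeBase.from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise KBLoadError([Finding(str(path), "schema", "error",
                                   f"malformed rule or medication entry: {exc}")]) from exc
    findings = [f for f in validate_kb(kb) if f.is_error]
    if findings:
        raise KBLoadError(findings)
    return kb


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(kb.to_dict(), sort_keys=False, allow_unicode=True),
        encoding="utf-8")


def _crcl_bands(rule: Rule) -> list[CrClIn]:
    return [a for a in rule.trigger.atoms() if isinstance(a, CrClIn)]


def _bands_overlap(a: CrClIn, b: CrClIn) -> bool:
    a_lo, a_hi = a.lo, a.hi if a.hi is not None else float("inf")
    b_lo, b_hi = b.lo, b.hi if b.hi is not None else float("inf")
    lo = max(a_lo, b_lo)
    hi = min(a_hi, b_hi)
    if lo < hi:
        return True
    if lo == hi:
        # touching bounds only collide if both sides include the point
        at_lo_inc = (a.lo_inclusive if lo == a_lo else a.hi_inclusive)
        bt_lo_inc = (b.lo_inclusive if lo == b_lo else b.hi_inclusive)
        return at_lo_inc and bt_lo_inc
    return False


def validate_kb(kb: KnowledgeBase) -> list[Finding]:
    """Re-check all structural invariants of an in-memory knowledge base."""
    findings: list[Finding] = []
    known_meds = kb.medications()
    seen_ids: set[str] = set()
    for rule in kb.rules:
        rid = rule.rule_id
        if rid in seen_ids:
            findings.append(Finding(rid, "unique_rule_id", "error",
                                    f"duplicate rule_id {rid!r}"))
        seen_ids.add(rid)
        if rule.medication not in known_meds:
            findings.append(Finding(rid, "known_medication", "error",
                                    f"medication {rule.medication!r} not in catalog"))
        if rule.severity_level not in (1, 2, 3):
            findings.append(Finding(rid, "severity_range", "error",
                                    f"severity_level {rule.severity_level} not in 1..3"))
        if rule.severity_level == 1 and rule.action.kind not in SEVERITY1_KINDS:
            findings.append(Finding(rid, "severity1_action_kind", "error",
                                    f"severity 1 not permitted for action kind {rule.action.kind!r}"))
        if rule.action.kind not in ACTION_KINDS:
            findings.append(Finding(rid, "known_action_kind", "error",
                                    f"unknown action kind {rule.action.kind!r}"))
        if rule.action.percent is not None and not (0 < rule.action.percent < 100):
            findings.append(Finding(rid, "percent_range", "error",
                                    f"percent {rule.action.percent} outside (0, 100)"))
        if rule.action.kind == "monitor":
            sched = rule.action.schedule
            if not rule.action.analytes:
                findings.append(Finding(rid, "monitor_analytes", "error",
                                        "monitor action lists no analytes"))
            if sched is None or (not sched.baseline and not sched.phases
                                 and sched.offset_days is None):
                findings.append(Finding(rid, "monitor_schedule", "error",
                                        "monitor schedule needs baseline, offset or repeat phase"))
        for atom in rule.trigger.atoms():
            if isinstance(atom, CrClIn):
                hi = atom.hi if atom.hi is not None else float("inf")
                if not (0 <= atom.lo < hi):
                    findings.append(Finding(rid, "band_well_formed", "error",
                                            f"CrCl band [{atom.lo}, {atom.hi}) ill-formed"))
            if isinstance(atom, LabCmp):
                if atom.threshold <= 0:
                    findings.append(Finding(rid, "threshold_positive", "error",
                                            f"threshold {atom.threshold} must be positive"))
                if atom.analyte not in CANONICAL_UNITS:
                    findings.append(Finding(rid, "derivable_analyte", "error",
                                            f"analyte {atom.analyte!r} is not derivable by the engine"))
            if isinstance(atom, LabMissing) and atom.analyte not in CANONICAL_UNITS:
                findings.append(Finding(rid, "derivable_analyte", "error",
                                        f"analyte {atom.analyte!r} is not derivable by the engine"))

    # Renal CrCl bands must be pairwise disjoint per medication.
    by_med: dict[str, list[tuple[str, CrClIn]]] = {}
    for rule in kb.rules:
        if rule.category is Category.renal:
            for band in _crcl_bands(rule):
                by_med.setdefault(rule.medication, []).append((rule.rule_id, band))
    for med, bands in by_med.items():
        for i in range(len(bands)):
            for j in range(i + 1, len(bands)):
                if _bands_overlap(bands[i][1], bands[j][1]):
                    findings.append(Finding(
                        f"{bands[i][0]}+{bands[j][0]}", "renal_bands_disjoint", "error",
                        f"overlapping renal CrCl bands for {med}: "
                        f"{bands[i][0]} and {bands[j][0]}"))
    return findings


def band_coverage(kb: KnowledgeBase, medication: str) -> list[dict]:
    """Report how a medication's renal bands tile (0, inf).

    Returns ordered segments, each with lo/hi and the covering rule_id or
    None for the implicit no-action region.  Useful for curation review.
    """
    bands: list[tuple[str, CrClIn]] = []
    for rule in kb.rules_for(medication):
        if rule.category is Category.renal:
            for band in _crcl_bands(rule):
                bands.append((rule.rule_id, band))
    bands.sort(key=lambda t: t[1].lo)
    segments: list[dict] = []
    cursor = 0.0
    for rid, band in bands:
        if band.lo > cursor:
            segments.append({"lo": cursor, "hi": band.lo, "rule_id": None})
        hi = band.hi if band.hi is not None else float("inf")
        segments.append({"lo": band.lo, "hi": hi, "rule_id": rid})
        cursor = hi
    if cursor != float("inf"):
        segments.append({"lo": cursor, "hi": float("inf"), "rule_id": None})
    return segments


# --------------------------------------------------------------------------
# Seeded knowledge base: the eight high-volume kidney-transplant medications
# --------------------------------------------------------------------------

def _monitor(analytes: list[str], text: str, schedule: MonitorSchedule,
             trigger: Predicate, rule_id: str, med: str,
             category: Category = Category.monitoring) -> Rule:
    return Rule(rule_id=rule_id, medication=med, category=category,
                trigger=trigger, action=Action(kind="monitor", text=text,
                                               analytes=tuple(analytes),
                                               schedule=schedule),
                severity_level=3)


def seeded_kb() -> KnowledgeBase:
    """The curated knowledge base for the eight seeded medications.

    Every recommendation string keeps the reference numerals verbatim.
    CrCl thresholds are in ml/min; liver thresholds in U/L and mg/dl.
    Where a repeat interval is stated only as "periodically", a 6-month
    default is used (a curation choice, overridable in the KB file).
    """
    catalog = [
        Medication("allopurinol", "M04", "ANTIGOUT PREPARATIONS", "Allopurinol"),
        Medication("azathioprine", "L04", "IMMUNOSUPPRESSANTS", "Azathioprine"),
        Medication("captopril", "C09", "AGENTS ACTING ON THE RENIN-ANGIOTENSIN SYSTEM",
                   "Captopril"),
        Medication("cyclosporine", "L04", "IMMUNOSUPPRESSANTS", "Cyclosporine"),
        Medication("hydrochlorothiazide", "C03", "DIURETICS", "Hydrochlorothiazide"),
        Medication("losartan", "C09", "AGENTS ACTING ON THE RENIN-ANGIOTENSIN SYSTEM",
                   "Losartan"),
        Medication("mycophenolate", "L04", "IMMUNOSUPPRESSANTS",
                   "Mycophenolate (mycophenolic acid)"),
        Medication("omeprazole", "A02", "DRUGS FOR ACID RELATED DISORDERS", "Omeprazole"),
    ]

    six_monthly = MonitorSchedule(baseline=False, phases=(Phase(every_months=6),))
    baseline_two_weeks = MonitorSchedule(baseline=True, offset_days=14)

    rules: list[Rule] = [
        # -- Allopurinol ----------------------------------------------------
        Rule("allopurinol-renal-crcl-10-20", "allopurinol", Category.renal,
             CrClIn(10, 20, True, False),
             Action("adjust_exact", "prescribe 200 mg/day per oral"), 1),
        Rule("allopurinol-renal-crcl-3-10", "allopurinol", Category.renal,
             CrClIn(3, 10, True, False),
             Action("adjust_exact", "prescribe 100 mg/day per oral"), 1),
        Rule("allopurinol-renal-crcl-lt-3", "allopurinol", Category.renal,
             CrClIn(0, 3, False, False),
             Action("adjust_interval",
                    "prescribe 100 mg per oral every 24 h or longer; "
                    "or 100 mg per oral every third day"), 1),
        Rule("allopurinol-hepatic-caution", "allopurinol", Category.hepatic,
             HepaticTierAtLeast("impaired"),
             Action("caution", "Dosage adjustment may be necessary; "
                               "No specific recommendations available"), 2),
        _monitor(["UricAcid"],
                 "Monitor Uric acid level: if normal, check it every 6 months; "
                 "if abnormal, change Allopurinol dose accordingly",
                 six_monthly, Always(), "allopurinol-monitor-uric-acid", "allopurinol"),

        # -- Azathioprine ---------------------------------------------------
        # Qualitative renal caution: the source gives no numeric band, only
        # "if renal impairment or oliguria exists"; CrCl < 60 ml/min is the
        # curated operationalisation of renal impairment.
        Rule("azathioprine-renal-caution", "azathioprine", Category.renal,
             CrClIn(0, 60, False, False),
             Action("caution",
                    "dosage should be modified depending on clinical response and "
                    "degree of renal impairment. No quantitative recommendations "
                    "are available"), 2),
        Rule("azathioprine-pregnancy-discontinue", "azathioprine", Category.pregnancy,
             Pregnant(), Action("discontinue", "Discontinue"), 1),

        # -- Captopril ------------------------------------------------------
        Rule("captopril-renal-crcl-10-50", "captopril", Category.renal,
             CrClIn(10, 50, True, False),
             Action("adjust_percent", "reduce the recommended dose by 25%",
                    percent=25), 1),
        Rule("captopril-renal-crcl-lt-10", "captopril", Category.renal,
             CrClIn(0, 10, False, False),
             Action("adjust_percent", "reduce the recommended dose by 50%",
                    percent=50), 1),
        Rule("captopril-pregnancy-discontinue", "captopril", Category.pregnancy,
             Pregnant(), Action("discontinue", "Discontinue"), 1),
        _monitor(["Na", "K"],
                 "Monitor Na and K at the baseline and 1–2 weeks after the start",
                 baseline_two_weeks, Always(), "captopril-monitor-na-k", "captopril"),

        # -- Cyclosporine ---------------------------------------------------
        _monitor(["CyclosporineLevel"],
                 "monitor Cyclosporine blood concentration level. May require "
                 "dose reduction based on concentration",
                 MonitorSchedule(baseline=True),
                 HepaticTierAtLeast("impaired"),
                 "cyclosporine-hepatic-monitor-level", "cyclosporine",
                 category=Category.hepatic),
        _monitor(["UricAcid", "K", "Mg"],
                 "Monitor Uric acid, K, and Mg levels every 2 weeks in the "
                 "first 3 months then monthly",
                 MonitorSchedule(baseline=False,
                                 phases=(Phase(every_days=14, until_months=3),
                                         Phase(every_months=1))),
                 Always(), "cyclosporine-monitor-uric-acid-k-mg", "cyclosporine"),

        # -- Hydrochlorothiazide --------------------------------------------
        Rule("hydrochlorothiazide-renal-crcl-lt-30", "hydrochlorothiazide",
             Category.renal, CrClIn(0, 30, False, False),
             Action("avoid", "do not use"), 1),
        Rule("hydrochlorothiazide-hepatic-caution", "hydrochlorothiazide",
             Category.hepatic, HepaticTierAtLeast("impaired"),
             Action("caution", "use with caution, since minor alteration of fluid "
                               "and electrolyte balance may precipitate hepatic coma"), 2),
        _monitor(["K", "Na", "Cl"], "Monitor K, Na and Cl",
                 MonitorSchedule(baseline=True, phases=(Phase(every_months=6),)),
                 Always(), "hydrochlorothiazide-monitor-k-na-cl", "hydrochlorothiazide"),

        # -- Losartan -------------------------------------------------------
        # No structured volume-status field exists; the volume-depletion
        # condition is carried in the message text on the CrCl trigger.
        Rule("losartan-renal-crcl-lt-30", "losartan", Category.renal,
             CrClIn(0, 30, False, False),
             Action("caution", "If the patient is also volume-depleted, "
                               "dose adjustment will be needed"), 2),
        Rule("losartan-hepatic-initiate-25", "losartan", Category.hepatic,
             HepaticTierAtLeast("impaired"),
             Action("initiate_dose", "initiate with 25 mg per oral once daily"), 2),
        Rule("losartan-pregnancy-discontinue", "losartan", Category.pregnancy,
             Pregnant(), Action("discontinue", "Discontinue"), 1),
        _monitor(["Na", "K"],
                 "Monitor Na and K at the baseline and 1–2 weeks after the start",
                 baseline_two_weeks, Always(), "losartan-monitor-na-k", "losartan"),

        # -- Mycophenolate --------------------------------------------------
        Rule("mycophenolate-renal-crcl-lt-25", "mycophenolate", Category.renal,
             CrClIn(0, 25, False, False),
             Action("adjust_cap", "do not exceed 1 g per oral twice daily"), 1),
        Rule("mycophenolate-pregnancy-discontinue", "mycophenolate", Category.pregnancy,
             Pregnant(), Action("discontinue", "Discontinue"), 1),
        _monitor(["bHCG"],
                 "Monitor pregnancy test (βHCG) 8 to 10 days after the initiation "
                 "and then every 3 months afterward",
                 MonitorSchedule(baseline=False, offset_days=10,
                                 phases=(Phase(every_months=3),)),
                 SexIs("female"), "mycophenolate-monitor-bhcg", "mycophenolate"),

        # -- Omeprazole -----------------------------------------------------
        Rule("omeprazole-hepatic-severe-reduce", "omeprazole", Category.hepatic,
             HepaticTierAtLeast("severe"),
             Action("adjust_exact", "reduce Omeprazole dose to 10 mg once daily "
                                    "receiving for long-term therapy"), 1),
        _monitor(["Mg", "VitB12"], "Monitor Mg and Vit B12 levels periodically",
                 six_monthly, Always(), "omeprazole-monitor-mg-vitb12", "omeprazole"),
    ]
    return KnowledgeBase(kb_version=KB_VERSION, medication_catalog=catalog, rules=rules)
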