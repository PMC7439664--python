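"""Domain types for drug-laboratory interaction (DLI) screening.

A DLI is a medication-safety hazard that arises when a prescription
ignores laboratory evidence: the wrong drug for the patient's organ
function, the wrong dose, or a missing lab-monitoring step.  These types
model everything the rule engine consumes: the patient, their
time-stamped lab results, and the active prescription list.

Validation is deliberately split in two layers.  Pydantic enforces
shape (field types, ISO-8601 dates, enum membership) at construction;
clinical invariants (pregnancy on a male record, negative lab values,
paediatric ages) are reported as *findings* by :func:`validate_record`
so that ingestion never hard-crashes on a malformed patient and every
problem in a bundle is reported at once.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass
from typing import Optional

from pydantic import BaseModel, ConfigDict

from ._dates import age_years, as_datetime


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Ascites(str, enum.Enum):
    none = "none"
    mild = "mild"
    moderate_severe = "moderate_severe"


class Encephalopathy(str, enum.Enum):
    none = "none"
    grade1_2 = "grade1_2"
    grade3_4 = "grade3_4"


class PrescriptionEvent(str, enum.Enum):
    new = "new"
    refill = "refill"
    revision = "revision"


#: Canonical reporting unit per known analyte.  ALT is occasionally
#: printed as "U/mL" in drug references; clinically it is the same
#: number reported per litre, so both spellings normalise to U/L.
CANONICAL_UNITS: dict[str, str] = {
    "Cr": "mg/dl",
    "AST": "U/L",
    "ALT": "U/L",
    "Bili_total": "mg/dl",
    "Na": "mEq/L",
    "K": "mEq/L",
    "Mg": "mg/dl",
    "Cl": "mEq/L",
    "UricAcid": "mg/dl",
    "VitB12": "pg/mL",
    "bHCG": "mIU/mL",
    "CyclosporineLevel": "ng/mL",
}

_UNIT_ALIASES = {"u/ml": "U/L", "u/l": "U/L", "meq/l": "mEq/L", "mg/dl": "mg/dl",
                 "pg/ml": "pg/mL", "miu/ml": "mIU/mL", "ng/ml": "ng/mL"}


def normalize_unit(unit: str) -> str:
    return _UNIT_ALIASES.get(unit.strip().lower(), unit.strip())


class PregnancyRecord(BaseModel):
    """Positive pregnancy evidence, optionally closed by a termination date."""

    model_config = ConfigDict(frozen=True)

    detected_date: dt.date
    termination_date: Optional[dt.date] = None


class ChildPughInputs(BaseModel):
    """The five Child-Pugh parameters (liver-disease severity scoring)."""

    model_config = ConfigDict(frozen=True)

    bilirubin_total: float  # mg/dl
    albumin: float  # g/dl
    inr: float
    ascites: Ascites
    encephalopathy: Encephalopathy


class PatientRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    sex: Sex
    birth_date: dt.date
    weight: float  # kg
    height: Optional[float] = None  # cm
    pregnancy: Optional[PregnancyRecord] = None
    cirrhosis_history: bool = False
    child_pugh_inputs: Optional[ChildPughInputs] = None

    def age(self, as_of: dt.date | dt.datetime) -> float:
        return age_years(self.birth_date, as_of)


class LabResult(BaseModel):
    """One analyte measurement in its canonical unit.

    ``positive`` carries a qualitative positive/negative flag for tests
    such as the beta-HCG pregnancy test, independent of the numeric value.
    """

    model_config = ConfigDict(frozen=True)

    analyte: str
    value: float
    unit: str
    observed_at: dt.datetime
    positive: Optional[bool] = None

    @property
    def observed_date(self) -> dt.date:
        return self.observed_at.date()


class Prescription(BaseModel):
    model_config = ConfigDict(frozen=True)

    medication_id: str  # catalog key, e.g. "allopurinol"
    medication_name: str = ""
    atc_code: str = ""
    dose: Optional[str] = None
    frequency: Optional[str] = None
    start_date: dt.date = dt.date(1970, 1, 1)
    event_kind: PrescriptionEvent = PrescriptionEvent.new


@dataclass(frozen=True)
class Finding:
    """One validation problem: which record, which invariant, how bad."""

    record: str
    invariant: str
    severity: str  # "error" | "warning"
    message: str

    @property
    def is_error(self) -> bool:
        return self.severity == "error"


def validate_record(
    patient: PatientRecord,
    labs: list[LabResult],
    prescriptions: list[Prescription],
    as_of: dt.date | dt.datetime,
    known_medications: Optional[set[str]] = None,
) -> list[Finding]:
    """Check all clinical invariants; return findings instead of raising.

    An empty list means the bundle is safe to evaluate.  Warnings (unknown
    analytes or medications) do not block evaluation — the knowledge base
    can grow without breaking ingestion.
    """
    findings: list[Finding] = []
    pid = patient.patient_id

    def err(invariant: str, message: str) -> None:
        findings.append(Finding(pid, invariant, "error", message))

    def warn(invariant: str, message: str) -> None:
        findings.append(Finding(pid, invariant, "warning", message))

    if patient.weight <= 0:
        err("weight_positive", f"weight must be > 0 kg, got {patient.weight}")
    if patient.height is not None and not (100 <= patient.height <= 250):
        err("height_range", f"height must be in [100, 250] cm, got {patient.height}")
    if patient.age(as_of) < 18:
        err("adult_scope", f"patient age {patient.age(as_of):.1f} < 18 at {as_of}; "
            "engine covers adult outpatients only")
    if patient.pregnancy is not None and patient.sex is not Sex.female:
        err("pregnancy_requires_female",
            "pregnancy record present on a non-female patient")
    if patient.pregnancy is not None:
        preg = patient.pregnancy
        if preg.termination_date is not None and preg.termination_date < preg.detected_date:
            err("pregnancy_dates_ordered",
                f"termination {preg.termination_date} precedes detection {preg.detected_date}")
    cp = patient.child_pugh_inputs
    if cp is not None:
        for field in ("bilirubin_total", "albumin", "inr"):
            if getattr(cp, field) <= 0:
                err("child_pugh_positive", f"Child-Pugh input {field} must be positive")

    for i, lab in enumerate(labs):
        label = f"{pid}/lab[{i}]:{lab.analyte}"
        if lab.value < 0:
            findings.append(Finding(label, "lab_value_nonnegative", "error",
                                    f"lab value {lab.value} < 0"))
        canonical = CANONICAL_UNITS.get(lab.analyte)
        if canonical is None:
            findings.append(Finding(label, "known_analyte", "warning",
                                    f"analyte {lab.analyte!r} is not in the canonical registry"))
        elif normalize_unit(lab.unit) != canonical:
            findings.append(Finding(label, "canonical_unit", "error",
                                    f"unit {lab.unit!r} does not normalise to {canonical!r}"))
        if as_datetime(lab.observed_at) > as_datetime(as_of):
            findings.append(Finding(label, "observed_not_future", "warning",
                                    f"lab observed at {lab.observed_at} is after as-of {as_of}"))

    for i, rx in enumerate(prescriptions):
        label = f"{pid}/prescription[{i}]:{rx.medication_id}"
        if known_medications is not None and rx.medication_id not in known_medications:
            findings.append(Finding(label, "known_medication", "warning",
                                    f"medication {rx.medication_id!r} not in the knowledge base; "
                                    "it is legal but generates no alerts"))
    return findings
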