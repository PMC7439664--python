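"""Independent brute-force re-evaluation of the seeded rules.

This module answers one question — "which seeded rules should fire for
this patient bundle?" — by re-deriving everything from scratch with the
thresholds written inline, straight from the curated drug references.
It deliberately does NOT import the knowledge-base predicate classes or
the rule engine: it is the second, hand-written route used to verify the
engine on boundary-crossing fixtures, so any disagreement between the
two implicates one of them.  Only calendar utilities are shared, so both
routes use identical month/window semantics by definition.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

from ._dates import add_months, age_years, as_datetime
from .core_model import LabResult, PatientRecord, Prescription


def _latest(labs: list[LabResult], analyte: str, as_of: dt.datetime,
            window_months: int) -> Optional[LabResult]:
    start = add_months(as_of, -window_months)
    best: Optional[LabResult] = None
    for lab in labs:
        if lab.analyte != analyte:
            continue
        if not (start < as_datetime(lab.observed_at) <= as_of):
            continue
        if best is None or lab.observed_at > best.observed_at:
            best = lab
    return best


def _crcl(patient: PatientRecord, cr: float, as_of: dt.datetime) -> float:
    # Cockcroft-Gault, written out independently of the physiology module
    # but with the identical operation order so floats agree bit-for-bit.
    age = age_years(patient.birth_date, as_of)
    crcl = (140.0 - age) * patient.weight / (72.0 * cr)
    if patient.sex.value == "female":
        crcl *= 0.85
    return crcl


def _child_pugh_class(cp) -> Optional[str]:
    if cp is None:
        return None
    pts = 0
    pts += 1 if cp.bilirubin_total < 2 else (2 if cp.bilirubin_total <= 3 else 3)
    pts += 1 if cp.albumin > 3.5 else (2 if cp.albumin >= 2.8 else 3)
    pts += 1 if cp.inr < 1.7 else (2 if cp.inr <= 2.3 else 3)
    pts += {"none": 1, "mild": 2, "moderate_severe": 3}[cp.ascites.value]
    pts += {"none": 1, "grade1_2": 2, "grade3_4": 3}[cp.encephalopathy.value]
    return "A" if pts <= 6 else ("B" if pts <= 9 else "C")


def expected_rule_ids(patient: PatientRecord, labs: list[LabResult],
                      prescriptions: list[Prescription],
                      as_of: dt.datetime | dt.date,
                      window_months: int = 6,
                      pregnancy_expiry_months: int = 9) -> frozenset[str]:
    """Rule ids of every seeded rule that should fire for this bundle."""
    as_of = as_datetime(as_of)
    meds = {rx.medication_id for rx in prescriptions}
    fired: set[str] = set()

    # ---- derived state, re-computed from first principles ----------------
    cr_lab = _latest(labs, "Cr", as_of, window_months)
    crcl = _crcl(patient, cr_lab.value, as_of) if cr_lab and cr_lab.value > 0 else None

    alt = _latest(labs, "ALT", as_of, window_months)
    ast = _latest(labs, "AST", as_of, window_months)
    bili = _latest(labs, "Bili_total", as_of, window_months)
    severe = ((ast is not None and ast.value > 120.0)
              or (alt is not None and alt.value > 120.0)
              or (bili is not None and bili.value > 3.0)
              or patient.cirrhosis_history
              or _child_pugh_class(patient.child_pugh_inputs) == "C")
    impaired_or_worse = severe or ((alt is not None and alt.value > 40.0)
                                   or (ast is not None and ast.value > 40.0)
                                   or (bili is not None and bili.value > 1.5))

    pregnant = False
    if patient.pregnancy is not None:
        preg = patient.pregnancy
        active = as_of < add_months(preg.detected_date, pregnancy_expiry_months)
        if preg.termination_date is not None and as_of >= as_datetime(preg.termination_date):
            active = False
        pregnant = active
    bhcg = _latest(labs, "bHCG", as_of, window_months)
    if bhcg is not None and bhcg.positive:
        pregnant = True

    female = patient.sex.value == "female"

    # ---- one block per medication, thresholds inline ---------------------
    if "allopurinol" in meds:
        if crcl is not None:
            if 10.0 <= crcl < 20.0:
                fired.add("allopurinol-renal-crcl-10-20")
            if 3.0 <= crcl < 10.0:
                fired.add("allopurinol-renal-crcl-3-10")
            if 0.0 < crcl < 3.0:
                fired.add("allopurinol-renal-crcl-lt-3")
        if impaired_or_worse:
            fired.add("allopurinol-hepatic-caution")
        fired.add("allopurinol-monitor-uric-acid")

    if "azathioprine" in meds:
        if crcl is not None and 0.0 < crcl < 60.0:
            fired.add("azathioprine-renal-caution")
        if pregnant:
            fired.add("azathioprine-pregnancy-discontinue")

    if "captopril" in meds:
        if crcl is not None:
            if 10.0 <= crcl < 50.0:
                fired.add("captopril-renal-crcl-10-50")
            if 0.0 < crcl < 10.0:
                fired.add("captopril-renal-crcl-lt-10")
        if pregnant:
            fired.add("captopril-pregnancy-discontinue")
        fired.add("captopril-monitor-na-k")

    if "cyclosporine" in meds:
        if impaired_or_worse:
            fired.add("cyclosporine-hepatic-monitor-level")
        fired.add("cyclosporine-monitor-uric-acid-k-mg")

    if "hydrochlorothiazide" in meds:
        if crcl is not None and 0.0 < crcl < 30.0:
            fired.add("hydrochlorothiazide-renal-crcl-lt-30")
        if impaired_or_worse:
            fired.add("hydrochlorothiazide-hepatic-caution")
        fired.add("hydrochlorothiazide-monitor-k-na-cl")

    if "losartan" in meds:
        if crcl is not None and 0.0 < crcl < 30.0:
            fired.add("losartan-renal-crcl-lt-30")
        if impaired_or_worse:
            fired.add("losartan-hepatic-initiate-25")
        if pregnant:
            fired.add("losartan-pregnancy-discontinue")
        fired.add("losartan-monitor-na-k")

    if "mycophenolate" in meds:
        if crcl is not None and 0.0 < crcl < 25.0:
            fired.add("mycophenolate-renal-crcl-lt-25")
        if pregnant:
            fired.add("mycophenolate-pregnancy-discontinue")
        if female:
            fired.add("mycophenolate-monitor-bhcg")

    if "omeprazole" in meds:
        if severe:
            fired.add("omeprazole-hepatic-severe-reduce")
        fired.add("omeprazole-monitor-mg-vitb12")

    return frozenset(fired)
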