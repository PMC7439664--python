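"""Synthetic patients: boundary-crossing fixtures and profiled cohorts.

Two generators, two purposes:

* :func:`fixture_patients` builds a deterministic grid of "fictitious
  patients" that cross every numeric rule threshold at t-eps, t, t+eps
  (eps = 1e-6 in the threshold's unit), plus pregnancy, cirrhosis,
  Child-Pugh, sex and freshness-window scenarios.  Serum creatinine is
  back-solved through Cockcroft-Gault so the derived clearance lands at
  the target value.  Every fixture carries its expected alert set as
  computed by the independent brute-force oracle — never by the engine
  under test — so the grid doubles as a sensitivity/specificity harness.

* :func:`sample_cohort` draws a seeded random outpatient cohort matching
  a kidney-transplant clinic profile: 56% male; age mean 47.44 y over
  20-73; weight mean 72.07 kg over 45-135; Cr 1.57 +/- 0.66 mg/dl,
  AST 19.64 +/- 8.16 U/L, ALT 21.14 +/- 13.24 U/L; medication
  prevalences per the same clinic census.  Ages and weights use a
  truncated normal with the stated range at roughly mean +/- 2.5 sd;
  labs are normals truncated at zero; all attributes are sampled
  independently (no correlation structure is modelled).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from ._dates import add_months
from .core_model import (Ascites, ChildPughInputs, Encephalopathy, LabResult,
                         PatientRecord, PregnancyRecord, Prescription, Sex)
from .knowledgebase import Category, CrClIn, KnowledgeBase, LabCmp
from .oracle import expected_rule_ids
from .physiology import (IMPAIRED_ALT, IMPAIRED_AST, IMPAIRED_BILI,
                         SEVERE_ALT, SEVERE_AST, SEVERE_BILI)

#: Fixed evaluation instant for fixtures, so boundary tests are reproducible.
FIXTURE_AS_OF = dt.datetime(2020, 6, 15)
EPSILON = 1e-6


@dataclass(frozen=True)
class FixturePatient:
    description: str
    patient: PatientRecord
    labs: tuple
    prescriptions: tuple
    as_of: dt.datetime
    expected_rule_ids: frozenset


def _base_patient(pid: str, sex: Sex, **overrides) -> PatientRecord:
    # age exactly 50.0 at FIXTURE_AS_OF so CrCl back-solving is exact
    defaults = dict(patient_id=pid, sex=sex, birth_date=dt.date(1970, 6, 15),
                    weight=72.0, height=170.0)
    defaults.update(overrides)
    return PatientRecord(**defaults)


def _lab(analyte: str, value: float, unit: str,
         when: dt.datetime | None = None, positive=None) -> LabResult:
    return LabResult(analyte=analyte, value=value, unit=unit,
                     observed_at=when or (FIXTURE_AS_OF - dt.timedelta(days=30)),
                     positive=positive)


def _rx(med: str, start: dt.date | None = None) -> Prescription:
    return Prescription(medication_id=med, medication_name=med.capitalize(),
                        start_date=start or dt.date(2020, 3, 1))


_NORMAL_LIVER = (
    ("ALT", 20.0, "U/L"), ("AST", 20.0, "U/L"), ("Bili_total", 1.0, "mg/dl"))


def _cr_for_target_crcl(target: float, sex: Sex) -> float:
    """Back-solve serum Cr so Cockcroft-Gault at (age 50, 72 kg) hits target.

    The arithmetic inversion of the same published formula; the forward
    evaluation is always re-run by the oracle, so a sub-ulp landing error
    cannot desynchronise expectation and engine.
    """
    k = (140.0 - 50.0) * 72.0 / 72.0
    if sex is Sex.female:
        k *= 0.85
    return k / target


def _make(desc: str, patient: PatientRecord, labs, prescriptions) -> FixturePatient:
    labs = tuple(labs)
    prescriptions = tuple(prescriptions)
    expected = expected_rule_ids(patient, list(labs), list(prescriptions),
                                 FIXTURE_AS_OF)
    return FixturePatient(desc, patient, labs, prescriptions, FIXTURE_AS_OF, expected)


def fixture_patients(kb: KnowledgeBase) -> list[FixturePatient]:
    """The deterministic boundary-crossing fixture grid for the seeded KB.

    Expected alert sets come from the hand-written per-rule oracle, which
    encodes the seeded rule set; a KB with different rules cannot be
    paired with it.
    """
    if kb.kb_version != "table1-v1":
        raise ValueError("fixture expectations are defined for the seeded "
                         f"knowledge base, not {kb.kb_version!r}")
    fixtures: list[FixturePatient] = []
    n = 0

    def next_id() -> str:
        nonlocal n
        n += 1
        return f"fx{n:04d}"

    # --- renal thresholds: t-eps, t, t+eps for each sex -------------------
    renal_thresholds: dict[str, set[float]] = {}
    for rule in kb.rules:
        if rule.category is not Category.renal:
            continue
        for atom in rule.trigger.atoms():
            if isinstance(atom, CrClIn):
                ts = renal_thresholds.setdefault(rule.medication, set())
                if atom.lo > 0:
                    ts.add(atom.lo)
                if atom.hi is not None:
                    ts.add(atom.hi)
    for med in sorted(renal_thresholds):
        for t in sorted(renal_thresholds[med]):
            for target in (t - EPSILON, t, t + EPSILON):
                for sex in (Sex.male, Sex.female):
                    cr = _cr_for_target_crcl(target, sex)
                    fixtures.append(_make(
                        f"{med}: CrCl target {target:.6f} ({sex.value})",
                        _base_patient(next_id(), sex),
                        [_lab("Cr", cr, "mg/dl")], [_rx(med)]))

    # --- hepatic thresholds, one analyte perturbed at a time --------------
    hepatic_meds = sorted({r.medication for r in kb.rules
                           if r.category is Category.hepatic})
    hepatic_grid = [("ALT", IMPAIRED_ALT, "U/L"), ("ALT", SEVERE_ALT, "U/L"),
                    ("AST", IMPAIRED_AST, "U/L"), ("AST", SEVERE_AST, "U/L"),
                    ("Bili_total", IMPAIRED_BILI, "mg/dl"),
                    ("Bili_total", SEVERE_BILI, "mg/dl")]
    for med in hepatic_meds:
        for analyte, t, unit in hepatic_grid:
            for value in (t - EPSILON, t, t + EPSILON):
                labs = [_lab(a, v, u) for a, v, u in _NORMAL_LIVER if a != analyte]
                labs.append(_lab(analyte, value, unit))
                fixtures.append(_make(
                    f"{med}: {analyte} {value:.6f} {unit}",
                    _base_patient(next_id(), Sex.male), labs, [_rx(med)]))
        # cirrhosis history alone, and Child-Pugh class C, imply severe
        fixtures.append(_make(
            f"{med}: cirrhosis history, normal labs",
            _base_patient(next_id(), Sex.male, cirrhosis_history=True),
            [_lab(a, v, u) for a, v, u in _NORMAL_LIVER], [_rx(med)]))
        fixtures.append(_make(
            f"{med}: Child-Pugh class C",
            _base_patient(next_id(), Sex.male, child_pugh_inputs=ChildPughInputs(
                bilirubin_total=3.5, albumin=2.5, inr=2.5,
                ascites=Ascites.moderate_severe,
                encephalopathy=Encephalopathy.grade3_4)),
            [_lab(a, v, u) for a, v, u in _NORMAL_LIVER], [_rx(med)]))

    # --- pregnancy scenarios ----------------------------------------------
    preg_meds = sorted({r.medication for r in kb.rules
                        if r.category is Category.pregnancy})
    for med in preg_meds:
        active = PregnancyRecord(detected_date=(FIXTURE_AS_OF
                                                - dt.timedelta(days=60)).date())
        expired = PregnancyRecord(
            detected_date=add_months(FIXTURE_AS_OF, -10).date())
        terminated = PregnancyRecord(
            detected_date=(FIXTURE_AS_OF - dt.timedelta(days=60)).date(),
            termination_date=(FIXTURE_AS_OF - dt.timedelta(days=1)).date())
        for tag, preg in (("active", active), ("expired", expired),
                          ("terminated", terminated)):
            fixtures.append(_make(
                f"{med}: pregnancy {tag}",
                _base_patient(next_id(), Sex.female, pregnancy=preg),
                [], [_rx(med)]))
        fixtures.append(_make(
            f"{med}: positive bHCG lab, no pregnancy record",
            _base_patient(next_id(), Sex.female),
            [_lab("bHCG", 1200.0, "mIU/mL", positive=True)], [_rx(med)]))
        fixtures.append(_make(
            f"{med}: negative bHCG lab",
            _base_patient(next_id(), Sex.female),
            [_lab("bHCG", 2.0, "mIU/mL", positive=False)], [_rx(med)]))
        fixtures.append(_make(
            f"{med}: male patient (no pregnancy rules)",
            _base_patient(next_id(), Sex.male), [], [_rx(med)]))

    # --- sex-specific monitoring and miscellaneous scenarios --------------
    for sex in (Sex.male, Sex.female):
        fixtures.append(_make(
            f"mycophenolate: pregnancy-test monitoring applies to {sex.value}",
            _base_patient(next_id(), sex), [], [_rx("mycophenolate")]))
    fixtures.append(_make(
        "no prescriptions: no alerts",
        _base_patient(next_id(), Sex.male),
        [_lab("Cr", 6.0, "mg/dl")], []))
    fixtures.append(_make(
        "stale Cr (7 months old): renal rules must not fire",
        _base_patient(next_id(), Sex.male),
        [_lab("Cr", 6.0, "mg/dl", when=add_months(FIXTURE_AS_OF, -7))],
        [_rx("allopurinol")]))
    fixtures.append(_make(
        "Cr exactly 6 months old: excluded by the half-open window",
        _base_patient(next_id(), Sex.male),
        [_lab("Cr", 6.0, "mg/dl", when=add_months(FIXTURE_AS_OF, -6))],
        [_rx("captopril")]))
    fixtures.append(_make(
        "Cr 5 months old: inside the window",
        _base_patient(next_id(), Sex.male),
        [_lab("Cr", 6.0, "mg/dl", when=add_months(FIXTURE_AS_OF, -5))],
        [_rx("captopril")]))
    fixtures.append(_make(
        "unknown medication generates no alerts",
        _base_patient(next_id(), Sex.male),
        [_lab("Cr", 6.0, "mg/dl")], [_rx("atorvastatin")]))
    return fixtures


# --------------------------------------------------------------------------
# Profiled random cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistSpec:
    mean: float
    sd: float
    lo: float = 0.0
    hi: float = float("inf")


@dataclass(frozen=True)
class CohortProfile:
    male_fraction: float
    age: DistSpec
    weight: DistSpec
    height_male: DistSpec
    height_female: DistSpec
    medication_prevalences: dict
    lab_distributions: dict  # analyte -> (DistSpec, unit)
    pregnancy_rate_female: float = 0.05
    cirrhosis_rate: float = 0.01

    def validate(self) -> None:
        probs = [self.male_fraction, self.pregnancy_rate_female, self.cirrhosis_rate,
                 *self.medication_prevalences.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        specs = [self.age, self.weight, self.height_male, self.height_female,
                 *(s for s, _ in self.lab_distributions.values())]
        if any(s.sd <= 0 for s in specs):
            raise ValueError("distribution standard deviations must be positive")


#: Clinic census profile: ranges sit at roughly mean +/- 2.5 sd.
TABLE2_PROFILE = CohortProfile(
    male_fraction=0.56,
    age=DistSpec(mean=47.44, sd=(73 - 20) / 5.0, lo=20, hi=73),
    weight=DistSpec(mean=72.07, sd=(135 - 45) / 5.0, lo=45, hi=135),
    height_male=DistSpec(mean=172.0, sd=7.0, lo=150, hi=200),
    height_female=DistSpec(mean=160.0, sd=7.0, lo=140, hi=195),
    medication_prevalences={
        "mycophenolate": 0.74, "cyclosporine": 0.71, "sirolimus": 0.23,
        "diltiazem": 0.51, "calcium": 0.50, "omeprazole": 0.39,
        "losartan": 0.34, "atorvastatin": 0.27,
    },
    lab_distributions={
        "Cr": (DistSpec(mean=1.57, sd=0.66, lo=0.0), "mg/dl"),
        "AST": (DistSpec(mean=19.64, sd=8.16, lo=0.0), "U/L"),
        "ALT": (DistSpec(mean=21.14, sd=13.24, lo=0.0), "U/L"),
    },
)


@dataclass(frozen=True)
class PatientBundle:
    patient: PatientRecord
    labs: tuple
    prescriptions: tuple

    def to_dict(self) -> dict:
        return {
            "patient": self.patient.model_dump(mode="json"),
            "labs": [lab.model_dump(mode="json") for lab in self.labs],
            "prescriptions": [rx.model_dump(mode="json") for rx in self.prescriptions],
        }


def _draw_trunc(rng: np.random.Generator, spec: DistSpec, size: int) -> np.ndarray:
    a = (spec.lo - spec.mean) / spec.sd
    b = (spec.hi - spec.mean) / spec.sd if np.isfinite(spec.hi) else np.inf
    return truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, size=size,
                         random_state=rng)


def sample_cohort(profile: CohortProfile, n: int, seed: int,
                  as_of: dt.date = dt.date(2020, 6, 15)) -> list[PatientBundle]:
    """Draw ``n`` patient bundles; identical (profile, n, seed) reproduce
    the same cohort bit-for-bit."""
    if n <= 0:
        raise ValueError("n must be positive")
    profile.validate()
    rng = np.random.default_rng(seed)

    male = rng.random(n) < profile.male_fraction
    ages = _draw_trunc(rng, profile.age, n)
    weights = _draw_trunc(rng, profile.weight, n)
    h_male = _draw_trunc(rng, profile.height_male, n)
    h_female = _draw_trunc(rng, profile.height_female, n)
    lab_names = sorted(profile.lab_distributions)
    lab_draws = {name: _draw_trunc(rng, profile.lab_distributions[name][0], n)
                 for name in lab_names}
    med_names = sorted(profile.medication_prevalences)
    med_draws = {m: rng.random(n) < profile.medication_prevalences[m]
                 for m in med_names}
    pregnant = rng.random(n) < profile.pregnancy_rate_female
    cirrhosis = rng.random(n) < profile.cirrhosis_rate

    lab_date = dt.datetime.combine(as_of, dt.time()) - dt.timedelta(days=30)
    rx_start = as_of - dt.timedelta(days=90)

    bundles: list[PatientBundle] = []
    for i in range(n):
        sex = Sex.male if male[i] else Sex.female
        birth = as_of - dt.timedelta(days=round(float(ages[i]) * 365.25))
        preg = None
        if sex is Sex.female and pregnant[i] and ages[i] < 50:
            preg = PregnancyRecord(detected_date=as_of - dt.timedelta(days=45))
        patient = PatientRecord(
            patient_id=f"syn{i:05d}", sex=sex, birth_date=birth,
            weight=round(float(weights[i]), 1),
            height=round(float(h_male[i] if male[i] else h_female[i]), 1),
            pregnancy=preg, cirrhosis_history=bool(cirrhosis[i]))
        labs = tuple(
            LabResult(analyte=name, value=round(float(lab_draws[name][i]), 2),
                      unit=profile.lab_distributions[name][1],
                      observed_at=lab_date)
            for name in lab_names)
        rxs = tuple(Prescription(medication_id=m, medication_name=m.capitalize(),
                                 start_date=rx_start)
                    for m in med_names if med_draws[m][i])
        bundles.append(PatientBundle(patient=patient, labs=labs, prescriptions=rxs))
    return bundles
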