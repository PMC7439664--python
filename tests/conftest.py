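import datetime as dt

import pytest

from dlicdss.core_model import (LabResult, PatientRecord, PregnancyRecord,
                                Prescription, Sex)
from dlicdss.knowledgebase import seeded_kb

#: Fixed evaluation instant for every test; evaluations never use the clock.
AS_OF = dt.datetime(2020, 6, 15)


@pytest.fixture(scope="session")
def kb():
    return seeded_kb()


@pytest.fixture
def as_of():
    return AS_OF


def make_patient(sex="male", *, age=50, weight=72.0, height=170.0,
                 pregnancy=None, cirrhosis=False, cp=None,
                 pid="p1") -> PatientRecord:
    """Patient whose age is exactly ``age`` years at AS_OF."""
    birth = dt.date(AS_OF.year - age, AS_OF.month, AS_OF.day)
    return PatientRecord(patient_id=pid, sex=Sex(sex), birth_date=birth,
                         weight=weight, height=height, pregnancy=pregnancy,
                         cirrhosis_history=cirrhosis, child_pugh_inputs=cp)


def lab(analyte, value, unit, *, days_ago=30, positive=None) -> LabResult:
    return LabResult(analyte=analyte, value=value, unit=unit,
                     observed_at=AS_OF - dt.timedelta(days=days_ago),
                     positive=positive)


def rx(med, *, start=dt.date(2020, 3, 1), event="new") -> Prescription:
    return Prescription(medication_id=med, medication_name=med.capitalize(),
                        start_date=start, event_kind=event)


def pregnant_record(months_ago=2, terminated_days_ago=None) -> PregnancyRecord:
    detected = (AS_OF - dt.timedelta(days=30 * months_ago)).date()
    term = (AS_OF - dt.timedelta(days=terminated_days_ago)).date() \
        if terminated_days_ago is not None else None
    return PregnancyRecord(detected_date=detected, termination_date=term)
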