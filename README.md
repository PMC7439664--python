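# dlicdss — drug–laboratory interaction screening for kidney-transplant prescribing

Kidney recipients live with a transplanted organ, lifelong immunosuppression,
poly-pharmacy and fragile renal and hepatic function.  Prescribing without
regard to the latest laboratory evidence — the wrong drug for the patient's
creatinine clearance, a full dose into a failing liver, a teratogen into a
pregnancy, a missed electrolyte check — is a *drug–laboratory interaction*
(DLI), one of the most common preventable medication errors in outpatient
care.

`dlicdss` is a clinical-decision-support rule engine for exactly this
problem.  It is aimed at informaticians and pharmacologists building or
studying medication-safety tooling: everything is a library call or a
headless CLI, there is no GUI, and no real patient data is needed anywhere —
a synthetic-cohort module generates boundary-crossing test patients and
profile-matched random cohorts.

## What it computes

**Physiology.**  Renal function is the Cockcroft–Gault creatinine clearance

```
CrCl [ml/min] = (140 − age) · weight / (72 · S_Cr)   (× 0.85 if female)
```

with age in years, weight in kg and serum creatinine in mg/dl.  Lean body
mass uses the Hume equations (male `0.32810·W + 0.33929·H − 29.5336`,
female `0.29569·W + 0.41813·H − 43.2933`).  Hepatic impairment is a
two-tier classification triangulated from liver tests, cirrhosis history and
the Child-Pugh score (standard 5-parameter, 5–15 point scheme):

* **impaired** — ALT > 40 U/L or AST > 40 U/L or total bilirubin > 1.5 mg/dl
* **severe** — AST > 120 or ALT > 120 or bilirubin > 3 mg/dl, or documented
  cirrhosis, or Child-Pugh class C

All comparisons are strict, exactly as curated; only laboratory results from
the last 6 calendar months (half-open window) are ever consulted.

**Rules.**  A knowledge base is a YAML/JSON list of IF/THEN rules —
medication + trigger predicate + action + category (renal / hepatic /
pregnancy / monitoring) + severity.  A seeded KB ships with 25 rules for
eight high-volume transplant-clinic medications (allopurinol, azathioprine,
captopril, cyclosporine, hydrochlorothiazide, losartan, mycophenolate,
omeprazole).

**Alerts.**  The engine evaluates every rule of every actively prescribed
medication as of an explicit instant and emits fully rendered alerts:
severity 1/2/3 ↔ red/orange/yellow, and *only* severity 1 (stop the drug or
change its dose) is interruptive — everything else is informational, to
limit alert fatigue.  Each alert message carries the medication, the
recommendation, and the latest rule-associated lab value with its date.
Overriding an alert never suppresses it: it reappears with every
prescription event, including refills, while the trigger holds; pregnancy
alerts expire after 9 months or on a recorded termination.  Every firing and
every clinician reaction is an immutable JSONL audit entry.

## Worked example

```python
import datetime as dt
from dlicdss import seeded_kb, evaluate, PatientRecord, LabResult, Prescription, Sex

kb = seeded_kb()
patient = PatientRecord(patient_id="kt-0042", sex=Sex.male,
                        birth_date=dt.date(1970, 6, 15), weight=72.0, height=170.0)
labs = [LabResult(analyte="Cr", value=6.0, unit="mg/dl",
                  observed_at=dt.datetime(2020, 5, 16)),
        LabResult(analyte="ALT", value=55.0, unit="U/L",
                  observed_at=dt.datetime(2020, 5, 16))]
rxs = [Prescription(medication_id="allopurinol", medication_name="Allopurinol",
                    start_date=dt.date(2020, 3, 1))]
for a in evaluate(patient, labs, rxs, kb, dt.datetime(2020, 6, 15)):
    print(f"[{a.color}/{a.display_mode}] {a.message}")
```

prints

```
[red/interruptive] Allopurinol: prescribe 200 mg/day per oral — CrCl 15.0 ml/min from Cr 6 mg/dl on 2020-05-16
[orange/informational] Allopurinol: Dosage adjustment may be necessary; No specific recommendations available — ALT 55 U/L (> 40 U/L) on 2020-05-16
[yellow/informational] Allopurinol: Monitor Uric acid level: if normal, check it every 6 months; if abnormal, change Allopurinol dose accordingly — no recent UricAcid result on file; baseline measurement needed
```

The 50-year-old, 72-kg patient's Cockcroft–Gault clearance is 90/6 = 15
ml/min, inside the `10 ≤ CrCl < 20` band, so the exact-dose rule fires as a
red interruptive pop-up; the ALT of 55 U/L puts him in the *impaired*
hepatic tier (orange caution); and the standing uric-acid monitoring
reminder appears as a yellow informational cue with baseline phrasing
because no uric-acid result is on file.

The same pipeline from a shell:

```
dli simulate --profile table2 --n 100 --seed 42 --out cohort.json
dli check cohort.json --at 2020-06-15 --out alerts.json --audit-log audit.jsonl
dli audit audit.jsonl
dli validate-kb my_kb.yaml
dli export-kb kb.yaml     # materialise the seeded KB for curation
```

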