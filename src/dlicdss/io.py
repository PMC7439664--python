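"""File readers/writers: patient bundles (JSON or CSV) and alert output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import ValidationError

from .core_model import LabResult, PatientRecord, Prescription
from .synthetic_cohort import PatientBundle


class BundleLoadError(Exception):
    """The patient file could not be parsed into valid bundles."""


def _bundle_from_dict(d: dict) -> PatientBundle:
    try:
        patient = PatientRecord.model_validate(d["patient"])
        labs = tuple(LabResult.model_validate(x) for x in d.get("labs", []))
        rxs = tuple(Prescription.model_validate(x) for x in d.get("prescriptions", []))
    except (KeyError, TypeError, ValidationError) as exc:
        raise BundleLoadError(f"malformed patient bundle: {exc}") from exc
    return PatientBundle(patient=patient, labs=labs, prescriptions=rxs)


def load_bundles_json(path: str | Path) -> list[PatientBundle]:
    """Read one bundle, a list of bundles, or {"patients": [...]}."""
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise BundleLoadError(f"{path}: not valid JSON: {exc}") from exc
    if isinstance(data, dict) and "patients" in data:
        data = data["patients"]
    if isinstance(data, dict):
        data = [data]
    if not isinstance(data, list):
        raise BundleLoadError(f"{path}: expected a bundle object or list")
    return [_bundle_from_dict(d) for d in data]


def save_bundles_json(bundles: list[PatientBundle], path: str | Path) -> None:
    payload = {"patients": [b.to_dict() for b in bundles]}
    Path(path).write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                          encoding="utf-8")


def load_bundles_csv(patients_csv: str | Path, labs_csv: Optional[str | Path] = None,
                     prescriptions_csv: Optional[str | Path] = None
                     ) -> list[PatientBundle]:
    """Flat-file ingestion: one lab or prescription per row, joined on
    ``patient_id``."""
    try:
        patients = pd.read_csv(patients_csv, dtype={"patient_id": str})
        labs = (pd.read_csv(labs_csv, dtype={"patient_id": str})
                if labs_csv else pd.DataFrame(columns=["patient_id"]))
        rxs = (pd.read_csv(prescriptions_csv, dtype={"patient_id": str})
               if prescriptions_csv else pd.DataFrame(columns=["patient_id"]))
    except (OSError, pd.errors.ParserError) as exc:
        raise BundleLoadError(str(exc)) from exc

    bundles = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        d = {"patient": {k: v for k, v in row.items() if pd.notna(v)},
             "labs": [{k: v for k, v in r.items() if k != "patient_id" and pd.notna(v)}
                      for _, r in labs[labs.patient_id == pid].iterrows()],
             "prescriptions": [{k: v for k, v in r.items()
                                if k != "patient_id" and pd.notna(v)}
                               for _, r in rxs[rxs.patient_id == pid].iterrows()]}
        bundles.append(_bundle_from_dict(d))
    return bundles


def alerts_payload(results: list[tuple[str, list]], as_of) -> dict:
    """Stable JSON payload: one entry per patient, alerts fully rendered."""
    return {
        "as_of": as_of.isoformat(),
        "patients": [
            {"patient_id": pid, "alerts": [a.to_dict() for a in alerts]}
            for pid, alerts in results
        ],
    }


def write_alerts(results: list[tuple[str, list]], as_of, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(alerts_payload(results, as_of), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8")
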