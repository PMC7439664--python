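"""Derived physiologic state: renal clearance, lean body mass, hepatic tier.

Renal function is estimated with the Cockcroft-Gault creatinine-clearance
formula, lean body mass with the Hume (1966) equations, and hepatic
impairment with a two-tier classification that triangulates liver
function tests, cirrhosis history and (optionally) the Child-Pugh score.

The dosing thresholds used by the knowledge base are printed by drug
references as ml/min/1.73 m^2 while Cockcroft-Gault yields raw ml/min;
clinical practice (and the system this engine models) compares the raw
value directly against those thresholds.  An optional BSA normalisation
(DuBois) is available but off by default.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Optional

from ._dates import within_window
from .core_model import Ascites, ChildPughInputs, Encephalopathy, LabResult, Sex

#: Two-tier hepatic thresholds, in canonical units (U/L, U/L, mg/dl).
IMPAIRED_ALT = 40.0
IMPAIRED_AST = 40.0
IMPAIRED_BILI = 1.5
SEVERE_ALT = 120.0
SEVERE_AST = 120.0
SEVERE_BILI = 3.0


class HepaticTier(enum.IntEnum):
    """Ordered so that comparisons express 'at least this impaired'."""

    normal = 0
    impaired = 1
    severe = 2


@dataclass(frozen=True)
class RenalState:
    crcl: float  # ml/min
    serum_cr_used: float  # mg/dl
    cr_observed_at: dt.datetime


@dataclass(frozen=True)
class BodyComposition:
    lbm: float  # kg


@dataclass(frozen=True)
class HepaticState:
    tier: HepaticTier
    #: (criterion, observed value, threshold description) per satisfied criterion.
    evidence: list = field(default_factory=list)
    #: Latest in-window liver lab per analyte, for alert rendering.
    latest_labs: dict = field(default_factory=dict)
    child_pugh: Optional[tuple[int, str]] = None
    #: True when no liver data at all was available (distinct from "data normal").
    no_data: bool = False


def creatinine_clearance(
    age: float,
    weight: float,
    sex: Sex,
    serum_cr: float,
    *,
    bsa_normalize: bool = False,
    height: Optional[float] = None,
) -> float:
    """Cockcroft-Gault creatinine clearance in ml/min.

    CrCl = (140 - age) * weight / (72 * serum_cr), times 0.85 for females.
    With ``bsa_normalize`` the result is scaled to 1.73 m^2 body surface
    area using the DuBois formula (requires height).
    """
    if serum_cr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {serum_cr}")
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if not 18 <= age < 140:
        raise ValueError(f"age {age} outside the formula's valid adult domain [18, 140)")
    crcl = (140.0 - age) * weight / (72.0 * serum_cr)
    if sex is Sex.female:
        crcl *= 0.85
    if bsa_normalize:
        if height is None:
            raise ValueError("BSA normalisation requires height")
        bsa = 0.007184 * weight**0.425 * height**0.725
        crcl *= 1.73 / bsa
    return crcl


def lean_body_mass(sex: Sex, weight: float, height: Optional[float]) -> BodyComposition:
    """Hume (1966) lean body mass estimate, kg.

    male:   0.32810 W + 0.33929 H - 29.5336
    female: 0.29569 W + 0.41813 H - 43.2933   (W in kg, H in cm)
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if height is None:
        raise ValueError("height is required for lean body mass")
    if sex is Sex.male:
        lbm = 0.32810 * weight + 0.33929 * height - 29.5336
    else:
        lbm = 0.29569 * weight + 0.41813 * height - 43.2933
    return BodyComposition(lbm=lbm)


_ASCITES_POINTS = {Ascites.none: 1, Ascites.mild: 2, Ascites.moderate_severe: 3}
_ENCEPH_POINTS = {Encephalopathy.none: 1, Encephalopathy.grade1_2: 2,
                  Encephalopathy.grade3_4: 3}


def child_pugh(inputs: ChildPughInputs) -> tuple[int, str]:
    """Child-Pugh score (5..15) and class (A: 5-6, B: 7-9, C: 10-15).

    Standard five-parameter scheme, 1-3 points each:
    bilirubin <2 / 2-3 / >3 mg/dl; albumin >3.5 / 2.8-3.5 / <2.8 g/dl;
    INR <1.7 / 1.7-2.3 / >2.3; ascites and encephalopathy by grade.
    """
    if inputs is None:
        raise ValueError("all five Child-Pugh parameters are required")
    b = inputs.bilirubin_total
    bili_pts = 1 if b < 2 else (2 if b <= 3 else 3)
    a = inputs.albumin
    alb_pts = 1 if a > 3.5 else (2 if a >= 2.8 else 3)
    i = inputs.inr
    inr_pts = 1 if i < 1.7 else (2 if i <= 2.3 else 3)
    score = (bili_pts + alb_pts + inr_pts
             + _ASCITES_POINTS[inputs.ascites] + _ENCEPH_POINTS[inputs.encephalopathy])
    cls = "A" if score <= 6 else ("B" if score <= 9 else "C")
    return score, cls


def latest_per_analyte(
    labs: list[LabResult],
    as_of: dt.datetime,
    window_months: int,
    analytes: Optional[set[str]] = None,
) -> dict[str, LabResult]:
    """Most recent in-window result for each analyte (half-open window]."""
    out: dict[str, LabResult] = {}
    for lab in labs:
        if analytes is not None and lab.analyte not in analytes:
            continue
        if not within_window(lab.observed_at, as_of, window_months):
            continue
        prev = out.get(lab.analyte)
        if prev is None or lab.observed_at > prev.observed_at:
            out[lab.analyte] = lab
    return out


def hepatic_state(
    labs: list[LabResult],
    cirrhosis_history: bool,
    cp: Optional[ChildPughInputs],
    as_of: dt.datetime,
    window_months: int = 6,
    *,
    cirrhosis_implies_severe: bool = True,
    child_pugh_c_implies_severe: bool = True,
) -> HepaticState:
    """Two-tier hepatic impairment from labs + history + Child-Pugh.

    severe   := AST > 120 or ALT > 120 or Bili-total > 3, or cirrhosis
                history, or Child-Pugh class C (the last two configurable);
    impaired := ALT > 40 or AST > 40 or Bili-total > 1.5, when not severe.

    Only the latest in-window result per analyte is consulted.  All
    comparisons are strict: a value exactly at a threshold does not
    qualify.  Every satisfied criterion is listed as evidence.
    """
    liver = latest_per_analyte(labs, as_of, window_months,
                               analytes={"ALT", "AST", "Bili_total"})
    alt = liver.get("ALT")
    ast = liver.get("AST")
    bili = liver.get("Bili_total")

    evidence: list[tuple[str, float | bool, str]] = []
    severe = False
    if ast is not None and ast.value > SEVERE_AST:
        severe = True
        evidence.append(("AST", ast.value, f"> {SEVERE_AST:g} U/L"))
    if alt is not None and alt.value > SEVERE_ALT:
        severe = True
        evidence.append(("ALT", alt.value, f"> {SEVERE_ALT:g} U/L"))
    if bili is not None and bili.value > SEVERE_BILI:
        severe = True
        evidence.append(("Bili_total", bili.value, f"> {SEVERE_BILI:g} mg/dl"))
    if cirrhosis_history and cirrhosis_implies_severe:
        severe = True
        evidence.append(("cirrhosis_history", True, "documented cirrhotic liver disease"))
    cp_result: Optional[tuple[int, str]] = None
    if cp is not None:
        cp_result = child_pugh(cp)
        if cp_result[1] == "C" and child_pugh_c_implies_severe:
            severe = True
            evidence.append(("child_pugh", cp_result[0], "class C"))

    impaired = False
    if not severe:
        if alt is not None and alt.value > IMPAIRED_ALT:
            impaired = True
            evidence.append(("ALT", alt.value, f"> {IMPAIRED_ALT:g} U/L"))
        if ast is not None and ast.value > IMPAIRED_AST:
            impaired = True
            evidence.append(("AST", ast.value, f"> {IMPAIRED_AST:g} U/L"))
        if bili is not None and bili.value > IMPAIRED_BILI:
            impaired = True
            evidence.append(("Bili_total", bili.value, f"> {IMPAIRED_BILI:g} mg/dl"))

    tier = HepaticTier.severe if severe else (
        HepaticTier.impaired if impaired else HepaticTier.normal)
    no_data = not liver and not cirrhosis_history and cp is None
    return HepaticState(tier=tier, evidence=evidence, latest_labs=liver,
                        child_pugh=cp_result, no_data=no_data)
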