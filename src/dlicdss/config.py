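"""Engine configuration: freshness windows and physiologic toggles."""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, field_validator


class EngineConfig(BaseModel):
    """Evaluation-time knobs, all with clinically conventional defaults.

    lab_window_months
        Historical lab results older than this (calendar months, half-open
        window) are never used to trigger or justify an alert.
    pregnancy_expiry_months
        Pregnancy-triggered alerts expire this many months after the
        positive evidence, or immediately on a recorded termination.
    bsa_normalize
        Scale Cockcroft-Gault output to 1.73 m^2 body surface area before
        comparing with CrCl thresholds.  Off by default: thresholds are
        compared against the raw ml/min estimate, mirroring common
        practice in transplant clinics.
    crcl_weight
        Which weight feeds Cockcroft-Gault: actual body weight (default)
        or Hume lean body mass.
    bhcg_positive_threshold
        Optional numeric positivity cut-off (mIU/mL) for the beta-HCG
        pregnancy test; by default only the qualitative positive flag on
        the lab record counts.
    """

    lab_window_months: int = 6
    pregnancy_expiry_months: int = 9
    bsa_normalize: bool = False
    crcl_weight: str = "actual"  # "actual" | "lbm"
    default_monitor_interval_months: int = 6
    bhcg_positive_threshold: Optional[float] = None
    cirrhosis_implies_severe: bool = True
    child_pugh_c_implies_severe: bool = True
    kb_path: Optional[str] = None
    log_path: Optional[str] = None

    @field_validator("lab_window_months", "pregnancy_expiry_months",
                     "default_monitor_interval_months")
    @classmethod
    def _positive_months(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("month values must be positive")
        return v

    @field_validator("crcl_weight")
    @classmethod
    def _weight_choice(cls, v: str) -> str:
        if v not in ("actual", "lbm"):
            raise ValueError("crcl_weight must be 'actual' or 'lbm'")
        return v
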