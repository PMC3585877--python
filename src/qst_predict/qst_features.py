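"""Derivation of the eight screened quantitative-sensory-testing predictors.

Raw measurements per patient: pressure pain detection thresholds (pPDT,
kPa) and electric pain detection thresholds (ePDT, mA) at the pancreatic
viscerotome (Th10) and a control dermatome (C5); pressure pain tolerance
thresholds (pPTT) on the thigh before and after a cold-pressor
conditioning stimulus; and the cold-pressor immersion time itself
(capped at 180 s by the protocol).

Derived predictors:

* site ratios pPDT_pancreas/pPDT_control and ePDT_pancreas/ePDT_control —
  a within-subject index of segmental sensitisation that cancels
  between-subject differences in absolute thresholds.  A *lower* ratio
  means the pancreatic viscerotome is relatively hypersensitive.
* the conditioned-pain-modulation (CPM) effect, 100*(pPTT_post -
  pPTT_pre)/pPTT_pre.  Positive = inhibitory modulation (the tolerance
  threshold rose after conditioning); the pre-conditioning value is the
  denominator.

A patient missing a raw measurement loses only the features that depend
on it; the remaining features stay available for per-feature screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import pandas as pd

from .synthetic_cohort import PatientRecord

__all__ = [
    "FEATURE_NAMES",
    "QSTFeatures",
    "sensitivity_ratio",
    "cpm_effect",
    "extract_features",
    "feature_table",
]

logger = logging.getLogger(__name__)

#: canonical screening order of the eight predictors; ties in feature
#: screening fall back on this order.
FEATURE_NAMES = (
    "ppdt_pancreas",
    "ppdt_control",
    "ppdt_ratio",
    "epdt_pancreas",
    "epdt_control",
    "epdt_ratio",
    "cold_pressor_time",
    "cpm_effect",
)


@dataclass(frozen=True)
class QSTFeatures:
    """The eight predictors for one patient; None marks a missing feature."""

    ppdt_pancreas: Optional[float]  # kPa
    ppdt_control: Optional[float]  # kPa
    ppdt_ratio: Optional[float]  # dimensionless
    epdt_pancreas: Optional[float]  # mA
    epdt_control: Optional[float]  # mA
    epdt_ratio: Optional[float]  # dimensionless
    cold_pressor_time: Optional[float]  # seconds
    cpm_effect: Optional[float]  # percent

    def to_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def sensitivity_ratio(pancreas_threshold: float, control_threshold: float) -> float:
    """Pancreatic-area threshold divided by control-area threshold.

    Dimensionless and invariant to common rescaling of both thresholds;
    values below 1 indicate relative pancreatic hypersensitivity.
    """
    if pancreas_threshold <= 0 or control_threshold <= 0:
        raise ValueError(
            f"pain thresholds must be positive, got pancreas={pancreas_threshold}, "
            f"control={control_threshold}"
        )
    return pancreas_threshold / control_threshold


def cpm_effect(pptt_pre: float, pptt_post: float) -> float:
    """Conditioned-pain-modulation effect as percent change in pPTT.

    100*(post - pre)/pre; positive values mean the tolerance threshold
    rose after the cold-pressor conditioning stimulus (inhibition),
    negative values mean facilitation.
    """
    if pptt_pre <= 0:
        raise ValueError(f"pre-conditioning pPTT must be positive, got {pptt_pre}")
    if pptt_post <= 0:
        raise ValueError(f"post-conditioning pPTT must be positive, got {pptt_post}")
    return 100.0 * (pptt_post - pptt_pre) / pptt_pre


def _present(*vals: Optional[float]) -> bool:
    return all(v is not None and v == v for v in vals)  # v == v filters NaN


def extract_features(record: PatientRecord) -> QSTFeatures:
    """Assemble the eight screened predictors from raw measurements.

    Pure: the same record always yields identical features.  Any missing
    raw field produces a missing marker for the dependent feature(s) only,
    logged with the patient id.
    """
    r = record
    out: dict[str, Optional[float]] = {name: None for name in FEATURE_NAMES}

    if _present(r.ppdt_pancreas):
        out["ppdt_pancreas"] = float(r.ppdt_pancreas)
    if _present(r.ppdt_control):
        out["ppdt_control"] = float(r.ppdt_control)
    if _present(r.ppdt_pancreas, r.ppdt_control):
        out["ppdt_ratio"] = sensitivity_ratio(r.ppdt_pancreas, r.ppdt_control)
    if _present(r.epdt_pancreas):
        out["epdt_pancreas"] = float(r.epdt_pancreas)
    if _present(r.epdt_control):
        out["epdt_control"] = float(r.epdt_control)
    if _present(r.epdt_pancreas, r.epdt_control):
        out["epdt_ratio"] = sensitivity_ratio(r.epdt_pancreas, r.epdt_control)
    if _present(r.cold_pressor_time):
        out["cold_pressor_time"] = float(r.cold_pressor_time)
    if _present(r.pptt_pre, r.pptt_post):
        out["cpm_effect"] = cpm_effect(r.pptt_pre, r.pptt_post)

    missing = [k for k, v in out.items() if v is None]
    if missing:
        logger.info("patient %s: missing features %s", r.patient_id, missing)
    return QSTFeatures(**out)


def feature_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Feature matrix indexed by patient id, columns in screening order."""
    rows = {rec.patient_id: extract_features(rec).to_dict() for rec in records}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    df.index.name = "patient_id"
    return df.astype(float)
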