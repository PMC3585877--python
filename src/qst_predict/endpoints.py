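"""Clinical endpoint: percent change in average daily pain and responder labels.

Patients keep a daily pain diary on a 0-10 visual analogue scale (VAS) for
the week before randomisation (baseline) and the last week of treatment.
The endpoint is the percent change of the weekly mean; a patient is a
*responder* when weekly mean pain fell by at least 30% (boundary
inclusive).  Patients with too few diary entries in either week are
non-evaluable and excluded from the per-protocol analysis rather than
imputed.

"Incomplete diary" is operationalised as fewer than ``min_days`` (default
4) recorded days in a week — a majority-of-week convention, configurable
because the underlying protocol leaves the cut-off open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import PatientRecord

__all__ = [
    "ResponderLabel",
    "DEFAULT_MIN_DAYS",
    "RESPONDER_THRESHOLD_PCT",
    "baseline_pain",
    "endpoint_pain",
    "classify_responder",
    "label_record",
    "label_cohort",
    "per_protocol_filter",
]

logger = logging.getLogger(__name__)

#: minimum number of non-missing diary days per week for evaluability.
DEFAULT_MIN_DAYS = 4

#: percent reduction in weekly mean pain defining a responder (inclusive).
RESPONDER_THRESHOLD_PCT = 30.0


@dataclass(frozen=True)
class ResponderLabel:
    """Responder status of one patient derived from the pain diary.

    ``percent_change`` is signed: negative means pain fell, and
    ``is_responder`` is True iff ``percent_change <= -30``.  Non-evaluable
    records (incomplete diary or zero baseline pain) carry no label:
    the numeric fields are None and ``reason`` says why.
    """

    baseline_mean: Optional[float]
    endpoint_mean: Optional[float]
    percent_change: Optional[float]
    is_responder: Optional[bool]
    evaluable: bool
    reason: Optional[str] = None


def _weekly_mean(days: Sequence[Optional[float]], min_days: int) -> Optional[float]:
    vals = [v for v in days if v is not None and not (isinstance(v, float) and np.isnan(v))]
    for v in vals:
        if not (0.0 <= v <= 10.0):
            raise ValueError(f"diary value {v} outside the 0-10 VAS range")
    if len(vals) < min_days:
        return None
    return float(np.mean(vals))


def baseline_pain(
    diary_baseline_week: Sequence[Optional[float]], min_days: int = DEFAULT_MIN_DAYS
) -> Optional[float]:
    """Mean of the non-missing baseline-week diary values.

    Returns None (non-evaluable) when fewer than ``min_days`` days were
    recorded; this is a signal, not an error, and propagates to
    per-protocol exclusion.
    """
    return _weekly_mean(diary_baseline_week, min_days)


def endpoint_pain(
    diary_final_week: Sequence[Optional[float]], min_days: int = DEFAULT_MIN_DAYS
) -> Optional[float]:
    """Mean of the non-missing final-treatment-week diary values."""
    return _weekly_mean(diary_final_week, min_days)


def classify_responder(
    baseline_mean: float,
    endpoint_mean: float,
    threshold_pct: float = RESPONDER_THRESHOLD_PCT,
) -> ResponderLabel:
    """Label a patient from weekly mean pain scores.

    A reduction of ``threshold_pct`` percent *or more* counts as response
    (the boundary is inclusive).  A zero baseline makes the percent change
    undefined; such a record is returned non-evaluable rather than raising,
    since pain-free patients fall outside the study population anyway.
    """
    if baseline_mean < 0 or endpoint_mean < 0:
        raise ValueError("weekly mean pain cannot be negative")
    if baseline_mean == 0:
        return ResponderLabel(
            baseline_mean=0.0,
            endpoint_mean=endpoint_mean,
            percent_change=None,
            is_responder=None,
            evaluable=False,
            reason="zero baseline pain: percent change undefined",
        )
    pct = 100.0 * (endpoint_mean - baseline_mean) / baseline_mean
    return ResponderLabel(
        baseline_mean=float(baseline_mean),
        endpoint_mean=float(endpoint_mean),
        percent_change=float(pct),
        is_responder=bool(pct <= -threshold_pct),
        evaluable=True,
    )


def label_record(
    record: PatientRecord,
    min_days: int = DEFAULT_MIN_DAYS,
    threshold_pct: float = RESPONDER_THRESHOLD_PCT,
) -> ResponderLabel:
    """Full diary-to-label pipeline for one patient."""
    base = baseline_pain(record.diary_baseline_week, min_days)
    endp = endpoint_pain(record.diary_final_week, min_days)
    if base is None or endp is None:
        missing = []
        if base is None:
            missing.append("baseline")
        if endp is None:
            missing.append("final")
        return ResponderLabel(
            baseline_mean=base,
            endpoint_mean=endp,
            percent_change=None,
            is_responder=None,
            evaluable=False,
            reason=f"incomplete {' and '.join(missing)} diary (<{min_days} days)",
        )
    return classify_responder(base, endp, threshold_pct)


def label_cohort(
    records: Sequence[PatientRecord],
    min_days: int = DEFAULT_MIN_DAYS,
    threshold_pct: float = RESPONDER_THRESHOLD_PCT,
) -> pd.DataFrame:
    """Label every patient; one row per patient, evaluable or not."""
    rows = []
    for rec in records:
        lab = label_record(rec, min_days=min_days, threshold_pct=threshold_pct)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "arm": rec.arm,
                "baseline_mean": lab.baseline_mean,
                "endpoint_mean": lab.endpoint_mean,
                "percent_change": lab.percent_change,
                "responder": lab.is_responder,
                "evaluable": lab.evaluable,
                "exclusion_reason": lab.reason,
            }
        )
    return pd.DataFrame(rows)


def per_protocol_filter(
    records: Sequence[PatientRecord],
    min_days: int = DEFAULT_MIN_DAYS,
    threshold_pct: float = RESPONDER_THRESHOLD_PCT,
) -> tuple[list[PatientRecord], dict[str, str]]:
    """Split a cohort into evaluable records and excluded patient ids.

    Returns the evaluable records (original order) and a mapping
    patient_id -> exclusion reason.  The partition is exhaustive and
    disjoint, and filtering is idempotent.
    """
    kept: list[PatientRecord] = []
    excluded: dict[str, str] = {}
    for rec in records:
        lab = label_record(rec, min_days=min_days, threshold_pct=threshold_pct)
        if lab.evaluable:
            kept.append(rec)
        else:
            excluded[rec.patient_id] = lab.reason or "non-evaluable"
            logger.info("excluding %s: %s", rec.patient_id, lab.reason)
    if records and not kept:
        warnings.warn("all records excluded: no evaluable diaries", stacklevel=2)
    return kept, excluded
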