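"""Synthetic two-arm cohort generator calibrated to printed group summaries.

The patient-level data behind the pregabalin/placebo QST prediction study
were never deposited; only group-level medians with interquartile ranges
and responder counts are available.  This module turns those summaries
into a generative model so that every downstream stage (endpoint
labelling, feature derivation, threshold screening, exact tests) can be
exercised end-to-end on data with known ground truth.

Generative model, per patient:

* Positive, right-skewed threshold measurements (pressure and electric
  pain detection thresholds, cold-pressor time) are log-normal, the
  simplest two-parameter positive law that can be pinned to a median/IQR
  summary.  The log-location is ln(median); the log-scale is
  (ln q3 - ln q1) / (2 * z_0.75).
* Site *ratios* are the scientifically calibrated quantities: the ratio
  and the control-site threshold are drawn independently and the
  pancreatic-site threshold is their product, so rescaling units leaves
  the ratio distribution untouched.
* The CPM effect (a percent change that may be negative) is normal with
  mean at the summary median and SD from the IQR; the pre-conditioning
  pressure tolerance threshold is log-normal and the post value is
  derived from the drawn effect.
* Cold-pressor times are clipped at the 180 s protocol ceiling.
* Responder status is *induced through the diary*: each arm gets a fixed
  responder count (reproducing printed counts exactly), and each
  patient's final-week diary is the baseline week scaled by a percent
  reduction drawn from the status-appropriate range, with per-day jitter
  (SD 0.3 VAS) whose weekly mean is removed so the endpoint stage
  recovers the intended label exactly when no missingness is injected.

Randomness uses one master seed with per-patient counter-derived
substreams, so growing a cohort never reshuffles earlier patients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exact_stats import MedianIQR, Z_UPPER_QUARTILE

__all__ = [
    "MedianIQR",
    "LogNormalParams",
    "NormalParams",
    "calibrate_lognormal",
    "calibrate_normal",
    "CohortConfig",
    "PatientRecord",
    "ARMS",
    "COLD_PRESSOR_CEILING_S",
    "default_config",
    "load_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

ARMS = ("pregabalin", "placebo")

#: protocol ceiling on cold-pressor immersion time, seconds.
COLD_PRESSOR_CEILING_S = 180.0

#: per-day diary jitter SD on the VAS scale.
DIARY_JITTER_SD = 0.3

#: relative tolerance for declaring a median/IQR summary log-symmetric.
_LOG_SYMMETRY_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Distribution calibration from median/IQR summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal calibrated to a median/IQR summary.

    ``median`` is matched exactly (location = ln median).  When the
    summary is symmetric on the log axis both theoretical quartiles match
    it too; otherwise the scale is the compromise
    (ln q3 - ln q1) / (2 z_0.75) and ``log_symmetric`` is False so the
    caller can see which regime applied.
    """

    location: float  # mean of ln X
    scale: float  # SD of ln X
    log_symmetric: bool

    @property
    def median(self) -> float:
        return math.exp(self.location)

    def quartiles(self) -> tuple[float, float]:
        """Theoretical (q1, q3) of the calibrated law."""
        d = Z_UPPER_QUARTILE * self.scale
        return math.exp(self.location - d), math.exp(self.location + d)

    def rvs(self, rng: np.random.Generator, size: int | None = None):
        return rng.lognormal(mean=self.location, sigma=self.scale, size=size)


@dataclass(frozen=True)
class NormalParams:
    """Normal law with mean at the summary median, SD from the IQR.

    Used for quantities that may be negative (the CPM percent effect),
    where a log-normal is unavailable.
    """

    mean: float
    sd: float

    def rvs(self, rng: np.random.Generator, size: int | None = None):
        return rng.normal(loc=self.mean, scale=self.sd, size=size)


def calibrate_lognormal(summary: MedianIQR) -> LogNormalParams:
    """Fit a log-normal to a median/IQR summary.

    Raises on non-positive summaries or zero spread (q1 == q3): a
    degenerate law cannot be represented.
    """
    if summary.median <= 0 or summary.q1 <= 0 or summary.q3 <= 0:
        raise ValueError(f"log-normal calibration needs positive summaries, got {summary}")
    if summary.q1 >= summary.q3:
        raise ValueError(f"degenerate spread: q1 ({summary.q1}) >= q3 ({summary.q3})")
    location = math.log(summary.median)
    scale = (math.log(summary.q3) - math.log(summary.q1)) / (2.0 * Z_UPPER_QUARTILE)
    lo_gap = location - math.log(summary.q1)
    hi_gap = math.log(summary.q3) - location
    symmetric = math.isclose(lo_gap, hi_gap, rel_tol=_LOG_SYMMETRY_RTOL, abs_tol=1e-12)
    return LogNormalParams(location=location, scale=scale, log_symmetric=symmetric)


def calibrate_normal(summary: MedianIQR) -> NormalParams:
    """Fit a normal law (median = mean, IQR -> SD) to a summary."""
    if summary.q1 >= summary.q3:
        raise ValueError(f"degenerate spread: q1 ({summary.q1}) >= q3 ({summary.q3})")
    return NormalParams(
        mean=summary.median, sd=(summary.q3 - summary.q1) / (2.0 * Z_UPPER_QUARTILE)
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: feature names expected in each (arm, status) calibration block and the
#: family used to model them.
_CALIBRATED_FEATURES = {
    "ppdt_control": "lognormal",  # kPa
    "ppdt_ratio": "lognormal",  # dimensionless
    "epdt_control": "lognormal",  # mA
    "epdt_ratio": "lognormal",  # dimensionless
    "cold_pressor": "lognormal",  # seconds, clipped at the 180 s ceiling
    "cpm": "normal",  # percent, may be negative
    "pptt_pre": "lognormal",  # kPa
}

_STATUSES = ("responder", "nonresponder")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a two-arm synthetic cohort.

    ``feature_calibration`` maps (arm, status) -> feature -> MedianIQR.
    Percent-reduction ranges are in "percent reduction of weekly mean
    pain" units (positive = improvement): responders draw from a range
    bounded below by 30, non-responders from a range bounded above by 30,
    with both ranges kept clear of the boundary so diary jitter cannot
    flip a label.
    """

    n_pregabalin: int
    n_placebo: int
    responder_rate_pregabalin: float
    responder_rate_placebo: float
    feature_calibration: Mapping[tuple[str, str], Mapping[str, MedianIQR]]
    diary_baseline: MedianIQR
    responder_reduction_range: tuple[float, float] = (35.0, 75.0)
    nonresponder_reduction_range: tuple[float, float] = (-25.0, 25.0)
    missing_diary_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pregabalin < 4 or self.n_placebo < 4:
            raise ValueError("each arm needs at least 4 patients")
        for r in (self.responder_rate_pregabalin, self.responder_rate_placebo):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"responder rate out of [0, 1]: {r}")
        lo, hi = self.responder_reduction_range
        if not (30.0 <= lo <= hi):
            raise ValueError("responder reduction range must lie at or above 30%")
        nlo, nhi = self.nonresponder_reduction_range
        if not (nlo <= nhi < 30.0):
            raise ValueError("non-responder reduction range must lie below 30%")
        if nhi >= lo:
            raise ValueError("responder and non-responder reduction ranges overlap")
        if not (0.0 <= self.missing_diary_fraction < 1.0):
            raise ValueError("missing_diary_fraction must be in [0, 1)")
        for arm in ARMS:
            for status in _STATUSES:
                block = self.feature_calibration.get((arm, status))
                if block is None:
                    raise ValueError(f"missing calibration block for ({arm}, {status})")
                for feat in _CALIBRATED_FEATURES:
                    if feat not in block:
                        raise ValueError(f"calibration ({arm}, {status}) lacks {feat!r}")

    def responder_count(self, arm: str) -> int:
        """Fixed responder count for an arm: round(rate * n)."""
        n = self.n_pregabalin if arm == "pregabalin" else self.n_placebo
        rate = (
            self.responder_rate_pregabalin
            if arm == "pregabalin"
            else self.responder_rate_placebo
        )
        return int(round(rate * n))

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _config_from_dict(raw: dict) -> CohortConfig:
    cal = {}
    for arm, statuses in raw["feature_calibration"].items():
        for status, feats in statuses.items():
            cal[(arm, status)] = {
                name: MedianIQR(median=v["median"], q1=v["q1"], q3=v["q3"])
                for name, v in feats.items()
            }
    db = raw["diary_baseline"]
    return CohortConfig(
        n_pregabalin=raw["n_pregabalin"],
        n_placebo=raw["n_placebo"],
        responder_rate_pregabalin=raw["responder_rate_pregabalin"],
        responder_rate_placebo=raw["responder_rate_placebo"],
        feature_calibration=cal,
        diary_baseline=MedianIQR(median=db["median"], q1=db["q1"], q3=db["q3"]),
        responder_reduction_range=tuple(raw.get("responder_reduction_range", (35.0, 75.0))),
        nonresponder_reduction_range=tuple(
            raw.get("nonresponder_reduction_range", (-25.0, 25.0))
        ),
        missing_diary_fraction=raw.get("missing_diary_fraction", 0.0),
        seed=raw.get("seed", 0),
    )


def load_config(path) -> CohortConfig:
    """Load a CohortConfig from a JSON file."""
    with open(path, encoding="utf-8") as fh:
        return _config_from_dict(json.load(fh))


def default_config(seed: int = 0) -> CohortConfig:
    """The calibration shipped with the package (printed group summaries)."""
    raw = json.loads(
        resources.files("qst_predict").joinpath("data/paper_calibration.json").read_text()
    )
    cfg = _config_from_dict(raw)
    return cfg.with_seed(seed)


# ---------------------------------------------------------------------------
# Patient records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One patient's arm, diaries and raw QST measurements.

    Diary weeks are 7-element sequences of daily average-pain VAS values
    (0-10), None marking a missing day.  Threshold fields must be positive
    when present; cold-pressor time lies in (0, 180].
    """

    patient_id: str
    arm: str
    diary_baseline_week: tuple[Optional[float], ...]
    diary_final_week: tuple[Optional[float], ...]
    ppdt_pancreas: Optional[float]  # kPa
    ppdt_control: Optional[float]  # kPa
    epdt_pancreas: Optional[float]  # mA
    epdt_control: Optional[float]  # mA
    pptt_pre: Optional[float]  # kPa
    pptt_post: Optional[float]  # kPa
    cold_pressor_time: Optional[float]  # seconds

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        for week_name in ("diary_baseline_week", "diary_final_week"):
            week = getattr(self, week_name)
            if len(week) != 7:
                raise ValueError(f"{week_name} must have 7 entries, got {len(week)}")
            for v in week:
                if v is not None and not (0.0 <= v <= 10.0):
                    raise ValueError(f"{week_name} value {v} outside 0-10 VAS range")
        for name in (
            "ppdt_pancreas",
            "ppdt_control",
            "epdt_pancreas",
            "epdt_control",
            "pptt_pre",
            "pptt_post",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v}")
        t = self.cold_pressor_time
        if t is not None and not (0.0 < t <= COLD_PRESSOR_CEILING_S):
            raise ValueError(
                f"cold_pressor_time must lie in (0, {COLD_PRESSOR_CEILING_S}], got {t}"
            )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, arm_index: int, counter: int) -> np.random.Generator:
    # counter-based substream: patient i's stream depends only on
    # (seed, arm, i), so enlarging the cohort never reshuffles earlier draws
    return np.random.default_rng(np.random.SeedSequence((seed, arm_index, counter)))


def _draw_diary(
    rng: np.random.Generator,
    baseline_law: LogNormalParams,
    reduction_range: tuple[float, float],
    is_responder: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and final diary weeks consistent with the intended label.

    The final week is built so its mean equals baseline_mean*(1 - r/100)
    exactly (jitter is mean-centred); clipping to the VAS range can only
    push a non-responder further from the 30% boundary, and a constant-
    diary fallback covers the rare clip near zero for responders.
    """
    b = float(np.clip(baseline_law.rvs(rng), 0.3, 9.5))
    base_days = np.clip(b + rng.normal(0.0, DIARY_JITTER_SD, 7), 0.0, 10.0)
    base_mean = float(base_days.mean())
    if base_mean <= 0.05:
        base_days = np.full(7, b)
        base_mean = b

    r = float(rng.uniform(*reduction_range))
    target = base_mean * (1.0 - r / 100.0)

    jitter = rng.normal(0.0, DIARY_JITTER_SD, 7)
    final_days = target + jitter - jitter.mean()
    for _ in range(10):
        clipped = np.clip(final_days, 0.0, 10.0)
        drift = target - clipped.mean()
        if abs(drift) < 1e-12:
            final_days = clipped
            break
        final_days = clipped + drift
    else:
        final_days = np.clip(final_days, 0.0, 10.0)

    pct_reduction = 100.0 * (base_mean - final_days.mean()) / base_mean
    if (pct_reduction >= 30.0) != is_responder:
        # clipping pushed the mean across the boundary: fall back to a
        # constant final week at the target (always representable for the
        # side that matters)
        final_days = np.full(7, float(np.clip(target, 0.0, 10.0)))
        pct_reduction = 100.0 * (base_mean - final_days.mean()) / base_mean
        assert (pct_reduction >= 30.0) == is_responder
    return base_days, final_days


def _inject_missing(week: np.ndarray, rng: np.random.Generator, frac: float):
    days: list[Optional[float]] = []
    for v in week:
        if frac > 0 and rng.random() < frac:
            days.append(None)
        else:
            days.append(float(v))
    return tuple(days)


def generate_cohort(config: CohortConfig) -> tuple[list[PatientRecord], list[bool]]:
    """Generate the two-arm cohort plus the ground-truth responder flags.

    Responder counts per arm are fixed (round(rate*n)) and assigned by a
    seeded permutation.  Flags are aligned with the returned records.
    Deterministic: the same config (including seed) yields identical
    output.
    """
    records: list[PatientRecord] = []
    flags: list[bool] = []
    sizes = {"pregabalin": config.n_pregabalin, "placebo": config.n_placebo}
    for arm_index, arm in enumerate(ARMS):
        n = sizes[arm]
        n_resp = config.responder_count(arm)
        assign_rng = _patient_rng(config.seed, arm_index, 0)
        order = assign_rng.permutation(n)
        is_resp = np.zeros(n, dtype=bool)
        is_resp[order[:n_resp]] = True

        for i in range(n):
            rng = _patient_rng(config.seed, arm_index, i + 1)
            status = "responder" if is_resp[i] else "nonresponder"
            cal = config.feature_calibration[(arm, status)]

            laws = {
                name: (
                    calibrate_lognormal(cal[name])
                    if family == "lognormal"
                    else calibrate_normal(cal[name])
                )
                for name, family in _CALIBRATED_FEATURES.items()
            }

            # ratio features: control and ratio are the calibrated draws,
            # the pancreatic threshold is derived
            ppdt_control = float(laws["ppdt_control"].rvs(rng))
            ppdt_ratio = float(laws["ppdt_ratio"].rvs(rng))
            epdt_control = float(laws["epdt_control"].rvs(rng))
            epdt_ratio = float(laws["epdt_ratio"].rvs(rng))
            cold = float(min(laws["cold_pressor"].rvs(rng), COLD_PRESSOR_CEILING_S))
            # CPM must stay above -100% so the post threshold is positive
            cpm = float(np.clip(laws["cpm"].rvs(rng), -90.0, 400.0))
            pptt_pre = float(laws["pptt_pre"].rvs(rng))

            reduction_range = (
                config.responder_reduction_range
                if is_resp[i]
                else config.nonresponder_reduction_range
            )
            base_days, final_days = _draw_diary(
                rng, calibrate_lognormal(config.diary_baseline), reduction_range, bool(is_resp[i])
            )

            rec = PatientRecord(
                patient_id=f"{arm[:4]}-{i + 1:03d}",
                arm=arm,
                diary_baseline_week=_inject_missing(
                    base_days, rng, config.missing_diary_fraction
                ),
                diary_final_week=_inject_missing(
                    final_days, rng, config.missing_diary_fraction
                ),
                ppdt_pancreas=ppdt_ratio * ppdt_control,
                ppdt_control=ppdt_control,
                epdt_pancreas=epdt_ratio * epdt_control,
                epdt_control=epdt_control,
                pptt_pre=pptt_pre,
                pptt_post=pptt_pre * (1.0 + cpm / 100.0),
                cold_pressor_time=cold,
            )
            records.append(rec)
            flags.append(bool(is_resp[i]))
    return records, flags


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    ["patient_id", "arm"]
    + [f"d_base_{i}" for i in range(1, 8)]
    + [f"d_final_{i}" for i in range(1, 8)]
    + [
        "ppdt_pancreas_kpa",
        "ppdt_control_kpa",
        "epdt_pancreas_ma",
        "epdt_control_ma",
        "pptt_pre_kpa",
        "pptt_post_kpa",
        "cold_pressor_s",
    ]
)


def write_cohort(records: Sequence[PatientRecord], path) -> None:
    """Write records to CSV (header always present, missing = empty field)."""
    rows = []
    for r in records:
        row: dict[str, object] = {"patient_id": r.patient_id, "arm": r.arm}
        for i, v in enumerate(r.diary_baseline_week, start=1):
            row[f"d_base_{i}"] = v
        for i, v in enumerate(r.diary_final_week, start=1):
            row[f"d_final_{i}"] = v
        row["ppdt_pancreas_kpa"] = r.ppdt_pancreas
        row["ppdt_control_kpa"] = r.ppdt_control
        row["epdt_pancreas_ma"] = r.epdt_pancreas
        row["epdt_control_ma"] = r.epdt_control
        row["pptt_pre_kpa"] = r.pptt_pre
        row["pptt_post_kpa"] = r.pptt_post
        row["cold_pressor_s"] = r.cold_pressor_time
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def _cell(df_row: pd.Series, col: str, row_no: int) -> Optional[float]:
    v = df_row[col]
    if pd.isna(v):
        return None
    try:
        return float(v)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row_no}, column {col!r}: cannot parse {v!r}") from exc


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV; parse errors name the offending row and column."""
    df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV lacks columns: {missing_cols}")
    records = []
    for idx, row in df.iterrows():
        row_no = int(idx) + 1
        pid = row["patient_id"]
        if pd.isna(pid) or str(pid) == "":
            raise ValueError(f"row {row_no}, column 'patient_id': missing id")
        try:
            rec = PatientRecord(
                patient_id=str(pid),
                arm=str(row["arm"]),
                diary_baseline_week=tuple(
                    _cell(row, f"d_base_{i}", row_no) for i in range(1, 8)
                ),
                diary_final_week=tuple(
                    _cell(row, f"d_final_{i}", row_no) for i in range(1, 8)
                ),
                ppdt_pancreas=_cell(row, "ppdt_pancreas_kpa", row_no),
                ppdt_control=_cell(row, "ppdt_control_kpa", row_no),
                epdt_pancreas=_cell(row, "epdt_pancreas_ma", row_no),
                epdt_control=_cell(row, "epdt_control_ma", row_no),
                pptt_pre=_cell(row, "pptt_pre_kpa", row_no),
                pptt_post=_cell(row, "pptt_post_kpa", row_no),
                cold_pressor_time=_cell(row, "cold_pressor_s", row_no),
            )
        except ValueError as exc:
            raise ValueError(f"row {row_no}: {exc}") from exc
        records.append(rec)
    return records
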