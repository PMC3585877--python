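"""End-to-end orchestration: simulate/ingest -> label -> features -> report.

The pipeline mirrors the study's analysis surfaces: per-protocol
responder labelling, per-arm group-comparison tables, per-arm LOO
screening of the eight QST predictors, and a final threshold fit for the
best feature of each arm.  The two arms are analysed independently — a
drug-response predictor and a placebo-response predictor are different
questions — and all randomness flows from the single cohort seed, so a
rerun with the same configuration is byte-identical (the manifest, which
carries wall-clock timestamps, is the one file excluded from that
guarantee).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .endpoints import DEFAULT_MIN_DAYS, label_cohort, per_protocol_filter
from .exact_stats import compare_groups
from .qst_features import FEATURE_NAMES, feature_table
from .synthetic_cohort import (
    ARMS,
    CohortConfig,
    PatientRecord,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .threshold_classifier import final_fit_report, screen_features

__all__ = ["RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: inputs, digests, timestamps."""

    seed: Optional[int]
    config_hash: Optional[str]
    package_version: str
    started: str
    finished: str = ""
    file_digests: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    outdir,
    config: Optional[CohortConfig] = None,
    cohort_csv=None,
    min_days: int = DEFAULT_MIN_DAYS,
    alpha: float = 0.05,
) -> dict:
    """Run the full analysis and write the report bundle to ``outdir``.

    Exactly one cohort source must be given: a :class:`CohortConfig`
    (synthetic cohort, seeded by ``config.seed``) or a cohort CSV path.
    The bundle contains ``cohort.csv``, ``labels.csv``, ``features.csv``,
    per-arm comparison tables (``table_<arm>.csv``), per-arm
    ``screening_<arm>.json`` and ``model_<arm>.json``, a ``summary.json``
    with the headline accuracy/sensitivity/specificity per arm, and a
    ``manifest.json``.  Returns the summary dictionary.
    """
    if (config is None) == (cohort_csv is None):
        raise ValueError("provide exactly one of config or cohort_csv")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=config.seed if config is not None else None,
        config_hash=(
            hashlib.sha256(repr(config).encode()).hexdigest() if config is not None else None
        ),
        package_version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    # stage 1: cohort
    if config is not None:
        records, _ = generate_cohort(config)
        cohort_path = outdir / "cohort.csv"
        write_cohort(records, cohort_path)
    else:
        cohort_path = Path(cohort_csv)
        records = read_cohort(cohort_path)
    logger.info("cohort: %d patients (%s)", len(records),
                "simulated" if config is not None else "ingested")

    # stage 2: endpoint labels and per-protocol filter
    labels_df = label_cohort(records, min_days=min_days)
    labels_df.to_csv(outdir / "labels.csv", index=False)
    evaluable, excluded = per_protocol_filter(records, min_days=min_days)
    logger.info("labels: %d evaluable, %d excluded", len(evaluable), len(excluded))

    # stage 3: features for evaluable patients
    feats = feature_table(evaluable)
    feats.to_csv(outdir / "features.csv")
    logger.info("features: %d patients x %d features", *feats.shape)

    eval_labels = labels_df.set_index("patient_id").loc[feats.index]
    summary: dict = {
        "n_total": len(records),
        "n_evaluable": len(evaluable),
        "excluded": excluded,
        "arms": {},
    }

    # stage 4: per-arm comparisons, screening and final fit
    for arm in ARMS:
        arm_mask = (eval_labels["arm"] == arm).to_numpy()
        if arm_mask.sum() == 0:
            continue
        arm_feats = feats.loc[arm_mask]
        arm_resp = eval_labels.loc[arm_mask, "responder"].astype(bool).to_numpy()
        n_resp = int(arm_resp.sum())
        logger.info("%s arm: %d patients, %d responders", arm, len(arm_feats), n_resp)
        if n_resp == 0 or n_resp == len(arm_feats):
            summary["arms"][arm] = {
                "n": int(len(arm_feats)),
                "n_responders": n_resp,
                "note": "single-class arm: screening not applicable",
            }
            continue

        table = compare_groups(arm_feats, arm_resp)
        table.to_csv(outdir / f"table_{arm}.csv", index=False)

        screening = screen_features(arm_feats, arm_resp, alpha=alpha)
        _write_json(outdir / f"screening_{arm}.json", screening.to_dict())

        best = screening.best_feature
        vals = arm_feats[best].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        report = final_fit_report(vals[mask], arm_resp[mask], feature_name=best)
        _write_json(outdir / f"model_{arm}.json", report.model.to_dict())

        summary["arms"][arm] = {
            "n": int(len(arm_feats)),
            "n_responders": n_resp,
            "best_feature": best,
            "best_loo_accuracy": screening.per_feature[best].loo_accuracy,
            "best_loo_p_value": screening.per_feature[best].p_value,
            "above_chance_features": sorted(
                name for name, fs in screening.per_feature.items() if fs.above_chance
            ),
            "final_threshold": report.model.threshold,
            "final_orientation": report.model.orientation,
            "final_accuracy": report.accuracy,
            "final_sensitivity": report.sensitivity,
            "final_specificity": report.specificity,
            "final_p_value": report.p_value,
        }
        logger.info(
            "%s arm: best=%s LOO acc=%.1f%% final acc=%.1f%% threshold=%.2f",
            arm, best, 100 * screening.per_feature[best].loo_accuracy,
            100 * report.accuracy, report.model.threshold,
        )

    _write_json(outdir / "summary.json", summary)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.file_digests = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest.write(outdir / "manifest.json")
    return summary
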