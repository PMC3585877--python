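"""Single-feature max-margin threshold classification with LOO screening.

A linear support-vector machine on one feature reduces to a cut point:
everything on one side is called responder, everything on the other
non-responder.  This module implements that reduction exactly rather
than through a quadratic-program solver: candidate cuts are the
midpoints of adjacent distinct sorted values plus the two infinite
sentinels (constant predictions), both orientations are tried, and the
winner minimises training misclassifications with ties broken by the
larger margin (distance from the cut to the nearest training value),
then the smaller cut, then the low-is-responder orientation.  The search
is deterministic, dependency-free and auditable, and a generic
soft-margin solver serves as a cross-check in the test suite only.

Predictive power of a feature is estimated by leave-one-out
cross-validation: each patient is predicted by a threshold trained on
the remaining patients, and screening accuracy is correct/total.
Whether a feature classifies above chance is judged against the
binomial chance level — the smallest accuracy whose exceedance
probability under majority-class guessing falls below alpha — with the
two-sided Fisher's exact test on the LOO confusion matrix reported
alongside as the discrimination significance.

Conventions (pinned, configurable where noted):

* a value exactly at the threshold classifies to the non-responder side;
* infinite-cut (majority-vote) models carry margin 0, so any finite
  separating cut is preferred among equally erroneous candidates;
* patients missing a feature are dropped from that feature's screening
  only (pairwise deletion).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .exact_stats import Table2x2, fisher_exact_two_sided
from .qst_features import FEATURE_NAMES

__all__ = [
    "ORIENT_LOW",
    "ORIENT_HIGH",
    "ThresholdModel",
    "ConfusionMatrix",
    "FeatureScreen",
    "ScreeningResult",
    "FinalFitReport",
    "fit_threshold",
    "predict",
    "loo_evaluate",
    "screen_features",
    "final_fit_report",
]

logger = logging.getLogger(__name__)

ORIENT_LOW = "low_is_responder"
ORIENT_HIGH = "high_is_responder"


@dataclass(frozen=True)
class ThresholdModel:
    """A fitted single-feature threshold rule.

    ``orientation`` says which side of the cut is the responder side;
    with ``low_is_responder`` a patient is predicted responder iff the
    feature value is strictly below the threshold.  An infinite
    threshold encodes a constant (majority-vote) prediction.
    """

    feature_name: str
    threshold: float
    orientation: str
    margin: float
    training_errors: int

    def __post_init__(self) -> None:
        if self.orientation not in (ORIENT_LOW, ORIENT_HIGH):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")

    def to_dict(self) -> dict:
        return {
            "feature": self.feature_name,
            "threshold": self.threshold,
            "orientation": self.orientation,
            "margin": self.margin,
            "training_errors": self.training_errors,
        }


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary prediction; tp = responder predicted responder."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.fp + self.tn)

    def as_table(self) -> Table2x2:
        return Table2x2(self.tp, self.fn, self.fp, self.tn)


def fit_threshold(
    values: Sequence[float],
    labels: Sequence[bool],
    feature_name: str = "feature",
    _warn: bool = True,
) -> ThresholdModel:
    """Exact minimum-error, maximum-margin threshold on one feature.

    Searches every candidate cut (midpoints of adjacent distinct sorted
    values plus the infinite sentinels) under both orientations and
    returns the lexicographic optimum of (training errors, -margin, cut,
    orientation), with ``low_is_responder`` preferred at full ties.  When
    only one class is present the fit degenerates to a majority vote
    (infinite threshold), reported with a warning.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.size == 0:
        raise ValueError("cannot fit a threshold on an empty sample")
    if v.shape != y.shape:
        raise ValueError("values and labels must align")
    if not np.isfinite(v).all():
        raise ValueError("feature values must be finite")

    if y.all() or not y.any():
        if _warn:
            warnings.warn(
                f"{feature_name}: only one class present; degenerating to a "
                "majority vote",
                stacklevel=2,
            )
        threshold = math.inf if y.all() else -math.inf
        return ThresholdModel(feature_name, threshold, ORIENT_LOW, 0.0, 0)

    order = np.argsort(v, kind="stable")
    vs = v[order]
    ys = y[order]
    n = vs.size
    n_resp = int(ys.sum())
    n_non = n - n_resp

    # cum_resp[i] = responders among the i smallest values; a cut at
    # position i places those i values below it
    cum_resp = np.concatenate([[0], np.cumsum(ys)])
    pos = np.arange(n + 1)
    errors_low = (n_resp - cum_resp) + (pos - cum_resp)  # responder iff below cut
    errors_high = cum_resp + (n_non - (pos - cum_resp))  # responder iff above cut

    interior = np.nonzero(np.diff(vs) > 0)[0] + 1  # cut positions between distinct values
    cuts = np.empty(n + 1)
    margins = np.zeros(n + 1)
    cuts[0], cuts[n] = -math.inf, math.inf
    cuts[interior] = 0.5 * (vs[interior - 1] + vs[interior])
    margins[interior] = 0.5 * (vs[interior] - vs[interior - 1])
    valid = np.concatenate([[0], interior, [n]])
    # margins enter the tie-break rounded to 1e-9 (far below measurement
    # resolution) so last-ulp float noise cannot decide between cuts
    margin_key = np.round(margins[valid], 9)

    best: Optional[tuple] = None
    for orient_rank, (orient, errs) in enumerate(
        [(ORIENT_LOW, errors_low), (ORIENT_HIGH, errors_high)]
    ):
        e = errs[valid]
        i = int(np.lexsort((cuts[valid], -margin_key, e))[0])
        key = (int(e[i]), -float(margin_key[i]), float(cuts[valid][i]), orient_rank)
        if best is None or key < best[0]:
            best = (key, orient, float(margins[valid][i]))
    key, orient, margin = best
    errors, _, cut, _ = key
    return ThresholdModel(feature_name, cut, orient, margin, errors)


def predict(model: ThresholdModel, value: Optional[float]) -> Optional[bool]:
    """Apply a fitted threshold to one value.

    A value exactly at the threshold classifies as non-responder.  A
    missing value yields None (no prediction).
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if model.orientation == ORIENT_LOW:
        return bool(value < model.threshold)
    return bool(value > model.threshold)


def loo_evaluate(
    values: Sequence[float],
    labels: Sequence[bool],
    feature_name: str = "feature",
) -> tuple[ConfusionMatrix, float]:
    """Leave-one-out evaluation of the threshold rule on one feature.

    Runs exactly n folds; fold i fits on the other n-1 patients and
    predicts patient i.  Folds whose training sample loses a whole class
    degenerate to a majority vote, silently.  Returns the pooled
    confusion matrix and accuracy = correct/n.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.size < 3:
        raise ValueError("leave-one-out needs at least 3 patients")
    tp = fn = fp = tn = 0
    mask = np.ones(v.size, dtype=bool)
    for i in range(v.size):
        mask[i] = False
        model = fit_threshold(v[mask], y[mask], feature_name, _warn=False)
        pred = predict(model, float(v[i]))
        mask[i] = True
        if y[i] and pred:
            tp += 1
        elif y[i]:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    cm = ConfusionMatrix(tp, fn, fp, tn)
    return cm, cm.accuracy


@dataclass(frozen=True)
class FeatureScreen:
    """LOO screening outcome for one feature.

    ``p_value`` is the two-sided Fisher test on the LOO confusion matrix
    (the reported significance); ``above_chance`` comes from the
    calibrated chance-level criterion, with ``chance_level`` the minimal
    accuracy it flags and ``chance_p_value`` the binomial exceedance
    probability of the observed correct count.
    """

    feature_name: str
    confusion: ConfusionMatrix
    loo_accuracy: float
    p_value: float
    above_chance: bool
    n_used: int
    chance_level: float
    chance_p_value: float

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "loo_accuracy": self.loo_accuracy,
            "confusion": [c.tp, c.fn, c.fp, c.tn],
            "p_value": self.p_value,
            "above_chance": self.above_chance,
            "n_used": self.n_used,
            "chance_level": self.chance_level,
            "chance_p_value": self.chance_p_value,
        }


@dataclass(frozen=True)
class ScreeningResult:
    """Per-feature screening table plus the winning feature.

    ``best_feature`` maximises LOO accuracy; ties resolve to the smaller
    Fisher p-value, then to the canonical screening order of the eight
    predictors (unknown features sort after them, in table order).
    """

    per_feature: dict[str, FeatureScreen]
    best_feature: str

    def to_dict(self) -> dict:
        out = {name: fs.to_dict() for name, fs in self.per_feature.items()}
        out["best_feature"] = self.best_feature
        return out


def chance_level_accuracy(n: int, prevalence: float, alpha: float) -> float:
    """Minimal LOO accuracy that beats chance at the given alpha.

    Chance performance is modelled as n Bernoulli(prevalence) guesses of
    the majority class; the chance level is the smallest k/n whose
    binomial exceedance probability falls below alpha.
    """
    k = int(_sps.binom.isf(alpha, n, prevalence))
    while k <= n and _sps.binom.sf(k - 1, n, prevalence) >= alpha:
        k += 1
    return k / n


def screen_features(
    feature_table: pd.DataFrame,
    labels: Sequence[bool],
    alpha: float = 0.05,
) -> ScreeningResult:
    """Screen every feature column for predictive power by LOO.

    Patients missing a feature are dropped from that feature's screening
    only.  A feature with fewer than 3 usable patients, or with all
    values missing, is skipped with a warning.

    ``above_chance`` asks whether the number of correct LOO
    classifications exceeds what guessing could achieve: a one-sided
    binomial exceedance test against the majority-class prevalence.
    When more than 5 features are screened the stricter multiplicity
    alpha of 0.01 applies, as for the group comparisons.  The two-sided
    Fisher p on the LOO confusion matrix is reported alongside, but does
    not drive the flag — the LOO folds are dependent and an uninformative
    feature's threshold is systematically wrong about the held-out
    patient, so the Fisher test is badly anti-conservative under the
    null, in both directions.
    """
    if feature_table.shape[1] < 2:
        raise ValueError("screening needs at least 2 features")
    y = np.asarray(labels, dtype=bool)
    if y.shape[0] != len(feature_table):
        raise ValueError("labels must align with feature rows")

    from .exact_stats import MULTIPLICITY_VARIABLE_LIMIT

    alpha_chance = 0.01 if feature_table.shape[1] > MULTIPLICITY_VARIABLE_LIMIT else alpha

    results: dict[str, FeatureScreen] = {}
    for col in feature_table.columns:
        vals = feature_table[col].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        n_used = int(mask.sum())
        if n_used < 3:
            warnings.warn(f"feature {col!r}: only {n_used} usable values, skipped", stacklevel=2)
            continue
        if n_used < mask.size:
            logger.info("feature %s: dropping %d patients with missing values",
                        col, mask.size - n_used)
        cm, acc = loo_evaluate(vals[mask], y[mask], feature_name=str(col))
        res = fisher_exact_two_sided(cm.as_table(), alpha=alpha)
        y_used = y[mask]
        prevalence = float(max(y_used.mean(), 1.0 - y_used.mean()))
        correct = cm.tp + cm.tn
        chance_p = float(_sps.binom.sf(correct - 1, cm.n, prevalence))
        results[str(col)] = FeatureScreen(
            feature_name=str(col),
            confusion=cm,
            loo_accuracy=acc,
            p_value=res.p_value,
            above_chance=bool(chance_p < alpha_chance),
            n_used=n_used,
            chance_level=chance_level_accuracy(cm.n, prevalence, alpha_chance),
            chance_p_value=chance_p,
        )
    if not results:
        raise ValueError("no feature had enough usable values to screen")

    canonical = {name: i for i, name in enumerate(FEATURE_NAMES)}
    table_order = {name: i for i, name in enumerate(results)}

    def sort_key(name: str):
        fs = results[name]
        return (
            -fs.loo_accuracy,
            fs.p_value,
            canonical.get(name, len(canonical)),
            table_order[name],
        )

    best = min(results, key=sort_key)
    return ScreeningResult(per_feature=results, best_feature=best)


@dataclass(frozen=True)
class FinalFitReport:
    """Threshold fitted on all patients with resubstitution performance."""

    model: ThresholdModel
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    p_value: float

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "model": self.model.to_dict(),
            "confusion": [c.tp, c.fn, c.fp, c.tn],
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "p_value": self.p_value,
        }


def final_fit_report(
    values: Sequence[float],
    labels: Sequence[bool],
    feature_name: str = "feature",
) -> FinalFitReport:
    """Fit the threshold on all patients and report its operating point.

    The confusion matrix comes from resubstitution (the same patients
    that trained the cut), matching how a single published operating
    point is usually quoted; the honest generalisation estimate is the
    LOO screening accuracy.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    model = fit_threshold(v, y, feature_name)
    preds = np.array([predict(model, float(x)) for x in v], dtype=bool)
    cm = ConfusionMatrix(
        tp=int((y & preds).sum()),
        fn=int((y & ~preds).sum()),
        fp=int((~y & preds).sum()),
        tn=int((~y & ~preds).sum()),
    )
    res = fisher_exact_two_sided(cm.as_table())
    return FinalFitReport(
        model=model,
        confusion=cm,
        accuracy=cm.accuracy,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        p_value=res.p_value,
    )
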