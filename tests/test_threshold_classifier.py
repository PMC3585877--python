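"""Max-margin threshold fitting, LOO evaluation and feature screening."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy.optimize import brentq

import qst_predict as qp
from qst_predict.threshold_classifier import ORIENT_HIGH, ORIENT_LOW

from _oracles import threshold_oracle


def _random_instance(rng, n=None):
    n = n if n is not None else int(rng.integers(2, 13))
    # duplicated values appear with positive probability to exercise ties
    vals = np.round(rng.normal(0, 1, n), 1)
    labs = rng.random(n) < 0.5
    if labs.all():
        labs[0] = False
    elif not labs.any():
        labs[0] = True
    return vals, labs


class TestFitThreshold:
    def test_separable_sample_midpoint_cut(self):
        vals = [1.0, 1.1, 1.2, 1.8, 1.9, 2.0]
        labs = [True, True, True, False, False, False]
        m = qp.fit_threshold(vals, labs)
        assert m.threshold == pytest.approx(1.5)
        assert m.orientation == ORIENT_LOW
        assert m.training_errors == 0
        assert m.margin == pytest.approx(0.3)

    def test_single_class_degenerates_to_majority(self):
        with pytest.warns(UserWarning, match="one class"):
            m = qp.fit_threshold([1.0, 2.0, 3.0], [True, True, True])
        assert math.isinf(m.threshold) and m.training_errors == 0
        assert qp.predict(m, 99.0) is True

    def test_overlapping_sample_matches_exhaustive_search(self):
        vals = [1.1, 1.3, 1.45, 1.5, 1.6, 1.7]
        labs = [True, True, False, True, False, False]
        m = qp.fit_threshold(vals, labs)
        errors, margin, cut, orient = threshold_oracle(vals, labs)
        assert (m.training_errors, m.margin, m.threshold, m.orientation) == (
            errors,
            pytest.approx(margin),
            pytest.approx(cut),
            orient,
        )

    def test_oracle_equivalence_random_instances(self, rng):
        """Exhaustive search over all cuts and orientations agrees with the
        scan for random small instances, including ties and duplicates."""
        for _ in range(300):
            vals, labs = _random_instance(rng)
            m = qp.fit_threshold(vals, labs)
            errors, margin, cut, orient = threshold_oracle(list(vals), list(labs))
            assert m.training_errors == errors
            assert m.margin == pytest.approx(margin)
            assert m.threshold == pytest.approx(cut)
            assert m.orientation == orient

    def test_resubstitution_beats_majority_prevalence(self, rng):
        """The infinite sentinel cut is always a candidate, so training
        accuracy can never fall below the majority-class prevalence."""
        for _ in range(200):
            vals, labs = _random_instance(rng)
            m = qp.fit_threshold(vals, labs)
            prevalence = max(labs.mean(), 1 - labs.mean())
            acc = 1 - m.training_errors / len(vals)
            assert acc >= prevalence - 1e-12

    def test_permutation_invariance(self, rng):
        vals, labs = _random_instance(rng, n=12)
        m1 = qp.fit_threshold(vals, labs)
        p = rng.permutation(len(vals))
        m2 = qp.fit_threshold(vals[p], labs[p])
        assert m1.threshold == m2.threshold and m1.orientation == m2.orientation

    def test_agrees_with_soft_margin_svm_on_separable_data(self):
        """On linearly separable 1-D data a hard-margin linear SVM's decision
        boundary is the max-margin midpoint; cross-check with sklearn."""
        from sklearn.svm import SVC

        vals = np.array([0.8, 1.0, 1.15, 1.7, 1.85, 2.1])
        labs = np.array([True, True, True, False, False, False])
        m = qp.fit_threshold(vals, labs)
        svc = SVC(kernel="linear", C=1e6).fit(vals.reshape(-1, 1), labs)
        boundary = -svc.intercept_[0] / svc.coef_[0][0]
        assert m.threshold == pytest.approx(boundary, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qp.fit_threshold([], [])


class TestPredict:
    def test_published_operating_point_orientation(self):
        """At the published cut of 1.41 (low ratio = responder) the group
        medians 1.2 and 1.6 classify to opposite sides."""
        m = qp.ThresholdModel("epdt_ratio", 1.41, ORIENT_LOW, 0.1, 0)
        assert qp.predict(m, 1.2) is True
        assert qp.predict(m, 1.6) is False

    def test_boundary_value_is_non_responder(self):
        m = qp.ThresholdModel("epdt_ratio", 1.41, ORIENT_LOW, 0.1, 0)
        assert qp.predict(m, 1.41) is False
        m_hi = qp.ThresholdModel("epdt_ratio", 1.41, ORIENT_HIGH, 0.1, 0)
        assert qp.predict(m_hi, 1.41) is False

    def test_missing_value_gives_no_prediction(self):
        m = qp.ThresholdModel("f", 1.0, ORIENT_LOW, 0.1, 0)
        assert qp.predict(m, None) is None
        assert qp.predict(m, float("nan")) is None


class TestLooEvaluate:
    def test_widely_separated_classes_perfect(self):
        vals = np.r_[np.linspace(0.9, 1.1, 8), np.linspace(5.0, 5.4, 7)]
        labs = np.array([True] * 8 + [False] * 7)
        cm, acc = qp.loo_evaluate(vals, labs)
        assert acc == 1.0 and cm.n == 15

    def test_null_feature_accuracy_near_prevalence(self, rng):
        """With labels independent of values, LOO accuracy stays within
        binomial noise of (actually at or below) the class prevalence."""
        n = 200
        vals = rng.normal(size=n)
        labs = rng.random(n) < 0.55
        _, acc = qp.loo_evaluate(vals, labs)
        prevalence = max(labs.mean(), 1 - labs.mean())
        assert acc <= prevalence + 2 * math.sqrt(prevalence * (1 - prevalence) / n)

    def test_folds_match_hand_run_oracle(self):
        vals = [1.1, 1.3, 1.45, 1.5, 1.6, 1.7]
        labs = [True, True, False, True, False, False]
        cm, acc = qp.loo_evaluate(vals, labs)
        correct = 0
        for i in range(6):
            rest_v = vals[:i] + vals[i + 1 :]
            rest_l = labs[:i] + labs[i + 1 :]
            errors, margin, cut, orient = threshold_oracle(rest_v, rest_l)
            pred = vals[i] < cut if orient == ORIENT_LOW else vals[i] > cut
            correct += pred == labs[i]
        assert acc == pytest.approx(correct / 6)

    def test_monotone_transform_leaves_fold_predictions_unchanged(self, rng):
        vals = rng.lognormal(0.2, 0.3, 20)
        labs = rng.random(20) < 0.5
        labs[0], labs[1] = True, False
        cm1, acc1 = qp.loo_evaluate(vals, labs)
        cm2, acc2 = qp.loo_evaluate(np.log(vals), labs)  # strictly monotone
        assert (cm1.tp, cm1.fn, cm1.fp, cm1.tn) == (cm2.tp, cm2.fn, cm2.fp, cm2.tn)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            qp.loo_evaluate([1.0, 2.0], [True, False])


class TestScreenFeatures:
    def _screen_frame(self, rng, n=60):
        labs = np.array([True] * (n // 2) + [False] * (n - n // 2))
        df = pd.DataFrame(
            {
                "informative": np.where(labs, rng.normal(0, 1, n), rng.normal(3, 1, n)),
                "noise_a": rng.normal(size=n),
                "noise_b": rng.normal(size=n),
            }
        )
        return df, labs

    def test_informative_feature_wins(self, rng):
        df, labs = self._screen_frame(rng)
        res = qp.screen_features(df, labs)
        assert res.best_feature == "informative"
        assert res.per_feature["informative"].above_chance
        assert not res.per_feature["noise_a"].above_chance

    def test_constant_feature_majority_accuracy(self, rng):
        labs = np.array([True] * 20 + [False] * 12)
        df = pd.DataFrame({"const": np.ones(32), "noise": rng.normal(size=32)})
        res = qp.screen_features(df, labs)
        assert res.per_feature["const"].loo_accuracy == pytest.approx(20 / 32)

    def test_all_missing_feature_skipped_with_warning(self, rng):
        df, labs = self._screen_frame(rng)
        df["all_nan"] = np.nan
        with pytest.warns(UserWarning, match="all_nan"):
            res = qp.screen_features(df, labs)
        assert "all_nan" not in res.per_feature

    def test_pairwise_deletion_per_feature(self, rng):
        df, labs = self._screen_frame(rng)
        df.loc[df.index[:5], "noise_a"] = np.nan
        res = qp.screen_features(df, labs)
        assert res.per_feature["noise_a"].n_used == len(df) - 5
        assert res.per_feature["informative"].n_used == len(df)

    def test_single_feature_rejected(self, rng):
        df, labs = self._screen_frame(rng)
        with pytest.raises(ValueError):
            qp.screen_features(df[["informative"]], labs)


class TestFinalFitReport:
    def test_perfectly_separable_cohort(self):
        vals = np.r_[np.linspace(1.0, 1.2, 16), np.linspace(1.6, 2.0, 15)]
        labs = np.array([True] * 16 + [False] * 15)
        rep = qp.final_fit_report(vals, labs)
        assert rep.accuracy == 1.0
        assert rep.p_value < 1e-6

    def test_confusion_metrics_consistency(self, rng):
        vals = rng.normal(size=31)
        labs = np.array([True] * 16 + [False] * 15)
        rep = qp.final_fit_report(vals, labs)
        c = rep.confusion
        assert c.n == 31
        assert rep.accuracy == pytest.approx((c.tp + c.tn) / 31)
        assert rep.sensitivity == pytest.approx(c.tp / 16)
        assert rep.specificity == pytest.approx(c.tn / 15)

    def test_large_sample_threshold_near_density_crossing(self):
        """Two log-normal classes with medians 1.2 and 1.6: the fitted
        min-error threshold converges to the equal-density crossing."""
        r_law = qp.calibrate_lognormal(qp.MedianIQR(1.2, 0.9, 1.3))
        n_law = qp.calibrate_lognormal(qp.MedianIQR(1.6, 1.5, 2.0))
        crossing = brentq(
            lambda x: st.lognorm.pdf(x, r_law.scale, scale=math.exp(r_law.location))
            - st.lognorm.pdf(x, n_law.scale, scale=math.exp(n_law.location)),
            1.2,
            1.6,
        )
        rng = np.random.default_rng(11)
        vals = np.concatenate([r_law.rvs(rng, 1000), n_law.rvs(rng, 1000)])
        labs = np.array([True] * 1000 + [False] * 1000)
        m = qp.fit_threshold(vals, labs)
        assert m.orientation == ORIENT_LOW
        assert m.threshold == pytest.approx(crossing, abs=0.12)
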