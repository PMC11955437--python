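"""Discrimination/calibration/decision-curve metrics vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from habitatmri.evaluation import (calibration_and_brier, confusion_metrics,
                                   decision_curve, delong_paired_test,
                                   roc_auc_delong, shapley_attributions)


def auc_bruteforce(scores, labels):
    """Concordant-pair counting with half-credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def delong_var_bruteforce(scores, labels):
    """DeLong variance from explicitly enumerated structural components."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    psi = lambda x, y: 1.0 if x > y else (0.5 if x == y else 0.0)
    v10 = np.array([np.mean([psi(p, q) for q in neg]) for p in pos])
    v01 = np.array([np.mean([psi(p, q) for p in pos]) for q in neg])
    return v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)


class TestAUC:
    def test_perfect_ranking(self):
        r = roc_auc_delong([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_hand_example(self):
        r = roc_auc_delong([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == 0.75

    def test_complement_symmetry(self):
        rng = np.random.default_rng(0)
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = roc_auc_delong(s, y).auc
        b = roc_auc_delong(1 - s, y).auc
        assert a + b == pytest.approx(1.0)

    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(8, 30)
            s = np.round(rng.random(n), 1)  # force ties
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            r = roc_auc_delong(s, y)
            assert r.auc == pytest.approx(auc_bruteforce(s, y), abs=1e-9)
            assert r.variance == pytest.approx(delong_var_bruteforce(s, y), abs=1e-9)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(2)
        r = roc_auc_delong(rng.random(50), rng.integers(0, 2, 50))
        assert r.ci[0] <= r.auc <= r.ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_delong([0.1, 0.2], [1, 1])


class TestDeLongPaired:
    def test_model_vs_itself(self):
        rng = np.random.default_rng(3)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        z, p = delong_paired_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        z, p = delong_paired_test(s, 1 / (1 + np.exp(-5 * s)), y)
        assert p == 1.0


class TestConfusion:
    def test_all_correct(self):
        m = confusion_metrics([0.9, 0.9, 0.1], [1, 1, 0])
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_hand_counts(self):
        scores = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        m = confusion_metrics(scores, labels)
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 1, 6)
        assert m.precision == pytest.approx(2 / 3)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.8)

    def test_no_predicted_positives_flagged(self):
        m = confusion_metrics([0.1, 0.2], [0, 1], threshold=0.9)
        assert m.precision == 0.0 and m.precision_undefined


class TestCalibration:
    def test_perfect_probabilities_zero_brier(self):
        _, brier = calibration_and_brier([0.0, 1.0, 1.0, 0.0, 1.0],
                                         [0, 1, 1, 0, 1], n_bins=2)
        assert brier == 0.0

    def test_constant_half_score(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        _, brier = calibration_and_brier(np.full(50, 0.5), y, n_bins=2)
        assert brier == 0.25

    def test_well_calibrated_curve_near_identity(self):
        rng = np.random.default_rng(6)
        p = rng.random(5000)
        y = (rng.random(5000) < p).astype(int)
        curve, _ = calibration_and_brier(p, y, n_bins=5)
        assert np.abs(curve["mean_score"] - curve["event_rate"]).max() < 0.05


class TestDecisionCurve:
    def test_treat_none_is_zero(self):
        rng = np.random.default_rng(7)
        dc = decision_curve(rng.random(40), rng.integers(0, 2, 40))
        assert (dc["treat_none"] == 0).all()

    def test_perfect_model_net_benefit_is_prevalence(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        dc = decision_curve(y.astype(float), y, thresholds=[0.2, 0.5, 0.8])
        assert np.allclose(dc["net_benefit"], 0.2)

    def test_low_threshold_approaches_prevalence(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 200)
        dc = decision_curve(np.full(200, 0.99), y, thresholds=[0.001])
        assert dc["net_benefit"].iloc[0] == pytest.approx(y.mean(), abs=1e-2)

    def test_never_beats_perfect_classifier(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 100)
        s = np.clip(y + rng.normal(0, 0.4, 100), 0, 1)
        model = decision_curve(s, y)["net_benefit"]
        perfect = decision_curve(y.astype(float), y)["net_benefit"]
        assert (model <= perfect + 1e-12).all()


class TestShapley:
    def _linear(self, w):
        return lambda X: np.asarray(X) @ np.asarray(w)

    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(10)
        w = np.array([1.0, -2.0, 0.5])
        bg = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        X = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        rep = shapley_attributions(self._linear(w), X, bg,
                                   n_permutations=400, seed=0)
        expected = (X - bg.mean()) * w
        assert np.abs(rep.values - expected).to_numpy().max() < 0.15

    def test_ignored_feature_gets_no_credit(self):
        rng = np.random.default_rng(11)
        bg = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=list("abc"))
        rep = shapley_attributions(self._linear([1.0, 0.0, 1.0]), X, bg,
                                   n_permutations=100, seed=1)
        assert np.abs(rep.values["b"]).max() < 1e-9

    def test_efficiency_within_three_mc_se(self):
        rng = np.random.default_rng(12)
        w = rng.normal(size=4)
        score = lambda X: np.tanh(np.asarray(X) @ w)  # non-linear model
        bg = pd.DataFrame(rng.normal(size=(60, 4)))
        X = pd.DataFrame(rng.normal(size=(6, 4)))
        rep = shapley_attributions(score, X, bg, n_permutations=150, seed=2)
        tol = 3 * rep.mc_se + 1e-9
        assert (rep.efficiency_gap.abs() <= tol + 0.05).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        bg = pd.DataFrame(rng.normal(size=(30, 2)))
        X = pd.DataFrame(rng.normal(size=(3, 2)))
        f = self._linear([1.0, 1.0])
        a = shapley_attributions(f, X, bg, n_permutations=50, seed=9)
        b = shapley_attributions(f, X, bg, n_permutations=50, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)
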