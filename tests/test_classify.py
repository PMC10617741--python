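"""Logistic regression, stepwise refinement, ROC/LOOCV evaluation."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import fallrisk as fr

from conftest import make_table


def pair_count_auc(scores, labels):
    """Brute-force AUC: concordant pairs / (n1 n2), ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        rep = fr.roc_auc(np.r_[np.arange(5) + 10.0, np.arange(5)], labels)
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 31))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            rep = fr.roc_auc(scores, labels)
            assert rep.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_null_scores_near_half(self, rng):
        aucs = [
            fr.roc_auc(rng.standard_normal(60), np.r_[np.ones(21), np.zeros(39)].astype(int)).auc
            for _ in range(20)
        ]
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1

    def test_constant_scores_flagged(self):
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        rep = fr.roc_auc(np.ones(10), labels)
        assert rep.degenerate and rep.auc == pytest.approx(0.5)

    def test_youden_point_is_internally_consistent(self, rng):
        scores = rng.standard_normal(40)
        labels = (scores + rng.standard_normal(40) > 0).astype(int)
        rep = fr.roc_auc(scores, labels)
        j_at_cutoff = rep.sensitivity + rep.specificity - 1
        assert j_at_cutoff == pytest.approx(float(np.max(rep.tpr - rep.fpr)), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fr.roc_auc([1.0, 2.0], [1, 1])


class TestConfusion:
    def test_extreme_cutoffs(self):
        labels = np.r_[np.ones(4), np.zeros(6)].astype(int)
        scores = np.arange(10.0)
        low = fr.confusion_at(scores, labels, -np.inf)
        assert low["sensitivity"] == 1.0 and low["specificity"] == 0.0
        high = fr.confusion_at(scores, labels, np.inf)
        assert high["sensitivity"] == 0.0 and high["specificity"] == 1.0

    def test_published_counts_round_to_printed_rates(self):
        # 18/21 fallers and 28/39 non-fallers correct -> 86% / 72%
        assert round(18 / 21 * 100) == 86
        labels = np.r_[np.ones(21), np.zeros(39)].astype(int)
        scores = np.r_[np.ones(18), np.zeros(3), np.ones(11), np.zeros(28)]
        rep = fr.confusion_at(scores, labels, 0.5)
        assert round(rep["sensitivity"] * 100) == 86
        assert round(rep["specificity"] * 100) == 72


class TestLogistic:
    def test_intercept_only_closed_form(self):
        t = make_table(
            np.zeros((60, 1)) + np.arange(60)[:, None],  # unused variable
            group=["faller"] * 21 + ["non_faller"] * 39,
        )
        rep = fr.logistic_fit(t, [])
        assert rep.coefficients["const"] == pytest.approx(np.log(21 / 39), abs=1e-8)
        assert np.allclose(rep.fitted_probabilities, 21 / 60, atol=1e-8)
        assert rep.mcfadden_r2 == pytest.approx(0.0, abs=1e-10)

    def test_duplicated_predictor_rejected(self, rng):
        x = rng.standard_normal((30, 1))
        t = make_table(np.hstack([x, x]), names=["a", "b"])
        with pytest.raises(ValueError, match="rank"):
            fr.logistic_fit(t, ["a", "b"])

    def test_matches_sklearn_unpenalized(self, rng):
        x = rng.standard_normal((80, 3))
        logits = 0.8 * x[:, 0] - 1.1 * x[:, 2] + 0.3
        y = (rng.random(80) < 1 / (1 + np.exp(-logits))).astype(int)
        t = make_table(
            x, group=["faller" if v else "non_faller" for v in y],
            names=["a", "b", "c"],
        )
        rep = fr.logistic_fit(t, ["a", "b", "c"])
        ref = LogisticRegression(C=np.inf, max_iter=2000, tol=1e-10).fit(x, y)
        assert rep.coefficients["const"] == pytest.approx(float(ref.intercept_[0]), abs=1e-6)
        for nm, c in zip(["a", "b", "c"], ref.coef_[0]):
            assert rep.coefficients[nm] == pytest.approx(float(c), abs=1e-6)

    def test_vif_detects_collinearity(self, rng):
        x = rng.standard_normal((60, 2))
        third = x[:, 0] + 0.05 * rng.standard_normal(60)
        t = make_table(np.column_stack([x, third]), names=["a", "b", "c"])
        rep = fr.logistic_fit(t, ["a", "b", "c"])
        assert rep.vif["a"] > 10 and rep.vif["c"] > 10 and rep.vif["b"] < 2

    def test_mcfadden_monotone_under_nesting(self, rng):
        x = rng.standard_normal((70, 4))
        y = (x[:, 0] + 0.5 * x[:, 1] + rng.standard_normal(70) > 0).astype(int)
        t = make_table(
            x, group=["faller" if v else "non_faller" for v in y],
            names=list("abcd"),
        )
        full = fr.logistic_fit(t, list("abcd"))
        for sub in (["a"], ["a", "b"], ["b", "c", "d"]):
            assert full.mcfadden_r2 >= fr.logistic_fit(t, sub).mcfadden_r2 - 1e-10


class TestStepwise:
    def test_pure_noise_reduces_to_intercept(self, rng):
        x = rng.standard_normal((60, 5))
        t = make_table(x, group=["faller"] * 21 + ["non_faller"] * 39,
                       names=list("abcde"))
        rep = fr.stepwise_backward(t, list("abcde"), "bic")
        assert rep.predictors == []

    def test_signal_predictors_retained(self, rng):
        n = 120
        x = rng.standard_normal((n, 10))
        logits = 2.0 * x[:, 0] - 2.0 * x[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        t = make_table(
            x, group=["faller" if v else "non_faller" for v in y],
            names=[f"v{j}" for j in range(10)],
        )
        rep = fr.stepwise_backward(t, [f"v{j}" for j in range(10)], "aic")
        assert {"v0", "v1"} <= set(rep.predictors)

    def test_criterion_not_worse_than_full_model(self, rng):
        x = rng.standard_normal((60, 6))
        y = (x[:, 0] + rng.standard_normal(60) > 0).astype(int)
        t = make_table(
            x, group=["faller" if v else "non_faller" for v in y],
            names=[f"v{j}" for j in range(6)],
        )
        full = fr.logistic_fit(t, [f"v{j}" for j in range(6)])
        refined = fr.stepwise_backward(t, [f"v{j}" for j in range(6)], "aic")
        assert refined.aic <= full.aic + 1e-10


class TestLoocv:
    def test_separable_data_near_perfect(self, signal_table):
        acc, bad = fr.loocv_accuracy(signal_table, ["v1"])
        assert acc > 0.9

    def test_null_data_near_majority_rate(self, rng):
        t = make_table(
            rng.standard_normal((60, 2)),
            group=["faller"] * 21 + ["non_faller"] * 39,
        )
        acc, _ = fr.loocv_accuracy(t, ["v1", "v2"])
        assert abs(acc - 0.65) < 0.2

    def test_deterministic(self, signal_table):
        a = fr.loocv_accuracy(signal_table, ["v1", "v2"])
        b = fr.loocv_accuracy(signal_table, ["v1", "v2"])
        assert a == b


class TestScoreClassifiers:
    def test_plsca_classifier_signal_and_null(self, signal_table, rng):
        rep = fr.plsca_classifier(signal_table, signal_table.names)
        assert rep.auc > 0.95
        null = make_table(
            rng.standard_normal((60, 5)),
            group=["faller"] * 21 + ["non_faller"] * 39,
        )
        rep0 = fr.plsca_classifier(null, null.names)
        assert rep0.auc >= 0.5  # orientation convention
        assert rep0.auc < 0.8

    def test_rf_classifier_signal(self, signal_table):
        rep = fr.rf_classifier(signal_table, signal_table.names, n_trees=300, seed=0)
        assert rep.auc > 0.9
        rep2 = fr.rf_classifier(signal_table, signal_table.names, n_trees=300, seed=0)
        assert rep2.auc == rep.auc  # deterministic at fixed seed
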