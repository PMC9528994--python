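"""Splits, ridge classifier, metrics, DeLong, DCA, statistical tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fwlomics.modeling import (
    ExperimentConfig,
    classification_metrics,
    cohort_characteristics,
    decision_curve,
    delong_ci,
    fit_ridge_classifier,
    paired_model_comparison,
    ridge_solve,
    roc_auc,
    stratified_splits,
)


class TestSplits:
    def test_126_patients_test_31(self):
        labels = np.array([1] * 64 + [0] * 62)
        ids = np.arange(126)
        cfg = ExperimentConfig(n_splits=10, seed=0)
        for tr, te in stratified_splits(ids, labels, cfg):
            assert te.size == 16 + 15  # floor(64/4) + floor(62/4)
            assert tr.size == 126 - 31

    def test_disjoint_and_stratified(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(40) > 0.5).astype(int)
        cfg = ExperimentConfig(n_splits=5, seed=1)
        for tr, te in stratified_splits(np.arange(40), labels, cfg):
            assert np.intersect1d(tr, te).size == 0
            assert np.union1d(tr, te).size == 40
            assert len(np.unique(labels[te])) == 2

    def test_same_seed_identical(self):
        labels = np.array([0, 1] * 20)
        cfg = ExperimentConfig(n_splits=4, seed=9)
        a = stratified_splits(np.arange(40), labels, cfg)
        b = stratified_splits(np.arange(40), labels, cfg)
        for (t1, e1), (t2, e2) in zip(a, b):
            np.testing.assert_array_equal(t1, t2)
            np.testing.assert_array_equal(e1, e2)

    def test_tiny_class_rejected(self):
        labels = np.array([0] * 10 + [1])
        with pytest.raises(ValueError):
            stratified_splits(np.arange(11), labels, ExperimentConfig())


class TestRidge:
    def test_normal_equation_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        for alpha in (0.1, 1.0, 10.0):
            w = ridge_solve(X, y, alpha)
            oracle = np.linalg.solve(X.T @ X + alpha * np.eye(2), X.T @ y)
            np.testing.assert_allclose(w, oracle, rtol=1e-10)

    def test_shrinkage_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        norms = [np.linalg.norm(ridge_solve(X, y, a)) for a in (0.01, 1, 100, 1000)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_perfect_1d_feature_training_auc_one(self):
        y = np.array([0] * 10 + [1] * 10)
        X = y.reshape(-1, 1).astype(float)
        model = fit_ridge_classifier(X, y, folds=5)
        assert roc_auc(model.decision(X), y) == 1.0

    def test_agrees_with_sklearn_ridge(self):
        # independent oracle: sklearn Ridge on the same standardized data
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        y = (rng.random(40) > 0.5).astype(int)
        alpha = 2.5
        model = fit_ridge_classifier(X, y, alpha_grid=[alpha], folds=5)
        Z = (X - model.mean) / model.scale
        ref = Ridge(alpha=alpha, fit_intercept=True).fit(Z, 2.0 * y - 1.0)
        np.testing.assert_allclose(model.coef, ref.coef_, rtol=1e-8)
        np.testing.assert_allclose(model.intercept, ref.intercept_, rtol=1e-8)


class TestMetrics:
    def test_perfect_ordering(self):
        m = classification_metrics(np.array([-2.0, -1.0, 1.0, 2.0]), np.array([0, 0, 1, 1]))
        assert all(v == 1.0 for v in m.values())

    def test_constant_score_auc_half(self):
        assert roc_auc(np.zeros(10), np.array([0, 1] * 5)) == 0.5

    def test_auc_equals_concordant_pair_fraction(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        # exhaustive pair enumeration oracle
        conc = total = 0.0
        for i, j in itertools.product(range(4), repeat=2):
            if labels[i] == 1 and labels[j] == 0:
                total += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
        assert roc_auc(scores, labels) == pytest.approx(conc / total)

    @pytest.mark.parametrize("seed", range(3))
    def test_auc_matches_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        scores = rng.normal(size=50).round(1)  # ties included
        labels = (rng.random(50) > 0.4).astype(int)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4, dtype=int))


class TestDeLong:
    def test_perfect_separation(self):
        out = delong_ci(np.array([1.0, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1]))
        assert out["auc"] == 1.0 and out["variance"] == 0.0

    def test_null_ci_covers_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=400)
        labels = (rng.random(400) > 0.5).astype(int)
        out = delong_ci(scores, labels)
        lo, hi = out["ci"]
        assert lo < 0.5 < hi

    def test_variance_agrees_with_bootstrap(self):
        rng = np.random.default_rng(5)
        labels = np.array([0, 1] * 20)
        scores = rng.normal(size=40) + labels
        out = delong_ci(scores, labels, n_boot=2000, seed=1)
        assert out["bootstrap_variance"] == pytest.approx(out["variance"], rel=0.35)

    def test_matches_per_point_oracle(self):
        # brute-force placement values via explicit loops
        rng = np.random.default_rng(6)
        labels = (rng.random(30) > 0.5).astype(int)
        scores = rng.normal(size=30)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
        v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
        var = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
        out = delong_ci(scores, labels)
        assert out["auc"] == pytest.approx(v10.mean())
        assert out["variance"] == pytest.approx(var)


class TestDecisionCurve:
    def test_formula_example(self):
        # n = 10, TP = 3, FP = 1 at pt = 0.2 -> NB = 0.3 - 0.1 * 0.25
        probs = np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        labels = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        out = decision_curve(probs, labels, thresholds=np.array([0.2]))
        assert out["net_benefit"].iloc[0] == pytest.approx(0.3 - 0.1 * 0.25)

    def test_treat_all_limit_and_treat_none(self):
        labels = np.array([1, 0, 1, 0, 1])
        probs = np.full(5, 0.5)
        out = decision_curve(probs, labels, thresholds=np.array([0.001, 0.3]))
        assert out["treat_all"].iloc[0] == pytest.approx(labels.mean(), abs=1e-2)
        assert (out["treat_none"] == 0).all()

    def test_pt_one_excluded(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([1]), thresholds=np.array([1.0]))


class TestPairedComparison:
    def test_identical_vectors_p_one(self):
        a = np.arange(10.0)
        assert paired_model_comparison(a, a.copy()) == 1.0

    def test_constant_shift_p_small(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=30)
        b = a + 1.0 + rng.normal(scale=1e-3, size=30)
        assert paired_model_comparison(a, b) < 1e-10

    def test_matches_scipy_oracle(self):
        a = np.array([0.7, 0.8, 0.75, 0.9, 0.65, 0.7, 0.85, 0.8, 0.72, 0.78])
        b = np.array([0.68, 0.82, 0.7, 0.85, 0.6, 0.72, 0.8, 0.79, 0.7, 0.75])
        assert paired_model_comparison(a, b) == pytest.approx(stats.ttest_rel(a, b).pvalue)


class TestCohortCharacteristics:
    def test_identical_distributions_p_one(self):
        cov = pd.DataFrame({"g": ["M"] * 10 + ["F"] * 10})
        labels = np.array([0, 1] * 10)
        p = cohort_characteristics(cov, labels)
        assert p["g"] == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # table {{20,10},{10,20}} -> chi2 = sum (O-E)^2/E with E = 15
        g = ["a"] * 30 + ["b"] * 30
        y = np.array([0] * 20 + [1] * 10 + [0] * 10 + [1] * 20)
        p = cohort_characteristics(pd.DataFrame({"g": g}), y)
        chi2 = 4 * (20 - 15) ** 2 / 15
        assert p["g"] == pytest.approx(stats.chi2.sf(chi2, 1))

    def test_continuous_null_uniformish(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            cov = pd.DataFrame({"age": rng.normal(60, 10, size=100)})
            labels = (rng.random(100) > 0.5).astype(int)
            pvals.append(cohort_characteristics(cov, labels)["age"])
        # KS against uniform
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
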