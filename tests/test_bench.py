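"""Metric primitives against brute-force oracles; tuning and evaluation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from sklearn.metrics import roc_auc_score

import telepain as tp
from telepain import bench as B


class TestFeatures:
    def test_metastasis_excluded(self, real218):
        X, _ = B.features(real218)
        assert "metastatic" not in X.columns
        assert "n_televisits" not in X.columns
        assert set(X.columns) == set(B.FEATURE_NUMERIC) | set(B.FEATURE_CATEGORICAL)

    def test_outcome_fraction_matches_visits(self, real218):
        _, y = B.features(real218)
        assert y.mean() == (real218["n_televisits"] > 1).mean()

    def test_design_width(self, real218):
        X, _ = B.features(real218)
        from telepain.preprocess import fit_encoding, encode

        emap = fit_encoding(
            X, numeric=B.FEATURE_NUMERIC, categorical=B.FEATURE_CATEGORICAL, drop_first=True
        )
        M, _ = encode(X, emap)
        # 2 numerics + (2-1) + (12-1) + 4 binaries with one level dropped
        assert M.shape[1] == 2 + 1 + 11 + 4


class TestF1:
    def test_boundary_values(self):
        assert B.f1(1.0, 1.0) == 1.0
        assert B.f1(0.5, 0.0) == 0.0
        assert B.f1(0.0, 0.0) == 0.0

    def test_all_positive_classifier_at_prevalence(self):
        # a model that labels everyone positive has recall 1 and precision
        # equal to the test-set prevalence
        assert round(B.f1(0.575, 1.0), 3) == 0.730
        assert round(B.f1(0.57, 1.0), 1) == 0.7

    def test_harmonic_mean_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p, r = rng.random(2)
            assert B.f1(p, r) == pytest.approx(2 * p * r / (p + r) if p + r else 0.0)


class TestAccuracyCI:
    def test_boundaries(self):
        assert B.accuracy_ci(10, 10)[1] == 1.0
        assert B.accuracy_ci(0, 10)[0] == 0.0

    def test_published_rf_row(self):
        lo, hi = B.accuracy_ci(70, 87)
        assert round(lo, 1) == 0.7
        assert round(hi, 2) == 0.88

    def test_beta_quantile_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 200))
            c = int(rng.integers(0, n + 1))
            lo, hi = B.accuracy_ci(c, n)
            o_lo = st.beta.ppf(0.025, c, n - c + 1) if c else 0.0
            o_hi = st.beta.ppf(0.975, c + 1, n - c) if c < n else 1.0
            assert (lo, hi) == pytest.approx((o_lo, o_hi))
            assert lo <= c / n <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            B.accuracy_ci(1, 0)
        with pytest.raises(ValueError):
            B.accuracy_ci(5, 3)


class TestAccVsNir:
    def test_no_evidence_at_the_rate(self):
        assert B.acc_vs_nir(50, 100, 0.5) > 0.4

    def test_overwhelming_evidence(self):
        assert B.acc_vs_nir(87, 87, 0.5) < 1e-20

    def test_exact_binomial_tail_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(5, 120))
            c = int(rng.integers(0, n + 1))
            nir = float(rng.uniform(0.2, 0.8))
            tail = sum(st.binom.pmf(k, n, nir) for k in range(c, n + 1))
            assert B.acc_vs_nir(c, n, nir) == pytest.approx(tail, abs=1e-9)
        assert B.acc_vs_nir(70, 87, 0.505) < 0.01


class TestRocAuc:
    def test_perfect_and_example(self):
        assert B.roc_auc([0.9, 0.8, 0.3], [1, 1, 0]) == 1.0
        assert B.roc_auc([0.1, 0.9], [1, 0]) == 0.0

    def test_null_distribution(self):
        rng = np.random.default_rng(3)
        aucs = []
        for _ in range(500):
            scores = rng.random(200)
            labels = rng.integers(0, 2, 200)
            if labels.min() == labels.max():
                continue
            aucs.append(B.roc_auc(scores, labels))
        assert 0.48 <= np.mean(aucs) <= 0.52

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert B.roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            B.roc_auc([0.2, 0.4], [1, 1])


class TestTune:
    def test_single_point_grid_selected(self, real218):
        X, y = B.features(real218)
        spec = B.default_specs()[2]  # gbm
        model = B.tune(spec, X, y, k=2, repeats=1, seed=0)
        assert model.spec.params == spec.params

    def test_deterministic(self, real218):
        X, y = B.features(real218)
        spec = B.default_specs()[0]
        a = B.tune(spec, X, y, k=2, repeats=1, seed=5)
        b = B.tune(spec, X, y, k=2, repeats=1, seed=5)
        assert a.cv_accuracy == b.cv_accuracy
        assert a.spec.params == b.spec.params

    def test_empty_grid_rejected(self, real218):
        X, y = B.features(real218)
        with pytest.raises(ValueError):
            B.tune(B.default_specs()[0], X, y, grid=[], k=2, repeats=1)

    def test_separable_data_learned_by_elastic(self, real218):
        # outcome perfectly determined by breakthrough pain; the shrinkage
        # grid runs strongest-first so CV must pick a weaker penalty
        X, _ = B.features(real218)
        y = X["btcp"].to_numpy().astype(int)
        grid = [{"alpha": 0.0, "lam": lam} for lam in (0.25, 0.01, 1e-4)]
        model = B.tune(B.default_specs()[0], X, y, grid=grid, k=5, repeats=1, seed=0)
        assert model.spec.params["lam"] < 0.25
        assert model.cv_accuracy >= 0.95


class _ConstantModel:
    """Always predicts the positive class (probability 1)."""

    def predict(self, X):
        return np.ones(len(X), dtype=int)

    def predict_proba_more(self, X):
        return np.ones(len(X))

    class spec:
        label = "const"


class TestEvaluate:
    def test_all_positive_model_panel(self, real218):
        X, _ = B.features(real218)
        n = 40
        X_te = X.iloc[:n].reset_index(drop=True)
        y_te = np.array([0, 1] * (n // 2))
        rep = B.evaluate(_ConstantModel(), X_te, np.ones(n, dtype=int), X_te, y_te)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.acc_test == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(B.f1(0.5, 1.0))

    def test_report_contract(self, real218):
        X, y = B.features(real218)
        model = B.tune(B.default_specs()[0], X.iloc[:150], y[:150], k=2, repeats=1, seed=0)
        rep = B.evaluate(model, X.iloc[:150], y[:150], X.iloc[150:], y[150:])
        row = rep.as_row()
        for key in ("AUC", "ACC_TR", "ACC_TST", "L", "U", "P", "SENS", "SPEC", "F1"):
            assert 0.0 <= row[key] <= 1.0
        assert rep.ci_low <= rep.acc_test <= rep.ci_high

    def test_empty_test_rejected(self, real218):
        X, y = B.features(real218)
        with pytest.raises(ValueError):
            B.evaluate(_ConstantModel(), X, y, X.iloc[:0], y[:0])


def test_signal_detected_by_every_classifier():
    """With the encoded age and pain effects, all four models beat chance."""
    pooled = tp.sample_cohort(tp.default_spec(n=2000), seed=20)
    table, _ = B.run_bench(pooled, seed=20, k=2, repeats=1)
    assert (table["AUC_TST"] > 0.5).all(), table[["Classifier", "AUC_TST"]]
    assert list(table["Classifier"]) == ["LASSO", "RF", "GBM", "ANN"]
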