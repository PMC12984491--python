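import numpy as np
import pandas as pd
import pytest

from cardiovcg.ml_eval import (
    MlEvalError,
    _FoldScaler,
    auc_pr,
    auc_roc,
    evaluate_task,
    fit_gradient_boosting,
    fit_l1_logistic,
    missingness_prepare,
    stratified_oof_probabilities,
    youden_threshold,
)


class TestMissingnessPrepare:
    def test_drop_three_worst_ties_alphabetical(self):
        n = 10
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(n, 5)),
                          columns=["a", "b", "c", "d", "e"])
        df.loc[:2, "c"] = np.nan   # 3 missing
        df.loc[:1, "b"] = np.nan   # 2 missing
        df.loc[:1, "e"] = np.nan   # 2 missing
        df.loc[0, "a"] = np.nan    # 1 missing
        subset = missingness_prepare(df, k_drop=3)
        assert subset.dropped_features == ["c", "b", "e"]
        assert subset.feature_names == ["a", "d"]
        # row 0 still missing 'a' -> excluded
        assert 0 in subset.excluded_records
        assert len(subset.record_ids) == n - 1

    def test_no_missing_unchanged(self):
        df = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        subset = missingness_prepare(df)
        assert subset.dropped_features == []
        assert subset.feature_names == list("abcd")
        assert len(subset.record_ids) == 5

    def test_all_rows_excluded_errors(self):
        df = pd.DataFrame({"a": [np.nan] * 4, "b": [np.nan] * 4,
                           "c": [np.nan] * 4, "d": [np.nan] * 4, "e": [np.nan] * 4})
        with pytest.raises(MlEvalError):
            missingness_prepare(df, k_drop=3)


class TestL1Logistic:
    def test_perfect_separation(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.uniform(-2, -0.1, 50), rng.uniform(0.1, 2, 50)].reshape(-1, 1)
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        model = fit_l1_logistic(x, y)
        assert model.coef_[0, 0] > 0
        assert (model.predict(x) == y).mean() == 1.0

    def test_noise_feature_shrunk(self):
        rng = np.random.default_rng(2)
        n = 200
        signal = rng.normal(0, 1, n)
        y = (signal + rng.normal(0, 0.3, n) > 0).astype(int)
        noise = rng.normal(0, 1, n)
        X = np.column_stack([signal, noise])
        X = (X - X.mean(0)) / X.std(0)
        model = fit_l1_logistic(X, y, inverse_reg=0.1)
        unreg = fit_l1_logistic(X, y, inverse_reg=1e6)
        assert abs(model.coef_[0, 1]) < 1e-3
        assert abs(unreg.coef_[0, 1]) > abs(model.coef_[0, 1])

    def test_duplicated_feature_weight_split(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(0, 1, n)
        y = (x + rng.normal(0, 0.5, n) > 0).astype(int)
        single = fit_l1_logistic(x.reshape(-1, 1), y)
        double = fit_l1_logistic(np.column_stack([x, x]), y)
        assert double.coef_[0].sum() == pytest.approx(single.coef_[0, 0], abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(MlEvalError):
            fit_l1_logistic(np.zeros((10, 2)), np.zeros(10, dtype=int))


class TestGradientBoosting:
    def test_xor(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (400, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        model = fit_gradient_boosting(X, y)
        p = model.predict_proba(X)[:, 1]
        assert auc_roc(y, p) > 0.99

    def test_permutation_null(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (400, 5))
        y = rng.permutation(np.r_[np.zeros(200), np.ones(200)]).astype(int)
        proba, _ = stratified_oof_probabilities("gradient_boosting", X, y, seed=11)
        assert 0.43 <= auc_roc(y, proba) <= 0.57

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (100, 3))
        y = (rng.uniform(size=100) > 0.5).astype(int)
        m1 = fit_gradient_boosting(X, y, seed=7)
        m2 = fit_gradient_boosting(X, y, seed=7)
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))


class TestStratifiedOof:
    def test_balanced_tiny_folds(self):
        X = np.arange(20).reshape(10, 2).astype(float)
        y = np.array([0, 1] * 5)
        proba, folds = stratified_oof_probabilities("l1_logistic", X, y, k=5, seed=1)
        for f in range(5):
            assert np.sum((folds == f) & (y == 1)) == 1
            assert np.sum((folds == f) & (y == 0)) == 1

    def test_each_record_exactly_once(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        proba, folds = stratified_oof_probabilities("l1_logistic", X, y, seed=2)
        assert np.all(folds >= 0)
        assert not np.any(np.isnan(proba))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 4))
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        p1, f1 = stratified_oof_probabilities("l1_logistic", X, y, seed=3)
        p2, f2 = stratified_oof_probabilities("l1_logistic", X, y, seed=3)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(p1, p2)

    def test_minority_smaller_than_k_rejected(self):
        X = np.zeros((10, 2))
        y = np.r_[np.zeros(8), np.ones(2)].astype(int)
        with pytest.raises(MlEvalError):
            stratified_oof_probabilities("l1_logistic", X, y, k=5)

    def test_no_leakage_of_training_statistics(self):
        """Perturbing test-fold rows must not change training-fold transforms."""
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 4))
        y = np.r_[np.zeros(25), np.ones(25)].astype(int)
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for tr, te in skf.split(X, y):
            base = _FoldScaler().fit(X[tr])
            X_pert = X.copy()
            X_pert[te] += 1000.0
            pert = _FoldScaler().fit(X_pert[tr])
            np.testing.assert_array_equal(base.mean_, pert.mean_)
            np.testing.assert_array_equal(base.sd_, pert.sd_)


class TestAucMetrics:
    def test_trivial(self):
        assert auc_roc([0, 1], [0.2, 0.9]) == 1.0

    def test_four_point_example(self):
        assert auc_roc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_equals_u_statistic(self):
        from cardiovcg.group_stats import mann_whitney_u

        rng = np.random.default_rng(11)
        for _ in range(100):
            n1, n0 = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            pos = rng.normal(0.5, 1, n1)
            neg = rng.normal(0, 1, n0)
            y = np.r_[np.ones(n1), np.zeros(n0)].astype(int)
            p = np.r_[pos, neg]
            u, _ = mann_whitney_u(pos, neg)
            assert auc_roc(y, p) == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_single_class_missing(self):
        assert auc_roc([1, 1], [0.5, 0.6]) is None
        assert auc_pr([0, 0], [0.5, 0.6]) is None

    def test_auc_pr_perfect(self):
        assert auc_pr([0, 1, 1], [0.1, 0.8, 0.9]) == pytest.approx(1.0)


class TestYouden:
    def test_trivial(self):
        tau, sens, spec = youden_threshold([0, 1], [0.2, 0.9])
        assert sens == 1.0 and spec == 1.0

    def test_tie_takes_lowest_threshold(self):
        tau, sens, spec = youden_threshold([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert tau == pytest.approx(0.35)
        assert sens == 1.0
        assert spec == pytest.approx(0.5)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p = rng.uniform(size=n)
            tau, sens, spec = youden_threshold(y, p)
            best_j, best_tau = -np.inf, None
            for cand in sorted(np.unique(p)):
                pred = p >= cand
                s1 = np.sum(pred & (y == 1)) / np.sum(y == 1)
                s0 = np.sum(~pred & (y == 0)) / np.sum(y == 0)
                j = s1 + s0 - 1
                if j > best_j:
                    best_j, best_tau = j, cand
            assert tau == pytest.approx(best_tau)
            assert sens + spec - 1 == pytest.approx(best_j)


class TestEvaluateTask:
    def _feature_table(self, rng, n_per=60, sep=3.0):
        pos = rng.normal(sep, 1, (n_per, 4))
        neg = rng.normal(0, 1, (n_per, 4))
        X = np.vstack([pos, neg])
        ids = [f"r{i}" for i in range(2 * n_per)]
        features = pd.DataFrame(X, index=ids, columns=["a", "b", "c", "d"])
        labels = pd.Series(["HCM"] * n_per + ["DCM-I"] * n_per, index=ids)
        return features, labels

    def test_separable_task(self):
        rng = np.random.default_rng(13)
        features, labels = self._feature_table(rng)
        result = evaluate_task(features, labels, "HCM_vs_DCM-I", "l1_logistic", seed=5)
        assert result.auc_roc_pooled >= 0.95
        assert result.n == 120
        assert 0 <= result.sensitivity <= 1 and 0 <= result.specificity <= 1

    def test_label_permutation_null(self):
        rng = np.random.default_rng(14)
        features, labels = self._feature_table(rng, n_per=100, sep=0.0)
        result = evaluate_task(features, labels, "HCM_vs_DCM-I", "l1_logistic", seed=1)
        assert 0.43 <= result.auc_roc_pooled <= 0.57

    def test_roundtrip_serialization(self):
        from cardiovcg.ml_eval import CvResult

        rng = np.random.default_rng(15)
        features, labels = self._feature_table(rng)
        result = evaluate_task(features, labels, "HCM_vs_DCM-I", "gradient_boosting", seed=7)
        back = CvResult.from_json(result.to_json())
        assert back.auc_roc_pooled == result.auc_roc_pooled
        assert back.fold_assignments == result.fold_assignments

    def test_hocm_task_restricts_to_top_15(self):
        rng = np.random.default_rng(16)
        n_per = 40
        X = rng.normal(0, 1, (2 * n_per, 20))
        X[:n_per, 0] += 2.0
        ids = [f"r{i}" for i in range(2 * n_per)]
        features = pd.DataFrame(X, index=ids, columns=[f"f{i}" for i in range(20)])
        labels = pd.Series(["HOCM"] * n_per + ["HNCM"] * n_per, index=ids)
        result = evaluate_task(features, labels, "HOCM_vs_HNCM", "l1_logistic", seed=8)
        assert result.n == 2 * n_per
        assert result.auc_roc_pooled > 0.7

    def test_unknown_task(self):
        with pytest.raises(MlEvalError):
            evaluate_task(pd.DataFrame({"a": [1.0]}), pd.Series(["x"]), "nope", "l1_logistic")
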