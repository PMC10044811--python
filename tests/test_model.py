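import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from liporadiomics import model as M


def _toy_table(n_per_class=34, n_features=5, shift=2.0, seed=0, ids_prefix="c"):
    """Feature table with one informative feature and noise columns."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    y = np.array(["benign"] * n_per_class + ["malignant"] * n_per_class)
    X[y == "malignant", 0] += shift
    cols = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "label", y)
    df.index = [f"{ids_prefix}{i:03d}" for i in range(n)]
    return df, cols


def newton_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent unpenalized logistic MLE via damped Newton iterations."""
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    w = np.zeros(p + 1)
    for _ in range(max_iter):
        mu = expit(Z @ w)
        grad = Z.T @ (y - mu)
        hess = Z.T @ (Z * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(hess + 1e-12 * np.eye(p + 1), grad)
        w = w + step
        if np.abs(step).max() < tol:
            break
    return w[1:], w[0]


class TestMakeSplit:
    def test_68_lesions_split_48_20(self):
        df, _ = _toy_table(n_per_class=34)
        df = df.iloc[: 68]
        # relabel to the 38/30 composition
        labels = ["benign"] * 38 + ["malignant"] * 30
        df = df.copy()
        df["label"] = labels
        plan = M.make_split(df, ratio=0.7, folds=10, seed=1)
        assert len(plan.learning_ids) == 48
        assert len(plan.testing_ids) == 20
        # folds partition the learning set, stratified by class
        assert set(plan.fold_assignment) == set(plan.learning_ids)
        assert set(plan.fold_assignment.values()) == set(range(1, 11))

    def test_same_seed_same_plan(self):
        df, _ = _toy_table()
        assert M.make_split(df, seed=3) == M.make_split(df, seed=3)

    def test_ratio_one_raises(self):
        df, _ = _toy_table()
        with pytest.raises(M.SplitError):
            M.make_split(df, ratio=1.0)

    def test_class_too_small_for_folds_raises(self):
        df, _ = _toy_table(n_per_class=6)
        with pytest.raises(M.SplitError, match="stratify"):
            M.make_split(df, ratio=0.7, folds=10)


class TestFitLassoLogistic:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(60) < 0.3).astype(float)
        lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
        beta, b0 = M.fit_lasso_logistic(X, y, lam_max * 1.01)
        assert np.all(beta == 0)
        assert b0 == pytest.approx(np.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_lambda_zero_matches_newton_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        X = (X - X.mean(0)) / X.std(0)
        logits = 0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(200) < expit(logits)).astype(float)
        beta, b0 = M.fit_lasso_logistic(X, y, 0.0)
        beta_ref, b0_ref = newton_logistic(X, y)
        np.testing.assert_allclose(beta, beta_ref, atol=1e-4)
        assert b0 == pytest.approx(b0_ref, abs=1e-4)

    @pytest.mark.parametrize("lam_frac", [0.5, 0.1, 0.02])
    def test_kkt_conditions(self, lam_frac):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 12))
        X = (X - X.mean(0)) / X.std(0)
        logits = X[:, 0] - 0.7 * X[:, 1]
        y = (rng.random(120) < expit(logits)).astype(float)
        lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
        lam = lam_frac * lam_max
        beta, b0 = M.fit_lasso_logistic(X, y, lam)
        p = expit(b0 + X @ beta)
        score = X.T @ (y - p) / len(y)
        active = beta != 0
        assert np.all(np.abs(score[~active]) <= lam + 1e-6)
        assert np.allclose(score[active], lam * np.sign(beta[active]), atol=1e-6)
        assert abs((y - p).mean()) <= 1e-6

    def test_sparse_recovery_with_noise_features(self):
        rng = np.random.default_rng(3)
        n = 200
        X = rng.normal(size=(n, 10))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(n) < expit(2.5 * X[:, 0])).astype(float)
        lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
        beta, _ = M.fit_lasso_logistic(X, y, 0.3 * lam_max)
        assert beta[0] != 0
        assert (beta[1:] == 0).sum() >= 7

    def test_matches_sklearn_l1_solver(self):
        """Independent cross-check: liblinear solves the same objective with
        C = 1 / (n * lam)."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(4)
        X = rng.normal(size=(150, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(150) < expit(X[:, 0] - X[:, 2])).astype(float)
        lam = 0.05
        beta, b0 = M.fit_lasso_logistic(X, y, lam)
        # saga leaves the intercept unpenalized, matching our objective
        ref = LogisticRegression(
            penalty="l1", C=1.0 / (len(y) * lam), solver="saga", tol=1e-8,
            max_iter=100000,
        ).fit(X, y)
        np.testing.assert_allclose(beta, ref.coef_[0], atol=2e-3)
        assert b0 == pytest.approx(float(ref.intercept_[0]), abs=2e-3)

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            M.fit_lasso_logistic(np.zeros((4, 1)), np.array([0, 1, 0, 1.0]), -1.0)


class TestCVSelectLambda:
    def test_perfect_feature_reaches_zero_cv_error(self):
        df, cols = _toy_table(n_per_class=30, shift=8.0, seed=5)
        df["f_dup"] = df["f0"]  # duplicated perfectly separating feature
        plan = M.make_split(df, folds=5, seed=5)
        path = M.cv_select_lambda(df, plan, cols + ["f_dup"])
        assert path.cv_error_mean.min() == 0.0

    def test_permuted_labels_track_class_prior_error(self):
        rng = np.random.default_rng(6)
        df, cols = _toy_table(n_per_class=50, shift=0.0, seed=6)
        df["label"] = rng.permutation(df["label"].to_numpy())
        plan = M.make_split(df, folds=5, seed=6)
        path = M.cv_select_lambda(df, plan, cols)
        chosen_err = path.cv_error_mean[
            np.flatnonzero(path.lambda_grid == path.chosen_lambda)[0]
        ]
        prior_err = 0.5  # balanced classes
        assert abs(chosen_err - prior_err) <= 0.1

    def test_grid_of_length_one(self):
        df, cols = _toy_table(seed=7)
        plan = M.make_split(df, folds=5, seed=7)
        path = M.cv_select_lambda(df, plan, cols, lambda_grid=np.array([0.123]))
        assert path.chosen_lambda == 0.123

    def test_ties_resolve_to_larger_lambda(self):
        df, cols = _toy_table(n_per_class=30, shift=8.0, seed=8)
        plan = M.make_split(df, folds=5, seed=8)
        path = M.cv_select_lambda(df, plan, cols)
        ties = path.lambda_grid[path.cv_error_mean == path.cv_error_mean.min()]
        assert path.chosen_lambda == ties.max()


class TestFinalModel:
    def test_refit_is_deterministic(self):
        df, cols = _toy_table(seed=9)
        plan = M.make_split(df, folds=5, seed=9)
        a = M.finalize(df, plan, cols, 0.05)
        b = M.finalize(df, plan, cols, 0.05)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        assert a.intercept == b.intercept

    def test_selected_features_are_nonzero_support(self):
        df, cols = _toy_table(seed=10, shift=3.0)
        plan = M.make_split(df, folds=5, seed=10)
        final = M.finalize(df, plan, cols, 0.05)
        assert set(final.selected_features) == {
            n for n, b in zip(final.feature_names, final.coefficients) if b != 0
        }
        assert "f0" in final.selected_features

    def test_json_roundtrip(self, tmp_path):
        df, cols = _toy_table(seed=11)
        plan = M.make_split(df, folds=5, seed=11)
        final = M.finalize(df, plan, cols, 0.05)
        p = tmp_path / "model.json"
        final.to_json(p)
        back = M.FinalModel.from_json(p)
        np.testing.assert_array_equal(back.coefficients, final.coefficients)
        assert back.feature_names == final.feature_names

    def test_importance_ranking_and_order_invariance(self):
        df, cols = _toy_table(seed=12, shift=3.0)
        plan = M.make_split(df, folds=5, seed=12)
        final = M.finalize(df, plan, cols, 0.02)
        ranking = M.importance_ranking(final)
        mags = [m for _, m in ranking]
        assert mags == sorted(mags, reverse=True)
        # permuting feature columns must not change the ranking (names exact,
        # magnitudes to solver precision)
        perm = list(reversed(cols))
        final_perm = M.finalize(df, plan, perm, 0.02)
        ranking_perm = M.importance_ranking(final_perm)
        assert [n for n, _ in ranking_perm] == [n for n, _ in ranking]
        np.testing.assert_allclose(
            [m for _, m in ranking_perm], [m for _, m in ranking], rtol=1e-6
        )

    def test_all_zero_model_has_empty_ranking(self):
        df, cols = _toy_table(seed=13)
        plan = M.make_split(df, folds=5, seed=13)
        final = M.finalize(df, plan, cols, 10.0)  # far beyond lambda_max
        assert M.importance_ranking(final) == []


class TestPredictProba:
    def _model(self):
        return M.FinalModel(
            feature_names=("a", "b"),
            coefficients=np.array([1.0, -2.0]),
            intercept=0.0,
            means=np.array([0.0, 0.0]),
            sds=np.array([1.0, 1.0]),
            chosen_lambda=0.1,
        )

    def test_zero_linear_predictor_gives_half(self):
        rows = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert M.predict_proba(self._model(), rows)[0] == pytest.approx(0.5)

    def test_hand_computed_logistic(self):
        rows = pd.DataFrame({"a": [1.0], "b": [0.5]})
        expected = 1 / (1 + np.exp(-(1.0 * 1.0 - 2.0 * 0.5)))
        assert M.predict_proba(self._model(), rows)[0] == pytest.approx(expected)

    def test_monotone_in_positive_feature(self):
        rows = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [0.0, 0.0, 0.0]})
        probs = M.predict_proba(self._model(), rows)
        assert np.all(np.diff(probs) > 0)

    def test_missing_feature_named_in_error(self):
        rows = pd.DataFrame({"a": [0.0]})
        with pytest.raises(KeyError, match="'b'"):
            M.predict_proba(self._model(), rows)
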