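"""Kernel ridge regression against independent linear-algebra oracles."""

import numpy as np
import pytest

from printopt.krr import (KernelConfig, compute_metrics, grid_search_cv,
                          krr_fit, krr_loss, krr_predict, polynomial_kernel)


class TestPolynomialKernel:
    def test_orthogonal_vectors_give_coef_cubed(self):
        x = np.array([1.0, 0.0])
        y = np.array([0.0, 1.0])
        k = polynomial_kernel(x, y, KernelConfig(degree=3, coef0=0.2, gamma=1.0))
        assert k[0, 0] == pytest.approx(0.2**3)

    def test_zero_vectors_give_coef_to_degree(self):
        z = np.zeros(4)
        k = polynomial_kernel(z, z, KernelConfig(degree=3, coef0=0.2))
        assert k[0, 0] == pytest.approx(0.2**3)

    def test_symmetry_and_psd(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 4))
        K = polynomial_kernel(X, X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            polynomial_kernel(np.ones((2, 3)), np.ones((2, 4)))

    def test_default_gamma_is_reciprocal_feature_count(self):
        X = np.eye(4)
        k_default = polynomial_kernel(X, X)
        k_explicit = polynomial_kernel(X, X, KernelConfig(gamma=0.25))
        np.testing.assert_allclose(k_default, k_explicit)


class TestKRRFit:
    def test_single_point_closed_form(self):
        X = np.array([[1.0, 2.0]])
        y = np.array([0.3])
        cfg = KernelConfig()
        model = krr_fit(X, y, lam=0.5, config=cfg)
        k11 = polynomial_kernel(X, X, cfg)[0, 0]
        assert model.weights[0] == pytest.approx(y[0] / (k11 + 0.5))

    def test_matches_dense_solve_oracle(self):
        # 20 random problems against an independent dense linear solve
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(3, 30)
            X = rng.normal(size=(n, 4))
            y = rng.normal(size=n)
            lam = float(rng.uniform(0.05, 2.0))
            model = krr_fit(X, y, lam)
            K = polynomial_kernel(X, X)
            w_oracle = np.linalg.solve(K + lam * np.eye(n), y)
            np.testing.assert_allclose(model.weights, w_oracle, atol=1e-8)

    def test_huge_lambda_shrinks_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        model = krr_fit(X, y, lam=1e6)
        assert np.linalg.norm(model.weights) <= np.linalg.norm(y) / 1e5

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            krr_fit(np.ones((2, 2)), np.ones(2), lam=0.0)


class TestKRRPredict:
    def test_interpolation_limit(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        model = krr_fit(X, y, lam=1e-10)
        np.testing.assert_allclose(krr_predict(model, X), y, atol=1e-6)

    def test_two_point_hand_case(self):
        cfg = KernelConfig(degree=2, coef0=1.0, gamma=1.0)
        X = np.array([[1.0], [2.0]])
        y = np.array([1.0, 0.0])
        model = krr_fit(X, y, lam=1.0, config=cfg)
        xs = np.array([[3.0]])
        # manual arithmetic: yhat = w1 K(x1,x*) + w2 K(x2,x*)
        k1 = (1 * 3 + 1.0) ** 2
        k2 = (2 * 3 + 1.0) ** 2
        expected = model.weights[0] * k1 + model.weights[1] * k2
        assert krr_predict(model, xs)[0] == pytest.approx(expected)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        xs = rng.normal(size=(5, 4))
        a = krr_predict(krr_fit(X, y, 0.3), xs)
        b = krr_predict(krr_fit(X[perm], y[perm], 0.3), xs)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestKRRLoss:
    def test_perfect_fit_tiny_lambda_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = krr_fit(X, y, lam=1e-12)
        assert krr_loss(model, X, y) < 1e-6

    def test_penalty_equals_brute_force_triple_sum(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        model = krr_fit(X, y, lam=0.4)
        K = polynomial_kernel(X, X)
        brute = sum(model.weights[i] * K[i, j] * model.weights[j]
                    for i in range(5) for j in range(5))
        resid = krr_predict(model, X) - y
        assert krr_loss(model, X, y) == pytest.approx(
            float(resid @ resid) + 0.4 * brute
        )

    def test_fitted_weights_minimize_loss(self):
        # the ridge solution beats 100 random perturbations of w
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 4))
        y = rng.normal(size=8)
        lam = 0.5
        model = krr_fit(X, y, lam)
        K = polynomial_kernel(X, X)

        def loss(w):
            resid = K @ w - y
            return float(resid @ resid + lam * w @ K @ w)

        base = loss(model.weights)
        for _ in range(100):
            w = model.weights + rng.normal(scale=0.05, size=8)
            assert loss(w) >= base - 1e-10


class TestGridSearchCV:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        lam, kernel, table = grid_search_cv(X, y, lam_grid=(0.3,),
                                            kernel_grid=(KernelConfig(),))
        assert lam == 0.3
        assert len(table) == 1

    def test_winner_has_minimal_cv_mse(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        y = krr_predict(krr_fit(X, rng.normal(size=30), 0.5), X)
        y = np.asarray(y) + rng.normal(scale=0.01, size=30)
        lam, _, table = grid_search_cv(X, y, lam_grid=(0.01, 0.1, 1.0, 10.0))
        best_mse = table.loc[table["lambda"] == lam, "mean_mse"].min()
        assert best_mse <= table["mean_mse"].min() + 1e-15

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="10-fold"):
            grid_search_cv(np.ones((5, 4)), np.ones(5))

    def test_folds_partition_samples(self):
        from printopt.krr import _fold_indices
        rng = np.random.default_rng(0)
        folds = _fold_indices(43, 10, rng)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 43
        assert len(np.unique(all_idx)) == 43


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([0.1, 0.4, 0.9])
        m = compute_metrics(y, y)
        assert (m.r2, m.mae, m.rmse) == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([0.0, 0.5, 1.0])
        m = compute_metrics(y, np.full(3, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_case(self):
        m = compute_metrics(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0]))
        assert m.mae == pytest.approx(1.0 / 3.0)
        assert m.rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert m.r2 == pytest.approx(0.5)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            y = rng.normal(size=15)
            pred = y + rng.normal(size=15)
            m = compute_metrics(y, pred)
            assert m.rmse >= m.mae

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compute_metrics(np.ones(5), np.zeros(5))


def test_matches_sklearn_kernel_ridge():
    """Independent cross-check against scikit-learn's KernelRidge."""
    from sklearn.kernel_ridge import KernelRidge

    rng = np.random.default_rng(11)
    X = rng.normal(size=(25, 4))
    y = rng.normal(size=25)
    cfg = KernelConfig(degree=3, coef0=0.2, gamma=0.25)
    model = krr_fit(X, y, lam=0.5, config=cfg)
    sk = KernelRidge(alpha=0.5, kernel="poly", degree=3, coef0=0.2,
                     gamma=0.25).fit(X, y)
    xs = rng.normal(size=(6, 4))
    np.testing.assert_allclose(krr_predict(model, xs), sk.predict(xs), atol=1e-8)
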