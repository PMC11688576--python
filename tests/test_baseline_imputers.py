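import numpy as np
import pytest

from ordimpute import apply_mask, mcar_mask
from ordimpute.impute import (
    EMImputer,
    KNNImputer,
    MvnParams,
    column_stat_impute,
    em_fit,
    em_impute,
    knn_impute,
)


class TestColumnStat:
    def test_mean_fill(self):
        X = np.array([[1.0, 1], [2, 1], [3, 1], [np.nan, 1]])
        out = column_stat_impute(X, "mean")
        assert out[3, 0] == 2.0

    def test_median_fill(self):
        X = np.array([[1.0], [1], [5], [np.nan]])
        assert column_stat_impute(X, "median")[3, 0] == 1.0

    def test_no_missing_is_identity(self, rng):
        X = rng.normal(size=(10, 3))
        assert np.array_equal(column_stat_impute(X, "mean"), X)

    def test_fully_missing_column_named_in_error(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            column_stat_impute(X, "mean")


class TestEmFit:
    def test_complete_data_is_ml_fixed_point(self, rng):
        X = rng.normal(size=(60, 4))
        params = em_fit(X)
        assert params.n_iter == 1 and params.converged
        np.testing.assert_allclose(params.mu, X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            params.sigma, np.cov(X.T, bias=True), atol=1e-12
        )

    def test_univariate_reduces_to_observed_ml(self):
        params = em_fit(np.array([[1.0], [2.0], [np.nan]]))
        assert params.mu[0] == pytest.approx(1.5, abs=1e-6)

    def test_parameter_recovery_under_mcar(self, rng):
        mu_star = np.array([1.0, 2.0, 3.0, 4.0])
        a = rng.normal(size=(4, 4))
        sigma_star = a @ a.T + np.eye(4)
        X = rng.multivariate_normal(mu_star, sigma_star, size=1000)
        X[rng.random(X.shape) < 0.10] = np.nan
        params = em_fit(X)
        se = np.sqrt(np.diag(sigma_star) / 1000)
        assert np.all(np.abs(params.mu - mu_star) < 3 * se)

    def test_loglik_monotone_on_every_fit(self, rng):
        for s in range(5):
            r = np.random.default_rng(s)
            X = r.multivariate_normal(
                np.zeros(3), [[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1]], 200
            )
            X[r.random(X.shape) < 0.2] = np.nan
            params = em_fit(X)
            assert np.all(np.diff(params.loglik_trace) >= -1e-6)


class TestEmImpute:
    def test_no_missing_passes_through(self, rng):
        X = rng.normal(size=(5, 2))
        params = em_fit(X)
        assert np.array_equal(em_impute(X, params, seed=0), X)

    def test_uncorrelated_gives_marginal_mean(self):
        params = MvnParams(mu=np.array([3.0, 7.0]), sigma=np.eye(2))
        row = np.array([[1.0, np.nan]])
        out = em_impute(row, params, stochastic=False)
        assert out[0, 1] == pytest.approx(7.0)

    def test_bivariate_conditional_mean_closed_form(self):
        params = MvnParams(
            mu=np.zeros(2), sigma=np.array([[1.0, 0.8], [0.8, 1.0]])
        )
        out = em_impute(np.array([[1.0, np.nan]]), params, stochastic=False)
        assert out[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_stochastic_residuals_have_conditional_spread(self):
        params = MvnParams(
            mu=np.zeros(2), sigma=np.array([[1.0, 0.8], [0.8, 1.0]])
        )
        rows = np.tile([1.0, np.nan], (4000, 1))
        out = em_impute(rows, params, stochastic=True, seed=1)
        # residual variance = 1 - 0.8^2 = 0.36
        assert out[:, 1].mean() == pytest.approx(0.8, abs=0.05)
        assert out[:, 1].var() == pytest.approx(0.36, rel=0.15)

    def test_beats_column_mean_on_correlated_data(self):
        # rho=0.8 bivariate, conditional-mean EM strictly better than mean
        for s in range(10):
            r = np.random.default_rng(s)
            X = r.multivariate_normal(
                [0, 0], [[1, 0.8], [0.8, 1]], size=500
            )
            mask = r.random(X.shape) < 0.1
            Xm = X.copy()
            Xm[mask] = np.nan
            params = em_fit(Xm)
            em_out = em_impute(Xm, params, stochastic=False)
            mean_out = column_stat_impute(Xm, "mean")
            em_err = np.mean((em_out[mask] - X[mask]) ** 2)
            mean_err = np.mean((mean_out[mask] - X[mask]) ** 2)
            assert em_err < mean_err

    def test_estimator_interface_and_determinism(self, incomplete_500):
        _, _, inc = incomplete_500
        a = EMImputer(random_state=3).fit(inc).transform(inc)
        b = EMImputer(random_state=3).fit(inc).transform(inc)
        assert np.array_equal(a, b)
        assert not np.isnan(a).any()


class TestKnn:
    def test_duplicate_donor_rows(self):
        X = np.array([[2.0, np.nan], [2.0, 4.0], [2.0, 4.0]])
        out = knn_impute(X, k=2)
        assert out[0, 1] == 4.0

    def test_k_equals_all_donors_is_donor_mean(self, rng):
        X = rng.integers(1, 6, size=(20, 3)).astype(float)
        X[0, 1] = np.nan
        out = knn_impute(X, k=19)
        assert out[0, 1] == pytest.approx(np.nanmean(X[1:, 1]))

    def test_hand_computed_nearest_neighbor(self):
        X = np.array(
            [[1.0, 1, 1], [1, 1, 2], [5, 5, 5], [1, np.nan, 1]]
        )
        # scaled distances from row 3: to row0 = 0, row1 = sqrt(3/2), far row2
        out = knn_impute(X, k=1)
        assert out[3, 1] == 1.0

    def test_matches_sklearn_on_tie_free_data(self, rng):
        from sklearn.impute import KNNImputer as SkKNNImputer

        X = rng.normal(size=(40, 5))
        X[rng.random(X.shape) < 0.15] = np.nan
        ours = knn_impute(X, k=3)
        theirs = SkKNNImputer(n_neighbors=3, weights="uniform").fit_transform(X)
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_row_order_of_donors_irrelevant_without_ties(self, rng):
        X = rng.normal(size=(30, 4))
        X[rng.random(X.shape) < 0.2] = np.nan
        miss = np.isnan(X)
        out = knn_impute(X, k=3)
        perm = rng.permutation(30)
        out_perm = knn_impute(X[perm], k=3)
        inv = np.argsort(perm)
        np.testing.assert_allclose(out_perm[inv][miss], out[miss], atol=1e-12)

    def test_no_shared_coordinates_falls_back_to_column_mean(self):
        X = np.array(
            [[1.0, np.nan, np.nan], [np.nan, 2.0, 3.0], [np.nan, 4.0, 5.0]]
        )
        out = knn_impute(X, k=3)
        # row 0 shares no observed coordinate with any donor for cols 1, 2
        assert out[0, 1] == pytest.approx(3.0)
        assert out[0, 2] == pytest.approx(4.0)

    def test_estimator_transform_of_new_rows(self, rng):
        train = rng.normal(size=(30, 3))
        est = KNNImputer(n_neighbors=3).fit(train)
        new = np.array([[train[0, 0], np.nan, train[0, 2]]])
        out = est.transform(new)
        assert np.isfinite(out).all()
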