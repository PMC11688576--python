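import numpy as np
import pytest

from ordimpute import round_clip
from ordimpute.impute import (
    AutoencoderImputer,
    MissForestImputer,
    ReMaskerImputer,
    column_stat_impute,
    remask_select,
)

from conftest import FAST_REMASKER


def _masked_rmse(truth, imputed, miss):
    return float(np.sqrt(np.mean((imputed[miss] - truth[miss]) ** 2)))


class TestMissForest:
    def test_no_missing_zero_sweeps(self, rng):
        X = rng.integers(1, 6, size=(30, 4)).astype(float)
        imp = MissForestImputer(n_trees=5, random_state=0)
        out = imp.fit(X).transform(X)
        assert np.array_equal(out, X)
        assert imp.n_iter_ == 0

    def test_duplicated_column_beats_column_mean(self, rng):
        base = rng.integers(1, 6, size=(300, 4)).astype(float)
        X = np.column_stack([base, base[:, 0]])  # col 4 duplicates col 0
        miss = np.zeros_like(X, dtype=bool)
        miss[rng.random(300) < 0.10, 4] = True
        Xm = X.copy()
        Xm[miss] = np.nan
        imp = MissForestImputer(n_trees=50, random_state=1)
        forest_err = _masked_rmse(X, imp.fit(Xm).transform(Xm), miss)
        mean_err = _masked_rmse(X, column_stat_impute(Xm, "mean"), miss)
        assert forest_err < mean_err

    def test_delta_rise_returns_prior_sweep(self, rng):
        # find a fit whose relative-difference sequence rises, then check
        # the returned matrix equals a rerun truncated at the prior sweep
        found = False
        for s in range(6):
            r = np.random.default_rng(s)
            X = r.integers(1, 6, size=(80, 5)).astype(float)
            X[r.random(X.shape) < 0.25] = np.nan
            imp = MissForestImputer(n_trees=10, max_iter=8, random_state=s)
            out = imp.fit(X).transform(X)
            d = imp.deltas_
            rises = [i for i in range(1, len(d)) if d[i] > d[i - 1]]
            if rises:
                found = True
                assert imp.n_iter_ == rises[0]  # stopped at first rise
                trunc = MissForestImputer(
                    n_trees=10, max_iter=imp.n_iter_, random_state=s
                )
                np.testing.assert_array_equal(
                    out, trunc.fit(X).transform(X)
                )
                break
        assert found, "no delta rise encountered in any replicate"

    def test_single_tree_matches_direct_refit(self, rng):
        # n_trees=1, max_iter=1 is one regression tree per column; mirror
        # the imputer's internal seeding and refit the same forest directly
        from sklearn.ensemble import RandomForestRegressor

        X = rng.normal(size=(60, 3))
        X[rng.random(60) < 0.2, 2] = np.nan
        imp = MissForestImputer(n_trees=1, max_iter=1, random_state=42, mtry=2)
        out = imp.fit(X).transform(X)

        derived = np.random.default_rng(42)
        miss = np.isnan(X[:, 2])
        filled = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        tree = RandomForestRegressor(
            n_estimators=1, max_features=2, bootstrap=True,
            random_state=int(derived.integers(2**31 - 1)), n_jobs=1,
        )
        tree.fit(filled[~miss][:, :2], filled[~miss, 2])
        np.testing.assert_allclose(
            out[miss, 2], tree.predict(filled[miss][:, :2]), atol=1e-12
        )

    def test_zero_variance_column_predicts_constant(self):
        X = np.array([[3.0, 1], [3.0, 2], [np.nan, 3], [3.0, 4]])
        imp = MissForestImputer(n_trees=5, random_state=0)
        out = imp.fit(X).transform(X)
        assert out[2, 0] == 3.0

    def test_deterministic_under_seed(self, rng):
        X = rng.integers(1, 6, size=(60, 4)).astype(float)
        X[rng.random(X.shape) < 0.15] = np.nan
        a = MissForestImputer(n_trees=10, random_state=5).fit(X).transform(X)
        b = MissForestImputer(n_trees=10, random_state=5).fit(X).transform(X)
        assert np.array_equal(a, b)


class TestAutoencoder:
    def test_loss_decreases(self, incomplete_500):
        _, _, inc = incomplete_500
        imp = AutoencoderImputer(random_state=0)
        imp.fit(inc)
        assert imp.loss_trace_[-1] <= imp.loss_trace_[0]

    def test_constant_dataset_reconstructs_constant(self, rng):
        X = np.full((100, 6), 3.0)
        X[rng.random(X.shape) < 0.1] = np.nan
        out = AutoencoderImputer(random_state=1).fit(X).transform(X)
        assert np.all(round_clip(out) == 3)

    def test_observed_cells_pass_through_exactly(self, incomplete_500):
        _, _, inc = incomplete_500
        out = AutoencoderImputer(epochs=5, random_state=0).fit(inc).transform(inc)
        obs = ~np.isnan(inc)
        assert np.array_equal(out[obs], inc[obs])

    def test_widths_must_decrease(self):
        with pytest.raises(ValueError, match="decrease"):
            AutoencoderImputer(hidden_dims=(5, 7)).fit(np.ones((10, 10)))

    def test_deterministic_under_seed(self, incomplete_500):
        _, _, inc = incomplete_500
        a = AutoencoderImputer(epochs=10, random_state=2).fit(inc).transform(inc)
        b = AutoencoderImputer(epochs=10, random_state=2).fit(inc).transform(inc)
        assert np.array_equal(a, b)


class TestRemaskSelect:
    def test_exact_count_and_containment(self, rng):
        obs = np.array([True, True, False, True, True, False])
        sel = remask_select(obs, 0.5, seed=0)
        assert sel.sum() == 2
        assert not sel[~obs].any()

    def test_empty_observed_gives_empty_selection(self):
        sel = remask_select(np.zeros(5, dtype=bool), 0.5, seed=0)
        assert not sel.any()

    def test_selection_uniform_over_observed(self):
        obs = np.ones(8, dtype=bool)
        rng = np.random.default_rng(1)
        freq = np.zeros(8)
        n_draws = 10_000
        for _ in range(n_draws):
            freq += remask_select(obs, 0.5, seed=rng)
        freq /= n_draws
        se = np.sqrt(0.5 * 0.5 / n_draws)
        assert np.all(np.abs(freq - 0.5) < 3 * se)


class TestReMasker:
    def test_observed_cells_pass_through_exactly(self, incomplete_500):
        _, _, inc = incomplete_500
        cfg = dict(FAST_REMASKER, epochs=3)
        out = ReMaskerImputer(**cfg, random_state=0).fit(inc).transform(inc)
        obs = ~np.isnan(inc)
        assert np.array_equal(out[obs], inc[obs])
        assert np.isfinite(out).all()

    def test_constant_dataset_reconstructs_constant(self, rng):
        X = np.full((100, 6), 4.0)
        X[rng.random(X.shape) < 0.1] = np.nan
        imp = ReMaskerImputer(
            embed_dim=16, encoder_depth=2, decoder_depth=1, n_heads=2,
            ff_mult=2, epochs=100, random_state=1,
        )
        out = imp.fit(X).transform(X)
        assert np.all(round_clip(out) == 4)

    def test_training_loss_decreases(self, incomplete_500):
        _, _, inc = incomplete_500
        for seed in (0, 1, 2):
            imp = ReMaskerImputer(**FAST_REMASKER, random_state=seed)
            imp.fit(inc)
            assert imp.loss_trace_[-1] < imp.loss_trace_[0]

    def test_twin_column_copied_by_attention(self, rng):
        # a column duplicated elsewhere is recoverable almost exactly;
        # column-mean imputation cannot exploit the twin
        wins = 0
        for s in range(4):
            r = np.random.default_rng(s)
            base = r.integers(1, 6, size=(200, 4)).astype(float)
            X = np.column_stack([base, base[:, 0]])
            miss = np.zeros_like(X, dtype=bool)
            miss[r.random(200) < 0.15, 4] = True
            Xm = X.copy()
            Xm[miss] = np.nan
            imp = ReMaskerImputer(**FAST_REMASKER, random_state=s)
            rm_err = _masked_rmse(X, imp.fit(Xm).transform(Xm), miss)
            mean_err = _masked_rmse(X, column_stat_impute(Xm, "mean"), miss)
            wins += rm_err < mean_err
        assert wins >= 3

    def test_embed_dim_head_divisibility_checked(self):
        with pytest.raises(ValueError, match="divisible"):
            ReMaskerImputer(embed_dim=10, n_heads=4).fit(np.ones((4, 3)))

    def test_deterministic_under_seed(self, incomplete_500):
        _, _, inc = incomplete_500
        cfg = dict(FAST_REMASKER, epochs=5)
        a = ReMaskerImputer(**cfg, random_state=9).fit(inc).transform(inc)
        b = ReMaskerImputer(**cfg, random_state=9).fit(inc).transform(inc)
        assert np.array_equal(a, b)
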