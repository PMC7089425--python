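import numpy as np
import pandas as pd
import pytest

from spatreg.forest import RFRK, ForestConfig, RandomForestQuantile
from spatreg.simulate import generate_case


@pytest.fixture(scope="module")
def small_forest_data():
    rng = np.random.default_rng(12)
    n = 120
    X = rng.uniform(size=(n, 4))
    y = 2 * X[:, 2] - X[:, 3] + np.sin(5 * np.pi * X[:, 0] * X[:, 1]) \
        + rng.normal(scale=0.3, size=n)
    return X, y


@pytest.fixture(scope="module")
def fitted_forest(small_forest_data):
    X, y = small_forest_data
    return RandomForestQuantile(n_trees=100, seed=5).fit(X, y)


class TestForestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            ForestConfig(n_trees=0)
        with pytest.raises(ValueError):
            ForestConfig(mtry=0)
        assert ForestConfig().resolve_mtry(4) == 1  # floor(4/3)
        assert ForestConfig().resolve_mtry(9) == 3
        with pytest.raises(ValueError):
            ForestConfig(mtry=5).resolve_mtry(4)


class TestForestFit:
    def test_constant_response_predicts_constant(self, rng):
        X = rng.uniform(size=(40, 2))
        f = RandomForestQuantile(n_trees=20, seed=0).fit(X, np.full(40, 7.0))
        np.testing.assert_allclose(f.predict(X), 7.0)

    def test_predictions_stay_in_observed_range(self, fitted_forest,
                                                small_forest_data, rng):
        X, y = small_forest_data
        preds = fitted_forest.predict(rng.uniform(size=(300, 4)))
        assert preds.min() >= y.min() - 1e-12
        assert preds.max() <= y.max() + 1e-12

    def test_missing_values_rejected(self, rng):
        X = rng.uniform(size=(20, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            RandomForestQuantile(n_trees=5).fit(X, rng.normal(size=20))

    def test_oob_beats_intercept_baseline_on_nonlinear_data(self):
        sim = generate_case(3, seed=1)  # structural signal dominates
        train = sim.train_idx
        X, y = sim.X.to_numpy()[train], sim.y[train]
        f = RandomForestQuantile(n_trees=200, seed=2).fit(X, y)
        oob = f.oob_prediction()
        ok = np.isfinite(oob)
        assert np.mean((y[ok] - oob[ok]) ** 2) < np.var(y)

    def test_same_seed_reproduces_predictions(self, small_forest_data):
        X, y = small_forest_data
        f1 = RandomForestQuantile(n_trees=30, seed=9).fit(X, y)
        f2 = RandomForestQuantile(n_trees=30, seed=9).fit(X, y)
        np.testing.assert_array_equal(f1.predict(X[:10]), f2.predict(X[:10]))


class TestQRFWeights:
    def test_single_tree_single_leaf_weights_are_bootstrap_frequencies(self):
        # min_node_size = n forces one leaf; weights equal bootstrap counts/n
        rng = np.random.default_rng(0)
        X, y = rng.uniform(size=(4, 2)), np.arange(4.0)
        f = RandomForestQuantile(n_trees=1, min_node_size=4, seed=1).fit(X, y)
        w = f.weights(X[:1])[0]
        counts = np.bincount(f.bootstrap_idx_[0], minlength=4)
        np.testing.assert_allclose(w, counts / 4.0, atol=1e-12)
        assert w.sum() == pytest.approx(1.0)

    def test_weights_sum_to_one(self, fitted_forest, rng):
        W = fitted_forest.weights(rng.uniform(size=(20, 4)))
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_mean_prediction_equals_weighted_training_mean(self, fitted_forest,
                                                           rng):
        X0 = rng.uniform(size=(25, 4))
        direct = fitted_forest.predict(X0)
        weighted = fitted_forest.weights(X0) @ fitted_forest.y_
        np.testing.assert_allclose(direct, weighted, atol=1e-8)


def brute_force_weighted_quantile(w, y, alpha):
    order = np.argsort(y, kind="stable")
    cum = 0.0
    for i in order:
        cum += w[i]
        if cum >= alpha - 1e-12:
            return y[i]
    return y[order[-1]]


class TestQRFQuantiles:
    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(50, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.2, size=50)
        f = RandomForestQuantile(n_trees=40, seed=4).fit(X, y)
        X0 = rng.uniform(size=(10, 3))
        W = f.weights(X0)
        for alpha in (0.05, 0.25, 0.5, 0.75, 0.95):
            got = f.quantile(X0, alpha)
            expected = [brute_force_weighted_quantile(W[i], y, alpha)
                        for i in range(len(X0))]
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_uniform_single_leaf_median(self):
        rng = np.random.default_rng(1)
        X, y = rng.uniform(size=(4, 2)), np.array([1.0, 2.0, 3.0, 4.0])
        f = RandomForestQuantile(n_trees=1, min_node_size=4, seed=None).fit(X, y)
        # with uniform weights 0.25 the 0.5-quantile is the second value
        w = f.weights(X[:1])[0]
        if np.allclose(w, 0.25):
            assert f.quantile(X[:1], 0.5)[0] == 2.0

    def test_alpha_near_one_returns_leaf_maximum(self, fitted_forest, rng):
        X0 = rng.uniform(size=(5, 4))
        q = fitted_forest.quantile(X0, 0.999999)
        assert np.all(q <= fitted_forest.y_.max())
        W = fitted_forest.weights(X0)
        for i in range(5):
            support_max = fitted_forest.y_[W[i] > 0].max()
            assert q[i] == pytest.approx(support_max)

    def test_monotone_in_alpha(self, fitted_forest, rng):
        X0 = rng.uniform(size=(100, 4))
        q = fitted_forest.quantile(X0, np.array([0.05, 0.5, 0.95]))
        assert np.all(q[:, 0] <= q[:, 1] + 1e-12)
        assert np.all(q[:, 1] <= q[:, 2] + 1e-12)

    def test_invalid_alpha_rejected(self, fitted_forest):
        with pytest.raises(ValueError):
            fitted_forest.quantile(np.zeros((1, 4)), 1.5)


class TestQRFIntervals:
    def test_level_90_uses_tail_quantiles(self, fitted_forest, rng):
        X0 = rng.uniform(size=(8, 4))
        res = fitted_forest.interval(X0, level=0.90)
        q = fitted_forest.quantile(X0, np.array([0.05, 0.95]))
        np.testing.assert_allclose(res.lower, q[:, 0])
        np.testing.assert_allclose(res.upper, q[:, 1])

    def test_constant_response_zero_width(self, rng):
        X = rng.uniform(size=(30, 2))
        f = RandomForestQuantile(n_trees=10, seed=0).fit(X, np.full(30, 2.0))
        res = f.interval(X[:5])
        np.testing.assert_allclose(res.upper - res.lower, 0.0)

    def test_interval_contains_forest_mean_almost_always(self, fitted_forest,
                                                         rng):
        X0 = rng.uniform(size=(200, 4))
        res = fitted_forest.interval(X0, level=0.90)
        inside = (res.lower <= res.mean) & (res.mean <= res.upper)
        assert np.mean(inside) >= 0.99


class TestPermutationImportance:
    def test_signal_outranks_pure_noise(self):
        rng = np.random.default_rng(8)
        n = 300
        X = pd.DataFrame({"x3": rng.uniform(size=n),
                          "noise": rng.uniform(size=n)})
        y = 2 * X["x3"].to_numpy() + rng.normal(scale=0.3, size=n)
        f = RandomForestQuantile(n_trees=150, seed=3).fit(X, y)
        table = f.permutation_importance()
        assert table.iloc[0]["covariate"] == "x3"
        x3_imp = table.set_index("covariate")["importance"]
        assert x3_imp["x3"] > 5 * max(x3_imp["noise"], 1e-12)

    def test_ranking_reproducible_under_seed(self, fitted_forest):
        t1 = fitted_forest.permutation_importance(seed=1)
        t2 = fitted_forest.permutation_importance(seed=1)
        pd.testing.assert_frame_equal(t1, t2)


class TestCrossCheckAgainstReferenceForest:
    def test_test_mse_comparable_to_sklearn_forest(self):
        """Independent check: our bagged-CART ensemble should predict about
        as well as scikit-learn's RandomForestRegressor under the same
        hyperparameters (different bootstrap streams, so compare MSE)."""
        from sklearn.ensemble import RandomForestRegressor

        sim = generate_case(3, seed=7)
        Xtr, ytr = sim.X.to_numpy()[sim.train_idx], sim.y[sim.train_idx]
        Xte, yte = sim.X.to_numpy()[sim.test_idx], sim.y[sim.test_idx]
        ours = RandomForestQuantile(n_trees=300, seed=0).fit(Xtr, ytr)
        ref = RandomForestRegressor(n_estimators=300, max_features=1,
                                    min_samples_split=6, random_state=0)
        ref.fit(Xtr, ytr)
        mse_ours = np.mean((yte - ours.predict(Xte)) ** 2)
        mse_ref = np.mean((yte - ref.predict(Xte)) ** 2)
        assert mse_ours == pytest.approx(mse_ref, rel=0.10)


class TestRFRK:
    def test_zero_residual_field_reduces_to_forest(self, rng):
        X = rng.uniform(size=(40, 2))
        y = np.full(40, 3.0)
        rfrk = RFRK(n_trees=20, seed=0).fit(X, y, rng.uniform(size=(40, 2)))
        res = rfrk.predict(X[:5], rng.uniform(size=(5, 2)))
        np.testing.assert_allclose(res.mean, 3.0)
        np.testing.assert_allclose(res.upper - res.lower, 0.0)

    def test_uncorrelated_residuals_leave_rfrk_close_to_rf(self):
        # nugget-dominated error: the kriged residual adjustment is ~0, so
        # RFRK predictions essentially coincide with the forest's.  (The ML
        # fit may express white noise as a near-zero-range spatial term,
        # which is behaviorally identical to a pure nugget.)
        sim = generate_case(3, seed=11)
        tr, te = sim.train_idx, sim.test_idx
        rfrk = RFRK(n_trees=150, seed=1).fit(sim.X.to_numpy()[tr], sim.y[tr],
                                             sim.coords[tr])
        rf_pred = rfrk.forest.predict(sim.X.to_numpy()[te])
        rfrk_pred = rfrk.predict(sim.X.to_numpy()[te], sim.coords[te]).mean
        adj = rfrk_pred - rf_pred
        assert np.corrcoef(rf_pred, rfrk_pred)[0, 1] > 0.95
        assert np.std(adj) < 0.5 * np.std(rfrk.residuals_)

    def test_kriging_residuals_improves_under_strong_autocorrelation(self):
        sim = generate_case(4, seed=3)  # strong spatial error, nonlinear f
        tr, te = sim.train_idx, sim.test_idx
        Xtr, Xte = sim.X.to_numpy()[tr], sim.X.to_numpy()[te]
        forest = RandomForestQuantile(n_trees=200, seed=5).fit(Xtr, sim.y[tr])
        rfrk = RFRK(forest=forest).fit(Xtr, sim.y[tr], sim.coords[tr],
                                       refit_forest=False)
        rf_mse = np.mean((sim.y[te] - forest.predict(Xte)) ** 2)
        rfrk_mse = np.mean(
            (sim.y[te] - rfrk.predict(Xte, sim.coords[te]).mean) ** 2)
        assert rfrk_mse < rf_mse
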