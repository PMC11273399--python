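"""Learner oracles: split enumeration, ensemble identities, closed forms."""

import numpy as np
import pytest

from pigmorph.models import (
    RegressorSpec,
    TrainingSet,
    fit_baseline,
    fit_gboost,
    fit_random_forest,
    fit_tree,
    load_model,
    predict,
    save_model,
)


def _regression_data(seed, n=200, d=5, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    beta = rng.normal(size=d)
    y = X @ beta + noise * rng.normal(size=n)
    return TrainingSet(X, y), beta


def _brute_force_best_split(X, y):
    """Enumerate every midpoint threshold of every feature; min child SSE."""
    best = None
    for f in range(X.shape[1]):
        vs = np.unique(X[:, f])
        for lo, hi in zip(vs, vs[1:]):
            thr = (lo + hi) / 2.0
            left, right = y[X[:, f] <= thr], y[X[:, f] > thr]
            sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            if best is None or sse < best[0] - 1e-12:
                best = (sse, f, thr)
    return best[1], best[2]


class TestRegressionTree:
    def test_constant_target_yields_single_leaf(self):
        ts = TrainingSet(np.arange(10.0).reshape(-1, 1), np.full(10, 3.5))
        tree = fit_tree(ts)
        assert tree.root_.is_leaf and tree.root_.value == 3.5

    def test_step_function_split_at_the_step(self):
        x = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (x.ravel() > 0).astype(float)
        tree = fit_tree(TrainingSet(x, y), max_depth=1)
        assert abs(tree.root_.threshold) < 0.06
        assert np.array_equal(tree.predict(x), y)

    @pytest.mark.parametrize("seed", range(6))
    def test_depth_one_split_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        tree = fit_tree(TrainingSet(X, y), max_depth=1)
        f, thr = _brute_force_best_split(X, y)
        assert tree.root_.feature == f
        assert tree.root_.threshold == pytest.approx(thr)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_tree(TrainingSet(np.empty((0, 2)), np.empty(0)))


class TestRandomForest:
    def test_single_full_tree_equals_fit_tree(self):
        ts, _ = _regression_data(1, n=50)
        forest = fit_random_forest(ts, n_trees=1, bootstrap=False, features_per_split=1.0)
        tree = fit_tree(ts)
        assert np.allclose(forest.predict(ts.X), tree.predict(ts.X))

    def test_prediction_is_exact_mean_of_trees(self):
        ts, _ = _regression_data(2, n=80)
        forest = fit_random_forest(ts, n_trees=12)
        external = np.stack([t.predict(ts.X) for t in forest.trees_]).mean(axis=0)
        assert np.array_equal(forest.predict(ts.X), external)

    def test_seed_determinism(self):
        ts, _ = _regression_data(3, n=60)
        a = fit_random_forest(ts, n_trees=10, seed=7).predict(ts.X)
        b = fit_random_forest(ts, n_trees=10, seed=7).predict(ts.X)
        assert np.array_equal(a, b)

    def test_variance_reduction_over_median_tree(self):
        train, _ = _regression_data(4, n=300, noise=1.0)
        test, _ = _regression_data(40, n=300, noise=1.0)
        # same planted coefficients required: regenerate with shared beta
        rng = np.random.default_rng(11)
        beta = rng.normal(size=5)
        Xtr = rng.normal(size=(250, 5)); ytr = Xtr @ beta + rng.normal(size=250)
        Xte = rng.normal(size=(250, 5)); yte = Xte @ beta + rng.normal(size=250)
        forest = fit_random_forest(TrainingSet(Xtr, ytr), n_trees=100, seed=0)
        forest_mse = np.mean((forest.predict(Xte) - yte) ** 2)
        tree_mses = sorted(np.mean((t.predict(Xte) - yte) ** 2) for t in forest.trees_)
        median_tree_mse = tree_mses[len(tree_mses) // 2]
        assert forest_mse <= median_tree_mse


class TestGradientBoosting:
    def test_single_leaf_round_matches_closed_form(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=12)
        X = rng.normal(size=(12, 2))
        lam = 2.5
        m = fit_gboost(TrainingSet(X, y), rounds=1, eta=1.0, lam=lam, max_depth=0)
        base = y.mean()
        expected = base + (y - base).sum() / (len(y) + lam)
        assert np.allclose(m.predict(X), expected)

    def test_huge_gamma_degenerates_to_single_leaves(self):
        ts, _ = _regression_data(6, n=60)
        m = fit_gboost(ts, rounds=5, gamma=1e12)
        assert all(root.is_leaf for root in m.trees_)

    def test_training_rmse_non_increasing_over_50_rounds(self):
        ts, _ = _regression_data(7, n=120)
        m = fit_gboost(ts, rounds=50, eta=0.3, gamma=0.0)
        assert all(
            later <= earlier + 1e-9
            for earlier, later in zip(m.train_rmse_, m.train_rmse_[1:])
        )

    def test_seed_and_rerun_determinism(self):
        ts, _ = _regression_data(8, n=80)
        a = fit_gboost(ts, rounds=30, seed=3).predict(ts.X)
        b = fit_gboost(ts, rounds=30, seed=3).predict(ts.X)
        assert np.array_equal(a, b)

    def test_agrees_with_reference_library_predictions(self):
        xgb = pytest.importorskip("xgboost")
        ts, _ = _regression_data(9, n=150, d=4, noise=0.3)
        ours = fit_gboost(ts, rounds=80, eta=0.3, lam=1.0, max_depth=3)
        ref = xgb.XGBRegressor(
            n_estimators=80, learning_rate=0.3, reg_lambda=1.0, max_depth=3,
            min_child_weight=0, base_score=float(ts.y.mean()), tree_method="exact",
        ).fit(ts.X, ts.y)
        ours_pred = ours.predict(ts.X)
        ref_pred = ref.predict(ts.X)
        # Independent implementations of the same algorithm: near-identical fits.
        assert np.corrcoef(ours_pred, ref_pred)[0, 1] > 0.999
        rmse = lambda p: float(np.sqrt(np.mean((p - ts.y) ** 2)))
        assert rmse(ours_pred) == pytest.approx(rmse(ref_pred), abs=0.05)

    def test_invalid_hyperparameters_rejected(self):
        ts, _ = _regression_data(10, n=20)
        with pytest.raises(ValueError):
            fit_gboost(ts, rounds=0)
        with pytest.raises(ValueError):
            fit_gboost(ts, lam=-1.0)


class TestBaselines:
    def test_lr_recovers_planted_coefficients_exactly(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 4))
        beta = rng.normal(size=4)
        y = X @ beta + 2.0
        model = fit_baseline(RegressorSpec("LR"), TrainingSet(X, y))
        assert np.allclose(model.coef_, beta, atol=1e-10)
        assert model.intercept_ == pytest.approx(2.0, abs=1e-10)

    def test_lasso_zero_penalty_limit_equals_lr(self):
        ts, _ = _regression_data(13, n=60, d=3)
        lr = fit_baseline(RegressorSpec("LR"), ts)
        lasso = fit_baseline(RegressorSpec("Lasso", {"alpha": 1e-12}), ts)
        assert np.allclose(lasso.coef_, lr.coef_, atol=1e-6)

    def test_lasso_huge_penalty_collapses_to_intercept(self):
        ts, _ = _regression_data(14, n=60, d=3)
        lasso = fit_baseline(RegressorSpec("Lasso", {"alpha": 1e9}), ts)
        assert np.all(lasso.coef_ == 0.0)
        assert lasso.intercept_ == pytest.approx(ts.y.mean())
        assert np.allclose(lasso.predict(ts.X), ts.y.mean())

    @pytest.mark.parametrize(
        "method", ["KRR", "Adaboost", "Stacking", "SVR", "MLP", "BP"]
    )
    def test_registry_methods_fit_and_predict(self, method):
        ts, _ = _regression_data(15, n=60, d=3)
        model = fit_baseline(RegressorSpec(method, seed=1), ts)
        pred = predict(model, ts.X)
        assert pred.shape == (60,)
        assert np.isfinite(pred).all()

    def test_unknown_method_lists_valid_names(self):
        with pytest.raises(ValueError, match="XGBoost.*RFR"):
            RegressorSpec("GradientDescentForest")

    def test_training_set_validates_shapes_and_nans(self):
        with pytest.raises(ValueError):
            TrainingSet(np.ones((3, 2)), np.ones(4))
        with pytest.raises(ValueError):
            TrainingSet(np.array([[1.0, np.nan]]), np.array([1.0]))


class TestPredictContract:
    def test_empty_input_gives_empty_output(self):
        ts, _ = _regression_data(16, n=30)
        m = fit_gboost(ts, rounds=5)
        assert predict(m, np.empty((0, ts.X.shape[1]))).shape == (0,)

    def test_duplicated_row_gives_identical_predictions(self):
        ts, _ = _regression_data(17, n=30)
        m = fit_random_forest(ts, n_trees=5)
        X = np.tile(ts.X[3], (7, 1))
        assert len(set(predict(m, X))) == 1


class TestSerialization:
    @pytest.mark.parametrize("kind", ["tree", "forest", "gboost", "lr", "lasso", "krr"])
    def test_json_round_trip_preserves_predictions(self, tmp_path, kind):
        ts, _ = _regression_data(18, n=40, d=3)
        model = {
            "tree": lambda: fit_tree(ts, max_depth=3),
            "forest": lambda: fit_random_forest(ts, n_trees=4),
            "gboost": lambda: fit_gboost(ts, rounds=10),
            "lr": lambda: fit_baseline(RegressorSpec("LR"), ts),
            "lasso": lambda: fit_baseline(RegressorSpec("Lasso"), ts),
            "krr": lambda: fit_baseline(RegressorSpec("KRR"), ts),
        }[kind]()
        path = tmp_path / "model.json"
        save_model(model, str(path))
        clone = load_model(str(path))
        assert np.allclose(clone.predict(ts.X), model.predict(ts.X))

    def test_adapter_models_refuse_serialization(self, tmp_path):
        ts, _ = _regression_data(19, n=40, d=3)
        model = fit_baseline(RegressorSpec("SVR"), ts)
        with pytest.raises(TypeError, match="serialization"):
            save_model(model, str(tmp_path / "m.json"))
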