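"""Strategy assembly, split protocol, metrics, Pearson screen, pipeline."""

import numpy as np
import pandas as pd
import pytest

from pigmorph.evaluation import (
    STRATEGY_COLUMNS,
    build_strategy_dataset,
    evaluate,
    grid_search_cv,
    pearson_screen,
    run_pipeline,
    split,
)
from pigmorph.models import RegressorSpec, TrainingSet, fit_baseline, predict


def _fake_tables(n_pigs=10, frames_per_pig=4, seed=0):
    rng = np.random.default_rng(seed)
    pigs = [f"pig{i:03d}" for i in range(n_pigs)]
    rows = []
    for p in pigs:
        for j in range(frames_per_pig):
            rows.append(
                {
                    "frame_id": f"{p}_f{j:03d}",
                    "pig_id": p,
                    "area_px2": rng.uniform(1e4, 5e4),
                    "per_px": rng.uniform(500, 1500),
                    "pbl_px": rng.uniform(300, 700),
                    "phw_px": rng.uniform(80, 200),
                    "ecc": rng.uniform(0.8, 0.99),
                    "dev": rng.uniform(0.85, 0.99),
                }
            )
    feats = pd.DataFrame(rows)
    biometry = pd.DataFrame(
        {
            "pig_id": pigs,
            "weight_kg": rng.uniform(104, 138, n_pigs),
            "body_length_cm": rng.uniform(110, 135, n_pigs),
            "hip_width_cm": rng.uniform(30, 38, n_pigs),
            "body_height_cm": rng.uniform(65, 74, n_pigs),
            "hip_height_cm": rng.uniform(70, 82, n_pigs),
        }
    )
    corrected = pd.DataFrame(
        {
            "bl_hat_cm": rng.uniform(110, 135, len(feats)),
            "hw_hat_cm": rng.uniform(30, 38, len(feats)),
            "hdep_hat_cm": rng.uniform(68, 78, len(feats)),
        }
    )
    return feats, biometry, corrected


class TestStrategyAssembly:
    @pytest.mark.parametrize(
        "strategy,expected",
        [
            ("1", ("area_px2", "per_px", "pbl_px", "phw_px", "ecc", "dev")),
            ("1b", ("area_px2", "per_px", "pbl_px", "phw_px", "ecc")),
            ("2", ("area_px2", "per_px", "bl_hat_cm", "hw_hat_cm", "ecc", "dev")),
            (
                "3",
                (
                    "area_px2", "per_px", "bl_hat_cm", "hw_hat_cm", "ecc", "dev",
                    "hdep_hat_cm",
                ),
            ),
        ],
    )
    def test_column_sets_per_strategy(self, strategy, expected):
        feats, biometry, corrected = _fake_tables()
        ds = build_strategy_dataset(feats, biometry, strategy, corrected)
        assert tuple(ds.frame.columns) == expected
        assert STRATEGY_COLUMNS[strategy] == expected
        assert len(ds.frame) == len(feats)
        assert (ds.weights.to_numpy() > 0).all()

    def test_corrected_required_for_strategies_2_and_3(self):
        feats, biometry, _ = _fake_tables()
        for s in ("2", "3"):
            with pytest.raises(ValueError, match="corrected"):
                build_strategy_dataset(feats, biometry, s)

    def test_unknown_strategy_rejected(self):
        feats, biometry, _ = _fake_tables()
        with pytest.raises(ValueError, match="unknown strategy"):
            build_strategy_dataset(feats, biometry, "4")


class TestSplit:
    def test_seven_three_floor_convention(self):
        feats, biometry, _ = _fake_tables(n_pigs=43, frames_per_pig=35)  # 1505 rows
        ds = build_strategy_dataset(feats, biometry, "1")
        plan = split(ds, ratio=0.7, seed=1)
        assert len(plan.train) == 1053 and len(plan.test) == 452

    def test_partition_is_disjoint_and_complete(self):
        feats, biometry, _ = _fake_tables()
        ds = build_strategy_dataset(feats, biometry, "1")
        plan = split(ds, seed=2)
        combined = np.concatenate([plan.train, plan.test])
        assert len(np.unique(combined)) == len(ds.frame)

    def test_by_pig_mode_keeps_pigs_on_one_side(self):
        feats, biometry, _ = _fake_tables(n_pigs=12)
        ds = build_strategy_dataset(feats, biometry, "1")
        plan = split(ds, mode="by-pig", seed=3)
        pigs = ds.pig_ids.to_numpy()
        assert set(pigs[plan.train]).isdisjoint(set(pigs[plan.test]))
        assert len(plan.train) + len(plan.test) == len(pigs)

    def test_same_seed_same_plan(self):
        feats, biometry, _ = _fake_tables()
        ds = build_strategy_dataset(feats, biometry, "1")
        a, b = split(ds, seed=9), split(ds, seed=9)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)

    def test_degenerate_sizes_rejected(self):
        feats, biometry, _ = _fake_tables(n_pigs=1, frames_per_pig=1)
        ds = build_strategy_dataset(feats, biometry, "1")
        with pytest.raises(ValueError):
            split(ds)


def _metrics_oracle(y, p, ref=None):
    """Independent transcription of the four error formulas."""
    y, p = np.asarray(y, float), np.asarray(p, float)
    M = len(y)
    mae = sum(abs(p[i] - y[i]) for i in range(M)) / M
    mape = 100.0 / M * sum(abs((p[i] - y[i]) / y[i]) for i in range(M))
    rmse = (sum((p[i] - y[i]) ** 2 for i in range(M)) / M) ** 0.5
    ybar = np.mean(y) if ref is None else ref
    r2 = 1.0 - sum((p[i] - y[i]) ** 2 for i in range(M)) / sum(
        (ybar - y[i]) ** 2 for i in range(M)
    )
    return mae, mape, rmse, r2


class TestMetrics:
    def test_hand_computed_pair(self):
        m = evaluate(np.array([100.0, 120.0]), np.array([110.0, 110.0]))
        assert m.mae == pytest.approx(10.0)
        assert m.rmse == pytest.approx(10.0)
        assert m.mape == pytest.approx(9.1667, abs=1e-3)

    def test_perfect_prediction(self):
        y = np.array([104.0, 120.0, 138.0])
        m = evaluate(y, y)
        assert (m.mae, m.mape, m.rmse, m.r2) == (0.0, 0.0, 0.0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dual_transcription(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(100, 140, 50)
        p = y + rng.normal(0, 3, 50)
        m = evaluate(y, p)
        mae, mape, rmse, r2 = _metrics_oracle(y, p)
        assert m.mae == pytest.approx(mae)
        assert m.mape == pytest.approx(mape)
        assert m.rmse == pytest.approx(rmse)
        assert m.r2 == pytest.approx(r2)
        assert m.mae <= m.rmse
        assert m.r2 <= 1.0

    def test_literal_predicted_mean_baseline_variant(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(100, 140, 30)
        p = y + rng.normal(0, 5, 30)
        literal = evaluate(y, p, r2_baseline="predicted")
        _, _, _, expected = _metrics_oracle(y, p, ref=p.mean())
        assert literal.r2 == pytest.approx(expected)

    def test_zero_true_value_rejected_for_mape(self):
        with pytest.raises(ValueError, match="MAPE"):
            evaluate(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestPearsonScreen:
    def test_perfect_positive_and_negative(self):
        w = np.linspace(100, 140, 20)
        table = pd.DataFrame({"same": w, "anti": -w})
        r = pearson_screen(table, w)
        assert r["same"] == pytest.approx(1.0)
        assert r["anti"] == pytest.approx(-1.0)

    def test_zero_variance_flagged_not_silent(self):
        w = np.linspace(100, 140, 10)
        table = pd.DataFrame({"flat": np.ones(10)})
        with pytest.warns(UserWarning, match="zero variance"):
            r = pearson_screen(table, w)
        assert np.isnan(r["flat"])

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            pearson_screen(pd.DataFrame({"x": [1.0, 2.0]}), np.array([1.0, 2.0]))


class TestGridSearch:
    def test_single_point_grid_returned(self):
        feats, biometry, _ = _fake_tables()
        ds = build_strategy_dataset(feats, biometry, "1")
        best, score = grid_search_cv(
            RegressorSpec("KRR"), {"alpha": [0.5]}, ds, k=3, seed=0
        )
        assert best == {"alpha": 0.5} and np.isfinite(score)

    def test_best_point_matches_independent_re_evaluation(self):
        feats, biometry, _ = _fake_tables(n_pigs=8, frames_per_pig=5, seed=3)
        ds = build_strategy_dataset(feats, biometry, "1")
        grid = {"alpha": [0.1, 1.0, 10.0]}
        best, best_score = grid_search_cv(RegressorSpec("KRR"), grid, ds, k=4, seed=5)
        # Re-evaluate every grid point with the same fold plan.
        from pigmorph.evaluation import _kfold_indices

        X = ds.frame.to_numpy(float)
        y = ds.weights.to_numpy(float)
        folds = _kfold_indices(len(y), 4, 5)
        scores = {}
        for alpha in grid["alpha"]:
            rmses = []
            for fold in folds:
                m = np.ones(len(y), bool)
                m[fold] = False
                model = fit_baseline(
                    RegressorSpec("KRR", {"alpha": alpha}), TrainingSet(X[m], y[m])
                )
                pred = predict(model, X[fold])
                rmses.append(np.sqrt(np.mean((pred - y[fold]) ** 2)))
            scores[alpha] = np.mean(rmses)
        assert best["alpha"] == min(scores, key=scores.get)
        assert best_score == pytest.approx(scores[best["alpha"]])

    def test_fold_sizes_balanced(self):
        from pigmorph.evaluation import _kfold_indices

        folds = _kfold_indices(23, 5, 0)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
        assert sorted(np.concatenate(folds)) == list(range(23))


@pytest.fixture(scope="module")
def tiny_report(small_camera):
    cfg = {
        "n_pigs": 8,
        "frames_per_pig": 3,
        "seed": 4,
        "camera": {
            "height_above_ground": 145.0,
            "focal_scale": 260.0,
            "image_width": 960,
            "image_height": 720,
        },
        "strategies": ["1", "2"],
        "methods": ["XGBoost", "LR"],
        "hyperparams": {"XGBoost": {"rounds": 40}},
    }
    return run_pipeline(cfg), cfg


class TestPipeline:
    def test_report_complete_and_finite(self, tiny_report):
        report, cfg = tiny_report
        assert set(report.metrics.index) == {
            (s, m) for s in cfg["strategies"] for m in cfg["methods"]
        }
        assert np.isfinite(report.metrics.to_numpy()).all()
        assert len(report.features) == cfg["n_pigs"] * cfg["frames_per_pig"]
        n_test = len(report.split_plan.test)
        assert len(report.predictions) == n_test * len(cfg["strategies"]) * len(
            cfg["methods"]
        )

    def test_no_leakage_refit_on_train_rows_is_identical(self, tiny_report):
        """Deleting held-out rows entirely must not change test predictions."""
        report, cfg = tiny_report
        ds = build_strategy_dataset(report.features, report.biometry, "1")
        plan = report.split_plan
        X = ds.frame.to_numpy(float)
        y = ds.weights.to_numpy(float)
        spec = RegressorSpec("XGBoost", {"rounds": 40}, seed=cfg["seed"])
        full = fit_baseline(spec, TrainingSet(X[plan.train], y[plan.train]))
        Xtr = X[plan.train].copy()  # test rows physically absent
        pruned = fit_baseline(spec, TrainingSet(Xtr, y[plan.train].copy()))
        assert np.array_equal(full.predict(X[plan.test]), pruned.predict(X[plan.test]))

    def test_grid_search_path_smoke(self, small_camera):
        cfg = {
            "n_pigs": 6,
            "frames_per_pig": 2,
            "seed": 6,
            "camera": {"focal_scale": 260.0, "image_width": 960, "image_height": 720},
            "strategies": ["1"],
            "methods": ["KRR"],
            "grids": {"KRR": {"alpha": [0.1, 1.0]}},
            "cv_folds": 3,
        }
        report = run_pipeline(cfg)
        assert ("1", "KRR") in report.best_params
        assert report.best_params[("1", "KRR")]["alpha"] in (0.1, 1.0)
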