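"""Strategy datasets, split/CV protocol, metrics and the end-to-end driver.

Three feature-combination strategies feed the weight regressors (plus the
five-feature ablation that drops Dev):

* ``1``  — raw image features  (Area, Per, PBL, PHW, Ecc, Dev)
* ``1b`` — ablation without Dev (Area, Per, PBL, PHW, Ecc)
* ``2``  — corrected body size  (Area, Per, BL_hat, HW_hat, Ecc, Dev)
* ``3``  — strategy 2 plus the estimated camera distance Hdep_hat

Protocol: a seeded 7:3 train/test split (by frame, or by pig to rule out
identity leakage), exhaustive grid search scored by five-fold
cross-validated RMSE on the training split, and MAE / MAPE / RMSE / R2 on
the held-out frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from . import features as _features
from . import masks as _masks
from .correction import apply_correction, fit_correction
from .models import RegressorSpec, TrainingSet, fit_baseline, predict
from .synthetic import CameraConfig, CurvatureDistribution, generate_dataset

STRATEGY_COLUMNS: dict[str, tuple[str, ...]] = {
    "1": ("area_px2", "per_px", "pbl_px", "phw_px", "ecc", "dev"),
    "1b": ("area_px2", "per_px", "pbl_px", "phw_px", "ecc"),
    "2": ("area_px2", "per_px", "bl_hat_cm", "hw_hat_cm", "ecc", "dev"),
    "3": ("area_px2", "per_px", "bl_hat_cm", "hw_hat_cm", "ecc", "dev", "hdep_hat_cm"),
}


@dataclass(frozen=True)
class StrategyDataset:
    """Feature matrix + weight targets for one strategy."""

    strategy: str
    frame: pd.DataFrame          # index frame_id; feature columns in order
    weights: pd.Series           # kg, aligned with frame
    pig_ids: pd.Series

    @property
    def training_set(self) -> TrainingSet:
        return TrainingSet(
            self.frame.to_numpy(dtype=float),
            self.weights.to_numpy(dtype=float),
            tuple(self.frame.columns),
        )


def build_strategy_dataset(
    features: pd.DataFrame,
    biometry: pd.DataFrame,
    strategy: str,
    corrected: pd.DataFrame | None = None,
) -> StrategyDataset:
    """Assemble the per-strategy design matrix.

    ``features`` carries frame_id, pig_id and the six image features;
    ``corrected`` (required for strategies 2 and 3) the per-frame corrected
    measurements, aligned on the same index as ``features``.
    """
    if strategy not in STRATEGY_COLUMNS:
        raise ValueError(f"unknown strategy {strategy!r}; valid: {sorted(STRATEGY_COLUMNS)}")
    cols = STRATEGY_COLUMNS[strategy]
    table = features.set_index("frame_id")
    if strategy in ("2", "3"):
        if corrected is None:
            raise ValueError(f"strategy {strategy} requires corrected features")
        corr = corrected.copy()
        corr.index = table.index
        table = table.join(corr)
    bio = biometry.set_index("pig_id")["weight_kg"]
    missing = sorted(set(table["pig_id"]) - set(bio.index))
    if missing:
        raise ValueError(f"frames reference pigs with no biometry: {missing}")
    weights = pd.Series(
        bio.loc[table["pig_id"]].to_numpy(), index=table.index, name="weight_kg"
    )
    return StrategyDataset(
        strategy=strategy,
        frame=table.loc[:, list(cols)],
        weights=weights,
        pig_ids=table["pig_id"],
    )


@dataclass(frozen=True)
class SplitPlan:
    train: np.ndarray
    test: np.ndarray
    ratio: float
    mode: str
    seed: int


def split(
    dataset: StrategyDataset,
    ratio: float = 0.7,
    mode: str = "by-frame",
    seed: int = 0,
) -> SplitPlan:
    """Seeded train/test partition.

    ``by-frame``: uniform random assignment with train size floor(ratio*n).
    ``by-pig``: whole pigs are assigned to one side (no identity leakage);
    the train fraction then only approximates the ratio.
    """
    n = len(dataset.frame)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    if mode == "by-frame":
        perm = rng.permutation(n)
        k = int(np.floor(ratio * n))
        if k < 1 or k >= n:
            raise ValueError(f"degenerate split sizes for n={n}, ratio={ratio}")
        return SplitPlan(np.sort(perm[:k]), np.sort(perm[k:]), ratio, mode, seed)
    if mode == "by-pig":
        pigs = dataset.pig_ids.to_numpy()
        uniq = pd.unique(pigs)
        if len(uniq) < 2:
            raise ValueError("by-pig split needs >= 2 pigs")
        order = rng.permutation(len(uniq))
        target = int(np.floor(ratio * n))
        train_pigs: set = set()
        count = 0
        for i in order:
            if count >= target or len(train_pigs) == len(uniq) - 1:
                break
            train_pigs.add(uniq[i])
            count += int((pigs == uniq[i]).sum())
        is_train = np.isin(pigs, list(train_pigs))
        return SplitPlan(
            np.flatnonzero(is_train), np.flatnonzero(~is_train), ratio, mode, seed
        )
    raise ValueError(f"unknown split mode {mode!r}")


@dataclass(frozen=True)
class EvalMetrics:
    mae: float   # kg
    mape: float  # percent
    rmse: float  # kg
    r2: float

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "mape": self.mape, "rmse": self.rmse, "r2": self.r2}


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    r2_baseline: str = "observed",
) -> EvalMetrics:
    """MAE, MAPE (percent), RMSE and R2.

    ``r2_baseline`` selects the reference level in the R2 denominator:
    ``"observed"`` (the conventional mean of the observations, default) or
    ``"predicted"`` (mean of the predictions).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if np.any(y_true == 0):
        raise ValueError("MAPE undefined: y_true contains zeros")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(y_true)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if r2_baseline == "observed":
        ref = y_true.mean()
    elif r2_baseline == "predicted":
        ref = y_pred.mean()
    else:
        raise ValueError("r2_baseline must be 'observed' or 'predicted'")
    denom = float(np.sum((ref - y_true) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / denom if denom > 0 else float("nan")
    return EvalMetrics(mae=mae, mape=mape, rmse=rmse, r2=r2)


def pearson_screen(features: pd.DataFrame, weights: np.ndarray) -> pd.Series:
    """Pearson r of every numeric feature column against weight.

    Zero-variance columns yield NaN with a warning rather than failing
    silently.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if len(w) < 3:
        raise ValueError("need >= 3 rows for a correlation screen")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(w) == 0:
            warnings.warn(f"zero variance in {col!r} or weights: correlation undefined")
            out[col] = float("nan")
        else:
            out[col] = float(np.corrcoef(x, w)[0, 1])
    return pd.Series(out, name="pearson_r")


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def grid_search_cv(
    spec: RegressorSpec,
    grid: Mapping[str, Iterable[Any]],
    dataset: StrategyDataset,
    train_idx: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive grid search scored by mean k-fold validation RMSE.

    Only the training rows (``train_idx``, default all) are used.  Ties go
    to the first grid point in iteration order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    keys = list(grid)
    combos = [dict(zip(keys, vals)) for vals in product(*(grid[kk] for kk in keys))]
    if not combos:
        raise ValueError("empty grid")
    X = dataset.frame.to_numpy(dtype=float)
    y = dataset.weights.to_numpy(dtype=float)
    if train_idx is not None:
        X, y = X[train_idx], y[train_idx]
    n = len(y)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} rows")
    folds = _kfold_indices(n, k, seed)
    best: tuple[float, dict] | None = None
    for combo in combos:
        rmses = []
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            model = fit_baseline(
                RegressorSpec(spec.method, {**spec.hyperparams, **combo}, spec.seed),
                TrainingSet(X[mask], y[mask]),
            )
            pred = predict(model, X[fold])
            rmses.append(float(np.sqrt(np.mean((pred - y[fold]) ** 2))))
        score = float(np.mean(rmses))
        if best is None or score < best[0]:
            best = (score, combo)
    assert best is not None
    return best[1], best[0]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "n_pigs": 39,
    "frames_per_pig": 39,
    "seed": 0,
    "camera": {},            # CameraConfig overrides
    "curvature_sd": 0.004,   # 1/cm
    "edge_noise": 0.0,
    "kernel_size": 70,
    "strategies": ["1", "2"],
    "methods": ["XGBoost", "RFR"],
    "hyperparams": {},       # per-method dicts
    "grids": {},             # per-method grid for CV search (optional)
    "split": {"ratio": 0.7, "mode": "by-frame"},
    "cv_folds": 5,
    "r2_baseline": "observed",
    "correction": {"include_hdep_input": False},
}


@dataclass
class PipelineReport:
    """Everything the end-to-end run produces."""

    metrics: pd.DataFrame        # rows: (strategy, method) -> mae/mape/rmse/r2
    correlations: pd.Series      # Pearson screen of strategy-1 features
    predictions: pd.DataFrame    # frame_id, strategy, method, true, predicted
    features: pd.DataFrame
    corrected: pd.DataFrame | None
    biometry: pd.DataFrame
    scene_truth: pd.DataFrame
    split_plan: SplitPlan
    best_params: dict = field(default_factory=dict)


def run_pipeline(config: Mapping[str, Any] | None = None) -> PipelineReport:
    """Simulate, extract, correct, assemble, split, fit and evaluate.

    Executes the full chain for every requested (strategy, method) pair and
    returns the per-cell metrics plus all intermediate tables.  Any stage
    failure propagates with its own error message.
    """
    cfg: dict[str, Any] = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    camera = CameraConfig(**cfg["camera"])
    from .synthetic import scene_table

    scenes, biometry = generate_dataset(
        n_pigs=int(cfg["n_pigs"]),
        frames_per_pig=int(cfg["frames_per_pig"]),
        camera=camera,
        curvature=CurvatureDistribution(sd=float(cfg["curvature_sd"])),
        seed=seed,
        edge_noise=float(cfg["edge_noise"]),
    )
    truth = scene_table(scenes)

    rows = []
    for s in scenes:
        cleaned = _masks.largest_component(
            _masks.morphological_open(s.mask, int(cfg["kernel_size"]))
        )
        f = _features.extract_features(cleaned)
        rows.append(
            {"frame_id": s.frame_id, "pig_id": s.biometry.pig_id, **f.as_dict()}
        )
    feats = pd.DataFrame(rows)

    # Split first (leakage hygiene), then fit correction on training frames.
    strategies = [str(s) for s in cfg["strategies"]]
    base = build_strategy_dataset(feats, biometry, "1")
    plan = split(
        base,
        ratio=float(cfg["split"]["ratio"]),
        mode=str(cfg["split"]["mode"]),
        seed=seed,
    )

    corrected = None
    if any(s in ("2", "3") for s in strategies):
        corr_model = fit_correction(
            feats.iloc[plan.train],
            biometry,
            camera,
            hyperparams=cfg.get("correction", {}).get("hyperparams"),
            seed=seed,
            include_hdep_input=bool(
                cfg.get("correction", {}).get("include_hdep_input", False)
            ),
        )
        corrected = apply_correction(corr_model, feats)

    correlations = pearson_screen(
        base.frame, base.weights.to_numpy()
    )

    metric_rows = []
    pred_rows = []
    best_params: dict = {}
    for strat in strategies:
        ds = build_strategy_dataset(feats, biometry, strat, corrected)
        X = ds.frame.to_numpy(dtype=float)
        y = ds.weights.to_numpy(dtype=float)
        for method in cfg["methods"]:
            hp = dict(cfg["hyperparams"].get(method, {}))
            grid = cfg["grids"].get(method)
            spec = RegressorSpec(method, hp, seed=seed)
            if grid:
                chosen, _ = grid_search_cv(
                    spec, grid, ds, train_idx=plan.train,
                    k=int(cfg["cv_folds"]), seed=seed,
                )
                hp.update(chosen)
                best_params[(strat, method)] = chosen
                spec = RegressorSpec(method, hp, seed=seed)
            model = fit_baseline(
                spec, TrainingSet(X[plan.train], y[plan.train], tuple(ds.frame.columns))
            )
            pred = predict(model, X[plan.test])
            m = evaluate(y[plan.test], pred, r2_baseline=str(cfg["r2_baseline"]))
            metric_rows.append({"strategy": strat, "method": method, **m.as_dict()})
            pred_rows.extend(
                {
                    "frame_id": fid,
                    "strategy": strat,
                    "method": method,
                    "weight_true_kg": yt,
                    "weight_pred_kg": yp,
                }
                for fid, yt, yp in zip(
                    ds.frame.index[plan.test], y[plan.test], pred
                )
            )
    metrics = pd.DataFrame(metric_rows).set_index(["strategy", "method"])
    predictions = pd.DataFrame(pred_rows)
    return PipelineReport(
        metrics=metrics,
        correlations=correlations,
        predictions=predictions,
        features=feats,
        corrected=corrected,
        biometry=biometry,
        scene_truth=truth,
        split_plan=plan,
        best_params=best_params,
    )
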