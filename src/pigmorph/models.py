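"""Tree-ensemble regressors and the 10-method baseline registry.

The three learners at the heart of the weight-estimation comparison are
implemented natively:

* ``RegressionTree`` — greedy top-down CART-style induction.  Split quality
  is the reduction in within-node sum of squared deviations (variance
  impurity, the regression analogue of information gain, which is undefined
  for continuous targets).
* ``RandomForest`` — bagged trees with per-split feature subsampling; the
  forest prediction is the exact arithmetic mean of the tree predictions.
* ``GradientBoosting`` — Newton (second-order) boosting with squared loss:
  per round the gradients are ``g = yhat - y`` and hessians ``h = 1``; a
  tree is grown on the split gain
  ``1/2 [G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda) - G^2/(H+lambda)] - gamma``
  with leaf weights ``-G/(H+lambda)``, and the ensemble is updated with
  shrinkage ``eta``.

The remaining comparison methods (LR, Lasso, KRR, AdaBoost.R2, Stacking,
SVR, MLP, BP) satisfy the same fit/predict contract; SVR and the two neural
baselines delegate to scikit-learn behind an adapter, everything else is
implemented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

__all__ = [
    "TrainingSet",
    "RegressionTree",
    "RandomForest",
    "GradientBoosting",
    "RegressorSpec",
    "fit_tree",
    "fit_random_forest",
    "fit_gboost",
    "fit_baseline",
    "predict",
    "VALID_METHODS",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix (frames x features) and weight targets (kg)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(X) != len(y):
            raise ValueError("X and y row counts differ")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values are not allowed")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y.ravel())
        if not self.feature_names:
            object.__setattr__(
                self, "feature_names", tuple(f"x{i}" for i in range(X.shape[1]))
            )


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------


def _best_split_sse(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    feats: np.ndarray,
    min_leaf: int,
) -> tuple[int, float] | None:
    """Exhaustive best (feature, threshold) by SSE reduction.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values.  Ties break to the lowest feature index, then lowest threshold.
    Returns None when no admissible split exists.
    """
    n = idx.size
    ysub = y[idx]
    best: tuple[float, int, float] | None = None  # (children_sse, feat, thr)
    for f in feats:
        x = X[idx, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ys = ysub[order]
        cs = np.cumsum(ys)
        css = np.cumsum(ys * ys)
        nl = np.arange(1, n)
        valid = xs[1:] != xs[:-1]
        valid &= (nl >= min_leaf) & (n - nl >= min_leaf)
        if not valid.any():
            continue
        sl, sl2 = cs[:-1], css[:-1]
        total, total2 = cs[-1], css[-1]
        nr = n - nl
        sse = (sl2 - sl * sl / nl) + ((total2 - sl2) - (total - sl) ** 2 / nr)
        sse = np.where(valid, sse, np.inf)
        i = int(np.argmin(sse))  # first minimum -> lowest threshold
        if best is None or sse[i] < best[0] - 1e-12:
            thr = float((xs[i] + xs[i + 1]) / 2.0)
            best = (float(sse[i]), int(f), thr)
    if best is None:
        return None
    return best[1], best[2]


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.value}
        assert self.left is not None and self.right is not None
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "_Node":
        if "leaf" in d:
            return _Node(value=float(d["leaf"]))
        return _Node(
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=_Node.from_dict(d["left"]),
            right=_Node.from_dict(d["right"]),
        )


def _predict_node(node: _Node, X: np.ndarray, out: np.ndarray, idx: np.ndarray) -> None:
    if node.is_leaf:
        out[idx] = node.value
        return
    go_left = X[idx, node.feature] <= node.threshold
    assert node.left is not None and node.right is not None
    _predict_node(node.left, X, out, idx[go_left])
    _predict_node(node.right, X, out, idx[~go_left])


class RegressionTree:
    """Single CART-style regression tree with variance-impurity splits."""

    def __init__(
        self,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        features_per_split: float = 1.0,
        seed: int = 0,
    ):
        if min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if not 0 < features_per_split <= 1:
            raise ValueError("features_per_split must lie in (0, 1]")
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.features_per_split = features_per_split
        self.seed = seed
        self.root_: _Node | None = None
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) == 0:
            raise ValueError("cannot fit a tree on empty data")
        self.n_features_ = X.shape[1]
        rng = np.random.default_rng(self.seed)
        n_sub = max(1, int(round(self.features_per_split * X.shape[1])))

        def grow(idx: np.ndarray, depth: int) -> _Node:
            node = _Node(value=float(y[idx].mean()))
            if (
                (self.max_depth is not None and depth >= self.max_depth)
                or idx.size < 2 * self.min_samples_leaf
                or np.ptp(y[idx]) == 0.0
            ):
                return node
            if n_sub < X.shape[1]:
                feats = np.sort(rng.choice(X.shape[1], size=n_sub, replace=False))
            else:
                feats = np.arange(X.shape[1])
            split = _best_split_sse(X, y, idx, feats, self.min_samples_leaf)
            if split is None:
                return node
            f, thr = split
            go_left = X[idx, f] <= thr
            node.feature, node.threshold = f, thr
            node.left = grow(idx[go_left], depth + 1)
            node.right = grow(idx[~go_left], depth + 1)
            return node

        self.root_ = grow(np.arange(len(X)), 0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.root_ is None:
            raise RuntimeError("tree is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape}"
            )
        out = np.empty(len(X), dtype=float)
        _predict_node(self.root_, X, out, np.arange(len(X)))
        return out

    def to_dict(self) -> dict:
        assert self.root_ is not None
        return {
            "kind": "tree",
            "n_features": self.n_features_,
            "params": {
                "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "features_per_split": self.features_per_split,
                "seed": self.seed,
            },
            "root": self.root_.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "RegressionTree":
        t = RegressionTree(**d["params"])
        t.root_ = _Node.from_dict(d["root"])
        t.n_features_ = d["n_features"]
        return t


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


class RandomForest:
    """Bagging ensemble; prediction is the exact mean over trees."""

    def __init__(
        self,
        n_trees: int = 200,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        features_per_split: float = 1.0 / 3.0,
        bootstrap: bool = True,
        seed: int = 0,
    ):
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.features_per_split = features_per_split
        self.bootstrap = bootstrap
        self.seed = seed
        self.trees_: list[RegressionTree] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = len(X)
        if n == 0:
            raise ValueError("cannot fit a forest on empty data")
        ss = np.random.SeedSequence(self.seed).spawn(self.n_trees)
        self.trees_ = []
        for k in range(self.n_trees):
            rng = np.random.default_rng(ss[k])
            idx = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
            tree = RegressionTree(
                max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                features_per_split=self.features_per_split,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise RuntimeError("forest is not fitted")
        preds = np.stack([t.predict(X) for t in self.trees_])
        return preds.mean(axis=0)

    def to_dict(self) -> dict:
        return {
            "kind": "forest",
            "params": {
                "n_trees": self.n_trees,
                "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "features_per_split": self.features_per_split,
                "bootstrap": self.bootstrap,
                "seed": self.seed,
            },
            "trees": [t.to_dict() for t in self.trees_],
        }

    @staticmethod
    def from_dict(d: dict) -> "RandomForest":
        m = RandomForest(**d["params"])
        m.trees_ = [RegressionTree.from_dict(t) for t in d["trees"]]
        return m


# ---------------------------------------------------------------------------
# Newton boosting
# ---------------------------------------------------------------------------


def _best_split_gh(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    idx: np.ndarray,
    lam: float,
    gamma: float,
    min_leaf: int,
) -> tuple[int, float, float] | None:
    """Best split by second-order gain; None if no split has positive gain."""
    n = idx.size
    gsub, hsub = g[idx], h[idx]
    G, H = gsub.sum(), hsub.sum()
    parent = G * G / (H + lam)
    best: tuple[float, int, float] | None = None  # (gain, feat, thr)
    for f in range(X.shape[1]):
        x = X[idx, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        gl = np.cumsum(gsub[order])[:-1]
        hl = np.cumsum(hsub[order])[:-1]
        nl = np.arange(1, n)
        valid = xs[1:] != xs[:-1]
        valid &= (nl >= min_leaf) & (n - nl >= min_leaf)
        if not valid.any():
            continue
        gain = 0.5 * (
            gl * gl / (hl + lam)
            + (G - gl) ** 2 / (H - hl + lam)
            - parent
        ) - gamma
        gain = np.where(valid, gain, -np.inf)
        i = int(np.argmax(gain))
        if gain[i] > 0 and (best is None or gain[i] > best[0] + 1e-12):
            thr = float((xs[i] + xs[i + 1]) / 2.0)
            best = (float(gain[i]), f, thr)
    if best is None:
        return None
    return best[1], best[2], best[0]


class GradientBoosting:
    """Second-order boosted trees with squared loss.

    ``rounds`` trees of depth ``max_depth`` are fitted to gradients
    ``g = yhat - y`` (hessians 1); leaf weight is ``-G/(H + lam)`` and splits
    must clear the per-leaf penalty ``gamma``.  The prediction is
    ``base_score + eta * sum_k tree_k(x)``.
    """

    def __init__(
        self,
        rounds: int = 300,
        eta: float = 0.1,
        lam: float = 1.0,
        gamma: float = 0.0,
        max_depth: int = 4,
        min_samples_leaf: int = 1,
        seed: int = 0,
    ):
        if rounds < 1:
            raise ValueError("rounds must be >= 1")
        if lam < 0 or gamma < 0:
            raise ValueError("lam and gamma must be non-negative")
        if eta <= 0:
            raise ValueError("eta must be positive")
        self.rounds = rounds
        self.eta = eta
        self.lam = lam
        self.gamma = gamma
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.base_score_: float = 0.0
        self.trees_: list[_Node] = []
        self.n_features_: int | None = None
        self.train_rmse_: list[float] = []

    def _grow(self, X: np.ndarray, g: np.ndarray, h: np.ndarray) -> _Node:
        def grow(idx: np.ndarray, depth: int) -> _Node:
            G, H = g[idx].sum(), h[idx].sum()
            node = _Node(value=float(-G / (H + self.lam)))
            if depth >= self.max_depth or idx.size < 2 * self.min_samples_leaf:
                return node
            split = _best_split_gh(
                X, g, h, idx, self.lam, self.gamma, self.min_samples_leaf
            )
            if split is None:
                return node
            f, thr, _ = split
            go_left = X[idx, f] <= thr
            node.feature, node.threshold = f, thr
            node.left = grow(idx[go_left], depth + 1)
            node.right = grow(idx[~go_left], depth + 1)
            return node

        return grow(np.arange(len(X)), 0)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoosting":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) == 0:
            raise ValueError("cannot fit on empty data")
        self.n_features_ = X.shape[1]
        self.base_score_ = float(y.mean())
        yhat = np.full(len(y), self.base_score_)
        self.trees_ = []
        self.train_rmse_ = []
        h = np.ones(len(y))
        for _ in range(self.rounds):
            g = yhat - y
            root = self._grow(X, g, h)
            out = np.empty(len(y))
            _predict_node(root, X, out, np.arange(len(y)))
            yhat = yhat + self.eta * out
            self.trees_.append(root)
            self.train_rmse_.append(float(np.sqrt(np.mean((yhat - y) ** 2))))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.n_features_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(f"expected {self.n_features_} features, got {X.shape}")
        yhat = np.full(len(X), self.base_score_)
        idx = np.arange(len(X))
        out = np.empty(len(X))
        for root in self.trees_:
            _predict_node(root, X, out, idx)
            yhat += self.eta * out
        return yhat

    def to_dict(self) -> dict:
        return {
            "kind": "gboost",
            "n_features": self.n_features_,
            "base_score": self.base_score_,
            "params": {
                "rounds": self.rounds,
                "eta": self.eta,
                "lam": self.lam,
                "gamma": self.gamma,
                "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "seed": self.seed,
            },
            "trees": [t.to_dict() for t in self.trees_],
        }

    @staticmethod
    def from_dict(d: dict) -> "GradientBoosting":
        m = GradientBoosting(**d["params"])
        m.base_score_ = float(d["base_score"])
        m.n_features_ = d["n_features"]
        m.trees_ = [_Node.from_dict(t) for t in d["trees"]]
        return m


# ---------------------------------------------------------------------------
# Classical baselines
# ---------------------------------------------------------------------------


class LinearRegressionNE:
    """Ordinary least squares via the normal equations (lstsq)."""

    def __init__(self) -> None:
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearRegressionNE":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        A = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "coef": [] if self.coef_ is None else list(map(float, self.coef_)),
            "intercept": self.intercept_,
        }

    @staticmethod
    def from_dict(d: dict) -> "LinearRegressionNE":
        m = LinearRegressionNE()
        m.coef_ = np.array(d["coef"], dtype=float)
        m.intercept_ = float(d["intercept"])
        return m


class KernelRidge:
    """Closed-form kernel ridge regression (RBF or linear kernel)."""

    def __init__(self, alpha: float = 1.0, kernel: str = "rbf", gamma: float | None = None):
        if kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        self.alpha = alpha
        self.kernel = kernel
        self.gamma = gamma
        self.X_: np.ndarray | None = None
        self.dual_: np.ndarray | None = None
        self.y_mean_: float = 0.0
        self._x_mean: np.ndarray | None = None
        self._x_scale: np.ndarray | None = None

    def _gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return A @ B.T
        g = self.gamma if self.gamma is not None else 1.0 / A.shape[1]
        d2 = (
            (A * A).sum(1)[:, None] + (B * B).sum(1)[None, :] - 2.0 * A @ B.T
        )
        return np.exp(-g * np.maximum(d2, 0.0))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KernelRidge":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        self._x_mean = X.mean(axis=0)
        scale = X.std(axis=0)
        self._x_scale = np.where(scale > 0, scale, 1.0)
        Xs = (X - self._x_mean) / self._x_scale
        self.y_mean_ = float(y.mean())
        K = self._gram(Xs, Xs)
        n = len(X)
        self.dual_ = np.linalg.solve(K + self.alpha * np.eye(n), y - self.y_mean_)
        self.X_ = Xs
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.dual_ is None:
            raise RuntimeError("model is not fitted")
        Xs = (np.asarray(X, dtype=float) - self._x_mean) / self._x_scale
        return self._gram(Xs, self.X_) @ self.dual_ + self.y_mean_

    def to_dict(self) -> dict:
        return {
            "kind": "krr",
            "alpha": self.alpha,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "X": self.X_.tolist(),
            "dual": self.dual_.tolist(),
            "y_mean": self.y_mean_,
            "x_mean": self._x_mean.tolist(),
            "x_scale": self._x_scale.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "KernelRidge":
        m = KernelRidge(alpha=d["alpha"], kernel=d["kernel"], gamma=d["gamma"])
        m.X_ = np.array(d["X"])
        m.dual_ = np.array(d["dual"])
        m.y_mean_ = d["y_mean"]
        m._x_mean = np.array(d["x_mean"])
        m._x_scale = np.array(d["x_scale"])
        return m


class LassoCD:
    """L1-penalised least squares by cyclic coordinate descent.

    Objective (scikit-learn convention): ``1/(2n) ||y - Xb||^2 + alpha ||b||_1``
    on internally standardised features; coefficients are returned on the
    original scale and the intercept absorbs the centring.
    """

    def __init__(self, alpha: float = 1.0, tol: float = 1e-8, max_iter: int = 10000):
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.coef_: np.ndarray | None = None
        self.intercept_: float = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LassoCD":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)
        Xs = (X - x_mean) / x_scale
        y_mean = y.mean()
        r = y - y_mean  # residual with beta = 0
        beta = np.zeros(d)
        col_sq = (Xs * Xs).sum(axis=0)
        for _ in range(self.max_iter):
            delta = 0.0
            for j in range(d):
                if col_sq[j] == 0:
                    continue
                rho = Xs[:, j] @ r + beta[j] * col_sq[j]
                bj = _soft_threshold(rho / n, self.alpha) / (col_sq[j] / n)
                if bj != beta[j]:
                    r += Xs[:, j] * (beta[j] - bj)
                    delta = max(delta, abs(bj - beta[j]))
                    beta[j] = bj
            if delta < self.tol:
                break
        self.coef_ = beta / x_scale
        self.intercept_ = float(y_mean - x_mean @ self.coef_)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def to_dict(self) -> dict:
        return {
            "kind": "lasso",
            "alpha": self.alpha,
            "coef": list(map(float, self.coef_)),
            "intercept": self.intercept_,
        }

    @staticmethod
    def from_dict(d: dict) -> "LassoCD":
        m = LassoCD(alpha=d["alpha"])
        m.coef_ = np.array(d["coef"])
        m.intercept_ = float(d["intercept"])
        return m


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


class AdaBoostR2:
    """AdaBoost.R2 with linear loss on shallow regression trees.

    Each round draws a weighted bootstrap sample, fits a tree, computes the
    linear loss per sample, reweights, and stores the log confidence
    ``log(1/beta)``.  Prediction is the weighted median over estimators.
    """

    def __init__(self, n_estimators: int = 50, max_depth: int = 3, seed: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.seed = seed
        self.estimators_: list[RegressionTree] = []
        self.log_conf_: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AdaBoostR2":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = len(X)
        w = np.full(n, 1.0 / n)
        rng = np.random.default_rng(self.seed)
        self.estimators_, self.log_conf_ = [], []
        for _ in range(self.n_estimators):
            idx = rng.choice(n, size=n, replace=True, p=w)
            tree = RegressionTree(
                max_depth=self.max_depth, seed=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(X[idx], y[idx])
            err = np.abs(tree.predict(X) - y)
            emax = err.max()
            if emax <= 0:
                self.estimators_.append(tree)
                self.log_conf_.append(np.log(1e12))
                break
            loss = err / emax
            ebar = float((w * loss).sum())
            if ebar >= 0.5:
                break
            beta = ebar / (1.0 - ebar)
            self.estimators_.append(tree)
            self.log_conf_.append(float(np.log(1.0 / max(beta, 1e-300))))
            w = w * beta ** (1.0 - loss)
            w = w / w.sum()
        if not self.estimators_:  # first round already too weak: keep it
            tree = RegressionTree(max_depth=self.max_depth, seed=self.seed)
            tree.fit(X, y)
            self.estimators_.append(tree)
            self.log_conf_.append(1.0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.stack([t.predict(X) for t in self.estimators_])  # (m, n)
        conf = np.asarray(self.log_conf_)
        order = np.argsort(preds, axis=0)
        sorted_preds = np.take_along_axis(preds, order, axis=0)
        csum = np.cumsum(conf[order], axis=0)
        half = 0.5 * conf.sum()
        pick = (csum >= half).argmax(axis=0)
        return sorted_preds[pick, np.arange(preds.shape[1])]

    def to_dict(self) -> dict:
        return {
            "kind": "adaboost_r2",
            "params": {
                "n_estimators": self.n_estimators,
                "max_depth": self.max_depth,
                "seed": self.seed,
            },
            "estimators": [t.to_dict() for t in self.estimators_],
            "log_conf": self.log_conf_,
        }

    @staticmethod
    def from_dict(d: dict) -> "AdaBoostR2":
        m = AdaBoostR2(**d["params"])
        m.estimators_ = [RegressionTree.from_dict(t) for t in d["estimators"]]
        m.log_conf_ = list(d["log_conf"])
        return m


class StackingRegressor:
    """Out-of-fold stacking: {forest, boosting, KRR} under a linear meta-model."""

    def __init__(self, k: int = 5, seed: int = 0):
        self.k = k
        self.seed = seed
        self.base_: list[Any] = []
        self.meta_: LinearRegressionNE | None = None

    def _make_bases(self) -> list[Any]:
        return [
            RandomForest(n_trees=50, seed=self.seed),
            GradientBoosting(rounds=100, seed=self.seed),
            KernelRidge(alpha=1.0),
        ]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StackingRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = len(X)
        rng = np.random.default_rng(self.seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, self.k)
        oof = np.zeros((n, 3))
        for fold in folds:
            train = np.setdiff1d(perm, fold, assume_unique=True)
            for j, model in enumerate(self._make_bases()):
                model.fit(X[train], y[train])
                oof[fold, j] = model.predict(X[fold])
        self.meta_ = LinearRegressionNE().fit(oof, y)
        self.base_ = [m.fit(X, y) for m in self._make_bases()]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.meta_ is None:
            raise RuntimeError("model is not fitted")
        Z = np.column_stack([m.predict(X) for m in self.base_])
        return self.meta_.predict(Z)


class _SklearnAdapter:
    """Uniform fit/predict wrapper with internal feature standardisation."""

    def __init__(self, factory: Callable[[], Any]):
        self._factory = factory
        self._model: Any = None
        self._x_mean: np.ndarray | None = None
        self._x_scale: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        self._x_mean = X.mean(axis=0)
        scale = X.std(axis=0)
        self._x_scale = np.where(scale > 0, scale, 1.0)
        self._model = self._factory()
        self._model.fit((X - self._x_mean) / self._x_scale, np.asarray(y, float).ravel())
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("model is not fitted")
        Xs = (np.asarray(X, dtype=float) - self._x_mean) / self._x_scale
        return np.asarray(self._model.predict(Xs), dtype=float)


def _make_svr(hp: dict) -> _SklearnAdapter:
    from sklearn.svm import SVR

    return _SklearnAdapter(
        lambda: SVR(
            C=hp.get("C", 100.0),
            epsilon=hp.get("epsilon", 0.1),
            gamma=hp.get("gamma", "scale"),
        )
    )


def _make_mlp(hp: dict, seed: int) -> _SklearnAdapter:
    from sklearn.neural_network import MLPRegressor

    return _SklearnAdapter(
        lambda: MLPRegressor(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (64, 32)),
            max_iter=hp.get("max_iter", 2000),
            random_state=seed,
        )
    )


def _make_bp(hp: dict, seed: int) -> _SklearnAdapter:
    # Classic back-propagation network: single logistic hidden layer, SGD.
    from sklearn.neural_network import MLPRegressor

    return _SklearnAdapter(
        lambda: MLPRegressor(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (32,)),
            activation="logistic",
            solver="sgd",
            learning_rate_init=hp.get("learning_rate_init", 0.01),
            max_iter=hp.get("max_iter", 3000),
            random_state=seed,
        )
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

VALID_METHODS = (
    "XGBoost",
    "BP",
    "Lasso",
    "LR",
    "MLP",
    "RFR",
    "Stacking",
    "SVR",
    "KRR",
    "Adaboost",
)


@dataclass(frozen=True)
class RegressorSpec:
    """Named entry of the 10-method comparison registry."""

    method: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; valid: {', '.join(VALID_METHODS)}"
            )


def fit_tree(
    data: TrainingSet,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    features_per_split: float = 1.0,
    seed: int = 0,
) -> RegressionTree:
    if len(data.y) < 1:
        raise ValueError("empty training set")
    return RegressionTree(max_depth, min_samples_leaf, features_per_split, seed).fit(
        data.X, data.y
    )


def fit_random_forest(
    data: TrainingSet,
    n_trees: int = 200,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    features_per_split: float = 1.0 / 3.0,
    bootstrap: bool = True,
    seed: int = 0,
) -> RandomForest:
    return RandomForest(
        n_trees, max_depth, min_samples_leaf, features_per_split, bootstrap, seed
    ).fit(data.X, data.y)


def fit_gboost(
    data: TrainingSet,
    rounds: int = 300,
    eta: float = 0.1,
    lam: float = 1.0,
    gamma: float = 0.0,
    max_depth: int = 4,
    min_samples_leaf: int = 1,
    seed: int = 0,
) -> GradientBoosting:
    return GradientBoosting(
        rounds, eta, lam, gamma, max_depth, min_samples_leaf, seed
    ).fit(data.X, data.y)


def fit_baseline(spec: RegressorSpec, data: TrainingSet):
    """Fit any registry method on a training set."""
    hp = dict(spec.hyperparams)
    m = spec.method
    if m == "XGBoost":
        model: Any = GradientBoosting(
            rounds=hp.get("rounds", 300),
            eta=hp.get("eta", 0.1),
            lam=hp.get("lam", 1.0),
            gamma=hp.get("gamma", 0.0),
            max_depth=hp.get("max_depth", 4),
            seed=spec.seed,
        )
    elif m == "RFR":
        model = RandomForest(
            n_trees=hp.get("n_trees", 200),
            max_depth=hp.get("max_depth"),
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            features_per_split=hp.get("features_per_split", 1.0 / 3.0),
            seed=spec.seed,
        )
    elif m == "LR":
        model = LinearRegressionNE()
    elif m == "Lasso":
        model = LassoCD(alpha=hp.get("alpha", 1.0))
    elif m == "KRR":
        model = KernelRidge(
            alpha=hp.get("alpha", 1.0),
            kernel=hp.get("kernel", "rbf"),
            gamma=hp.get("gamma"),
        )
    elif m == "Adaboost":
        model = AdaBoostR2(
            n_estimators=hp.get("n_estimators", 50),
            max_depth=hp.get("max_depth", 3),
            seed=spec.seed,
        )
    elif m == "Stacking":
        model = StackingRegressor(k=hp.get("k", 5), seed=spec.seed)
    elif m == "SVR":
        model = _make_svr(hp)
    elif m == "MLP":
        model = _make_mlp(hp, spec.seed)
    elif m == "BP":
        model = _make_bp(hp, spec.seed)
    else:  # pragma: no cover - guarded by RegressorSpec
        raise ValueError(m)
    return model.fit(data.X, data.y)


def predict(model: Any, X: np.ndarray) -> np.ndarray:
    """Row-wise predictions; empty input yields empty output."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        return np.empty(0)
    return np.asarray(model.predict(X), dtype=float)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_KINDS = {
    "tree": RegressionTree,
    "forest": RandomForest,
    "gboost": GradientBoosting,
    "linear": LinearRegressionNE,
    "krr": KernelRidge,
    "lasso": LassoCD,
    "adaboost_r2": AdaBoostR2,
}


def save_model(model: Any, path: str) -> None:
    """Dump a native model to the portable JSON tree/coefficient format."""
    if not hasattr(model, "to_dict"):
        raise TypeError(
            f"{type(model).__name__} does not support JSON serialization; "
            "refit it from its spec and seed instead"
        )
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path: str) -> Any:
    with open(path) as fh:
        d = json.load(fh)
    cls = _KINDS.get(d.get("kind"))
    if cls is None:
        raise ValueError(f"unknown model kind {d.get('kind')!r}")
    return cls.from_dict(d)
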