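"""Least-squares SVM with RBF kernel, one-vs-one multiclass wrapping,
gamma grid search and stratified cross-validation.

Training a binary LS-SVM is a single linear solve of the KKT system

    [ 0   1^T          ] [ b     ]   [ 0 ]
    [ 1   K + I/gamma  ] [ alpha ] = [ y ]

with K_ij = exp(-||x_i - x_j||^2 / sigma2).  The regularization gamma is
searched pointwise on [1, 1000]; sigma2 defaults to the median pairwise
squared distance of the calibration rows (median heuristic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.model_selection import StratifiedKFold

from .spectra import SpectraMatrix

GAMMA_RANGE = (1.0, 1000.0)


def _as_xy(matrix, labels=None):
    if isinstance(matrix, SpectraMatrix):
        return matrix.reflectance, (matrix.labels if labels is None else np.asarray(labels))
    if labels is None:
        raise ValueError("labels required when matrix is a bare array")
    return np.asarray(matrix, dtype=float), np.asarray(labels)


@dataclass
class LSSVMParams:
    gamma: float = 10.0
    sigma2: float | None = None  # None -> median heuristic at fit time
    gamma_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(0, 3, 100)
    )
    sigma2_grid: np.ndarray | None = None
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        self.gamma_grid = np.asarray(self.gamma_grid, dtype=float)
        if self.gamma_grid.size == 0:
            raise ValueError("gamma grid must be non-empty")


def rbf_kernel(X_a: np.ndarray, X_b: np.ndarray, sigma2: float) -> np.ndarray:
    """K_ij = exp(-||a_i - b_j||^2 / sigma2)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    X_a = np.atleast_2d(np.asarray(X_a, dtype=float))
    X_b = np.atleast_2d(np.asarray(X_b, dtype=float))
    sq = cdist(X_a, X_b, metric="sqeuclidean")
    return np.exp(-sq / sigma2)


def median_heuristic_sigma2(X: np.ndarray) -> float:
    """Median pairwise squared Euclidean distance (positive fallback 1.0)."""
    d2 = pdist(np.asarray(X, dtype=float), metric="sqeuclidean")
    med = float(np.median(d2)) if d2.size else 0.0
    return med if med > 0 else 1.0


@dataclass
class BinaryLSSVM:
    X_train: np.ndarray
    alpha: np.ndarray
    bias: float
    gamma: float
    sigma2: float

    def decision(self, X) -> np.ndarray:
        K = rbf_kernel(np.atleast_2d(X), self.X_train, self.sigma2)
        return K @ self.alpha + self.bias

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)


def lssvm_train_binary(X, y, gamma: float, sigma2: float) -> BinaryLSSVM:
    """Solve the LS-SVM KKT linear system directly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("binary labels must be in {-1, +1}")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    n = X.shape[0]
    K = rbf_kernel(X, X, sigma2)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        cond = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"singular LS-SVM system (condition number {cond:.3e})"
        ) from err
    return BinaryLSSVM(X, sol[1:], float(sol[0]), gamma, sigma2)


@dataclass
class LSSVMModel:
    """One-vs-one multiclass LS-SVM; majority vote, ties broken by summed
    decision values."""

    classes: list
    models: dict  # (i, j) -> BinaryLSSVM, classes[i] coded +1, classes[j] -1
    gamma: float
    sigma2: float

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        k = len(self.classes)
        votes = np.zeros((n, k))
        margin = np.zeros((n, k))
        for (i, j), model in self.models.items():
            d = model.decision(X)
            pos = d >= 0
            votes[pos, i] += 1
            votes[~pos, j] += 1
            margin[:, i] += d
            margin[:, j] -= d
        # majority vote; break ties by summed decision values
        best = np.zeros(n, dtype=int)
        for r in range(n):
            top = np.flatnonzero(votes[r] == votes[r].max())
            best[r] = top[np.argmax(margin[r, top])]
        return np.asarray(self.classes, dtype=object)[best]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": [str(c) for c in self.classes],
            "gamma": self.gamma,
            "sigma2": self.sigma2,
            "models": {
                f"{i}|{j}": {
                    "alpha": m.alpha.tolist(),
                    "bias": m.bias,
                    "X_train": m.X_train.tolist(),
                }
                for (i, j), m in self.models.items()
            },
        }
        Path(path).write_text(json.dumps(payload))


def lssvm_train_multiclass(
    matrix, labels=None, params: LSSVMParams | None = None, class_order=None
) -> LSSVMModel:
    """Train one binary LS-SVM per class pair (one-vs-one)."""
    if params is None:
        params = LSSVMParams()
    X, y = _as_xy(matrix, labels)
    classes = list(class_order) if class_order is not None else list(dict.fromkeys(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    sigma2 = params.sigma2 if params.sigma2 is not None else median_heuristic_sigma2(X)
    models = {}
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            rows = np.flatnonzero((y == classes[i]) | (y == classes[j]))
            yb = np.where(y[rows] == classes[i], 1.0, -1.0)
            models[(i, j)] = lssvm_train_binary(X[rows], yb, params.gamma, sigma2)
    return LSSVMModel(classes, models, params.gamma, sigma2)


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def cross_validate(
    matrix, labels=None, params: LSSVMParams | None = None, folds: int = 10
) -> float:
    """Stratified k-fold CV accuracy (pooled over folds, i.e. weighted by
    fold size), seeded through ``params.seed``."""
    if params is None:
        params = LSSVMParams()
    X, y = _as_xy(matrix, labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    correct = 0
    for train, test in _stratified_folds(y, folds, params.seed):
        model = lssvm_train_multiclass(X[train], y[train], params)
        correct += int(np.sum(model.predict(X[test]) == y[test]))
    return correct / y.size


def tune(
    matrix, labels=None, params: LSSVMParams | None = None, folds: int | None = None
) -> LSSVMParams:
    """Pointwise grid search for gamma (and optionally sigma2) by stratified
    CV accuracy; ties resolve to the smallest gamma, then smallest sigma2."""
    if params is None:
        params = LSSVMParams()
    X, y = _as_xy(matrix, labels)
    folds = folds if folds is not None else params.cv_folds
    sigma2_grid = (
        np.sort(np.asarray(params.sigma2_grid, dtype=float))
        if params.sigma2_grid is not None
        else np.array([median_heuristic_sigma2(X)])
    )
    gamma_grid = np.sort(params.gamma_grid)
    split_folds = _stratified_folds(y, folds, params.seed)
    best = None
    for gamma in gamma_grid:
        for sigma2 in sigma2_grid:
            correct = 0
            for train, test in split_folds:
                model = lssvm_train_multiclass(
                    X[train], y[train], replace(params, gamma=gamma, sigma2=sigma2)
                )
                correct += int(np.sum(model.predict(X[test]) == y[test]))
            acc = correct / y.size
            if best is None or acc > best[0] + 1e-12:
                best = (acc, gamma, sigma2)
    _, gamma, sigma2 = best
    return replace(params, gamma=float(gamma), sigma2=float(sigma2))
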