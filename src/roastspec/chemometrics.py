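"""In-house PCA and PLS1 engines used by the wavelength selectors.

PCA is a mean-centered SVD with a fixed sign convention (the largest-
magnitude element of each loading is positive) so loading plots are
reproducible.  PLS1 is the classic NIPALS recursion on centered X and y;
with the full latent dimension it reproduces the ordinary least-squares
solution, which the test suite uses as an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .spectra import SpectraMatrix


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, SpectraMatrix):
        return matrix.reflectance
    return np.asarray(matrix, dtype=float)


@dataclass
class PCAModel:
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # p x k, orthonormal columns
    scores: np.ndarray  # n x k
    explained_variance_fraction: np.ndarray  # length k

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: np.asarray(v).tolist() for k, v in asdict(self).items()})
        )


@dataclass
class PLSModel:
    n_latent: int
    coefficients: np.ndarray  # length p, on the original (uncentered) scale
    intercept: float
    x_mean: np.ndarray
    y_mean: float

    def predict(self, X) -> np.ndarray:
        X = _as_array(X)
        return X @ self.coefficients + self.intercept

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_latent": self.n_latent,
                    "coefficients": self.coefficients.tolist(),
                    "intercept": self.intercept,
                    "x_mean": self.x_mean.tolist(),
                    "y_mean": self.y_mean,
                }
            )
        )


def pca_fit(matrix, k: int) -> PCAModel:
    """Principal components of the column-mean-centered data via SVD."""
    X = _as_array(matrix)
    n, p = X.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k must be in [1, {min(n, p)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    # sign convention: largest-|.| element of each loading positive
    for j in range(k):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    if total_var == 0.0:
        frac = np.zeros(k)
    else:
        frac = s[:k] ** 2 / total_var
    return PCAModel(mean, loadings, scores, frac)


def pls1_fit(matrix, y, n_latent: int) -> PLSModel:
    """PLS1 regression by NIPALS on centered X and y."""
    X = _as_array(matrix)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("y must align with the rows of X")
    if not 1 <= n_latent <= min(n - 1, p):
        raise ValueError(f"n_latent must be in [1, {min(n - 1, p)}]")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    q = np.zeros(n_latent)
    for a in range(n_latent):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # nothing left to model
            W, P, q = W[:, :a], P[:, :a], q[:a]
            n_latent = a
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-28:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            n_latent = a
            break
        p_load = E.T @ t / tt
        q_a = float(f @ t) / tt
        E = E - np.outer(t, p_load)
        f = f - q_a * t
        W[:, a], P[:, a], q[a] = w, p_load, q_a

    if n_latent == 0:
        coef = np.zeros(p)
    else:
        # B = W (P^T W)^{-1} q
        coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(n_latent, coef, intercept, x_mean, y_mean)


def rmse(y_true, y_pred) -> float:
    """Root mean squared error."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def response_vector(labels, class_order) -> np.ndarray:
    """Encode class labels as ordinal dummy numbers 1..n_classes."""
    class_order = list(class_order)
    lookup = {c: i + 1 for i, c in enumerate(class_order)}
    try:
        return np.array([lookup[l] for l in labels], dtype=float)
    except KeyError as err:
        raise ValueError(f"label {err.args[0]!r} not in class order") from err
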