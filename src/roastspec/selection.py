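"""Effective-wavelength (EW) selection.

Three selectors, each returning a :class:`SelectionResult`:

* ``xloading_select`` — local extrema of the absolute PCA X-loading curves,
  pooled over components and ranked by magnitude.
* ``spa_select`` — successive projections algorithm: forward chains that
  greedily maximize the residual column norm after orthogonal projection
  onto the span of the bands already chosen, scored by hold-out MLR RMSE.
* ``random_frog`` — reversible-jump Monte-Carlo subset search with an inner
  PLS1 model; a band's importance is its selection probability (SP), the
  fraction of retained subsets containing it, averaged over repeated runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import PCAModel, pls1_fit, rmse
from .grid import WavelengthGrid
from .sampling import kennard_stone_split
from .spectra import SpectraMatrix


@dataclass
class SelectionResult:
    """Per-band importance plus the ranked list of chosen wavelengths."""

    method: str
    importance: np.ndarray
    selected_indices: np.ndarray
    selected_wavelengths: np.ndarray
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.selected_wavelengths,
                "importance": self.importance[self.selected_indices],
                "rank": np.arange(1, self.selected_indices.size + 1),
                "method": self.method,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "method": self.method,
                    "importance": self.importance.tolist(),
                    "selected_indices": self.selected_indices.tolist(),
                    "selected_wavelengths": self.selected_wavelengths.tolist(),
                    "flags": self.flags,
                }
            )
        )


def top_k(result: SelectionResult, k: int) -> SelectionResult:
    """Truncate the ranked selection to its first k entries."""
    if k > result.importance.size:
        raise ValueError("k exceeds the number of bands")
    return SelectionResult(
        result.method,
        result.importance,
        result.selected_indices[:k],
        result.selected_wavelengths[:k],
        list(result.flags),
    )


# ---------------------------------------------------------------- X-loading


def _local_extrema(curve: np.ndarray) -> np.ndarray:
    """Indices of local maxima of a non-negative curve, endpoints included."""
    n = curve.size
    if n == 1:
        return np.array([0])
    keep = np.zeros(n, dtype=bool)
    keep[0] = curve[0] >= curve[1]
    keep[-1] = curve[-1] >= curve[-2]
    interior = (curve[1:-1] >= curve[:-2]) & (curve[1:-1] >= curve[2:])
    keep[1:-1] = interior
    return np.flatnonzero(keep)


def xloading_select(
    pca: PCAModel,
    grid: WavelengthGrid,
    n_components: int = 2,
    n_select: int = 7,
) -> SelectionResult:
    """Pick the bands where the absolute X-loadings peak.

    Local extrema of |loading| are pooled over the first ``n_components``
    components (a band counted once, at its largest magnitude) and the
    ``n_select`` largest survive.
    """
    if pca.n_components < n_components:
        raise ValueError("PCA model has too few components")
    abs_load = np.abs(pca.loadings[:, :n_components])
    importance = abs_load.max(axis=1)
    candidate_best = {}
    for j in range(n_components):
        for idx in _local_extrema(abs_load[:, j]):
            val = abs_load[idx, j]
            if val > candidate_best.get(idx, -1.0):
                candidate_best[idx] = val
    cands = np.array(sorted(candidate_best), dtype=int)
    vals = np.array([candidate_best[i] for i in cands])
    order = np.argsort(-vals, kind="stable")  # ties -> lowest band index
    ranked = cands[order]
    flags = []
    if ranked.size < n_select:
        flags.append(f"only {ranked.size} extrema found (requested {n_select})")
    chosen = ranked[:n_select]
    return SelectionResult(
        "xloading", importance, chosen, grid.centers[chosen], flags
    )


# ---------------------------------------------------------------------- SPA


def _spa_chain(X: np.ndarray, start: int, length: int) -> tuple[list[int], bool]:
    """One SPA forward chain from a starting column.

    After each pick every remaining column is projected onto the orthogonal
    complement of the chosen column; the next pick maximizes residual norm.
    Returns (chain, truncated_flag).
    """
    R = X.astype(float).copy()
    p = X.shape[1]
    chain = [start]
    available = np.ones(p, dtype=bool)
    available[start] = False
    current = start
    for _ in range(length - 1):
        v = R[:, current]
        vv = float(v @ v)
        if vv < 1e-24:
            return chain, True
        proj = (v @ R) / vv
        R = R - np.outer(v, proj)
        norms = np.linalg.norm(R, axis=0)
        norms[~available] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] < 1e-12:
            return chain, True
        chain.append(nxt)
        available[nxt] = False
        current = nxt
    return chain, False


def _holdout_mlr_rmse(
    X: np.ndarray, y: np.ndarray, cols, train_idx, val_idx
) -> float:
    cols = np.asarray(cols, dtype=int)
    A = np.column_stack([np.ones(len(train_idx)), X[np.ix_(train_idx, cols)]])
    beta, *_ = np.linalg.lstsq(A, y[train_idx], rcond=None)
    Av = np.column_stack([np.ones(len(val_idx)), X[np.ix_(val_idx, cols)]])
    return rmse(y[val_idx], Av @ beta)


def spa_select(
    matrix,
    y,
    n_select: int = 5,
    validation_fraction: float = 1 / 3,
    grid: WavelengthGrid | None = None,
) -> SelectionResult:
    """Successive projections algorithm with hold-out MLR scoring.

    A chain of ``n_select`` minimally collinear bands is built from every
    possible starting band; each chain is scored by the RMSE of a multiple
    linear regression predicting the dummy-number response on a held-out
    validation split (a deterministic Kennard-Stone row split), and the best
    chain is returned in selection order.
    """
    if isinstance(matrix, SpectraMatrix):
        X, grid = matrix.reflectance, matrix.grid
    else:
        X = np.asarray(matrix, dtype=float)
        if grid is None:
            raise ValueError("grid required when matrix is a bare array")
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_select > p:
        raise ValueError("n_select exceeds the number of bands")
    split = kennard_stone_split(X, 1.0 - validation_fraction)
    train_idx, val_idx = split.calibration_indices, split.prediction_indices

    best = None
    for start in range(p):
        chain, truncated = _spa_chain(X[train_idx], start, n_select)
        score = _holdout_mlr_rmse(X, y, chain, train_idx, val_idx)
        if not np.isfinite(score):
            continue
        if best is None or score < best[0] - 1e-15:
            best = (score, chain, truncated)
    if best is None:
        raise ValueError("no valid SPA chain found")
    score, chain, truncated = best
    chain = np.array(chain, dtype=int)
    importance = np.zeros(p)
    importance[chain] = np.arange(n_select, n_select - chain.size, -1, dtype=float)
    flags = []
    if truncated:
        flags.append("chain truncated early: projections became degenerate")
    return SelectionResult("spa", importance, chain, grid.centers[chain], flags)


# -------------------------------------------------------------- random frog


@dataclass
class RFParams:
    """Random-frog controls: T iterations per run, Q initial subset size,
    theta the proposal-variance coefficient, omega the candidate-pool
    coefficient, eta the acceptance-probability upper bound; SP is averaged
    over n_runs independent runs."""

    T: int = 10000
    Q: int = 50
    theta: float = 0.3
    omega: int = 3
    eta: float = 1.0
    n_runs: int = 50
    inner_latent: int = 10
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.Q < 1:
            raise ValueError("T and Q must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")
        if self.omega < 1 or self.n_runs < 1:
            raise ValueError("omega and n_runs must be >= 1")


def _pls_coef_rank(X: np.ndarray, y: np.ndarray, cols: np.ndarray, params) -> np.ndarray:
    """Column indices of ``cols`` ordered by standardized |PLS coefficient|
    (coefficient times band SD, i.e. coefficient magnitude on autoscaled
    variables), descending.  Standardizing keeps the importance ranking
    invariant to per-band scale."""
    k = min(params.inner_latent, cols.size, X.shape[0] - 1)
    model = pls1_fit(X[:, cols], y, k)
    weight = np.abs(model.coefficients) * X[:, cols].std(axis=0)
    order = np.argsort(-weight, kind="stable")
    return cols[order]


def _cv_rmse(X: np.ndarray, y: np.ndarray, cols: np.ndarray, folds, params) -> float:
    """K-fold cross-validated RMSE of the inner PLS1 model on a subset."""
    press = 0.0
    for val in folds:
        train = np.setdiff1d(np.arange(X.shape[0]), val, assume_unique=False)
        k = min(params.inner_latent, cols.size, train.size - 1)
        try:
            model = pls1_fit(X[np.ix_(train, cols)], y[train], k)
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        resid = y[val] - model.predict(X[np.ix_(val, cols)])
        press += float(resid @ resid)
    return float(np.sqrt(press / X.shape[0]))


def random_frog(
    matrix,
    y,
    params: RFParams | None = None,
    grid: WavelengthGrid | None = None,
) -> SelectionResult:
    """Monte-Carlo subset search; returns bands ranked by mean selection
    probability over ``params.n_runs`` independent runs.

    Each iteration proposes a candidate subset whose size is drawn from a
    normal law centered on the current size with SD theta * size; the subset
    grows by sampling an omega-fold candidate pool ranked by inner-PLS
    coefficient magnitude and shrinks by dropping the least important
    members.  The candidate is accepted with probability
    min(eta, RMSE_current / RMSE_candidate) under cross-validated PLS RMSE.
    """
    if params is None:
        params = RFParams()
    if isinstance(matrix, SpectraMatrix):
        X, grid = matrix.reflectance, matrix.grid
    else:
        X = np.asarray(matrix, dtype=float)
        if grid is None:
            raise ValueError("grid required when matrix is a bare array")
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if params.Q > p:
        raise ValueError(f"Q={params.Q} exceeds the number of bands ({p})")

    sp_runs = np.zeros((params.n_runs, p))
    for run in range(params.n_runs):
        rng = np.random.default_rng([params.seed, run])
        perm = rng.permutation(n)
        folds = np.array_split(perm, params.cv_folds)
        V = np.sort(rng.choice(p, params.Q, replace=False))
        rmse_V = _cv_rmse(X, y, V, folds, params)
        counts = np.zeros(p)
        for _ in range(params.T):
            size = V.size
            # SD floor of one band keeps the dimension proposal mobile when
            # the subset is small (theta * size < 1 would freeze the chain)
            q_star = int(round(rng.normal(size, max(params.theta * size, 1.0))))
            q_star = min(max(q_star, 1), p)
            if q_star == size:
                V_star, rmse_star = V, rmse_V
            else:
                if q_star < size:
                    ranked = _pls_coef_rank(X, y, V, params)
                    V_star = np.sort(ranked[:q_star])
                else:
                    n_new = q_star - size
                    comp = np.setdiff1d(np.arange(p), V, assume_unique=False)
                    pool_n = min(params.omega * n_new, comp.size)
                    pool = rng.choice(comp, pool_n, replace=False)
                    union = np.concatenate([V, pool])
                    ranked = _pls_coef_rank(X, y, union, params)
                    V_star = np.sort(ranked[:q_star])
                rmse_star = _cv_rmse(X, y, V_star, folds, params)
            if not np.isfinite(rmse_star):
                counts[V] += 1  # candidate rejected outright
                continue
            accept_p = min(params.eta, rmse_V / rmse_star) if rmse_star > 0 else params.eta
            if rng.uniform() <= accept_p:
                V, rmse_V = V_star, rmse_star
            counts[V] += 1
        sp_runs[run] = counts / params.T

    sp = sp_runs.mean(axis=0)
    order = np.argsort(-sp, kind="stable")
    return SelectionResult(
        "rf", sp, order, grid.centers[order], []
    )
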