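"""Kennard-Stone partitioning into calibration and prediction subsets.

Deterministic max-min-distance design: seed with the two most distant
samples in spectral (Euclidean) space, then repeatedly add the sample whose
minimum distance to the already-selected set is largest.  Ties break to the
lowest row index for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .spectra import SpectraMatrix


@dataclass(frozen=True)
class SplitResult:
    calibration_indices: np.ndarray
    prediction_indices: np.ndarray
    ratio: float

    def to_csv(self, path: str | Path, sample_ids=None) -> None:
        n = self.calibration_indices.size + self.prediction_indices.size
        subset = np.empty(n, dtype=object)
        subset[self.calibration_indices] = "calibration"
        subset[self.prediction_indices] = "prediction"
        ids = sample_ids if sample_ids is not None else np.arange(n)
        pd.DataFrame({"sample_id": ids, "subset": subset}).to_csv(path, index=False)


def kennard_stone_split(
    matrix: SpectraMatrix | np.ndarray, cal_fraction: float = 2 / 3
) -> SplitResult:
    """Split rows into calibration (round(cal_fraction * n)) and prediction sets.

    525 rows at a 2:1 ratio yield the classic 350/175 partition.
    """
    X = matrix.reflectance if isinstance(matrix, SpectraMatrix) else np.asarray(matrix, float)
    n = X.shape[0]
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must be in (0, 1)")
    if n < 3:
        raise ValueError("need at least 3 samples")
    n_cal = int(round(cal_fraction * n))
    n_cal = max(2, min(n_cal, n - 1))

    D = squareform(pdist(X, metric="euclidean"))
    # seed pair: maximal distance; ties -> lexicographically smallest (i, j)
    flat = np.argmax(D)  # first occurrence = smallest flat index
    i, j = np.unravel_index(flat, D.shape)
    selected = [min(i, j), max(i, j)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    min_dist[in_set] = -np.inf

    while len(selected) < n_cal:
        nxt = int(np.argmax(min_dist))  # ties -> lowest index
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
        min_dist[in_set] = -np.inf

    cal = np.array(sorted(selected))
    pred = np.flatnonzero(~in_set)
    return SplitResult(cal, pred, cal_fraction)


def kennard_stone_split_per_class(
    matrix: SpectraMatrix, cal_fraction: float = 2 / 3
) -> SplitResult:
    """Run the split independently within each class and merge the indices."""
    cal_parts, pred_parts = [], []
    for label in np.unique(matrix.labels):
        rows = np.flatnonzero(matrix.labels == label)
        sub = kennard_stone_split(matrix.reflectance[rows], cal_fraction)
        cal_parts.append(rows[sub.calibration_indices])
        pred_parts.append(rows[sub.prediction_indices])
    return SplitResult(
        np.sort(np.concatenate(cal_parts)),
        np.sort(np.concatenate(pred_parts)),
        cal_fraction,
    )
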