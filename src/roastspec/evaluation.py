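"""Confusion matrices and overall-accuracy statistics for the seven-class
roast-degree problem (rows = true class, columns = predicted class)."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import ROAST_CLASSES


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray
    class_order: tuple

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError("counts must be square and match class_order")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def metrics_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_total": self.n_total,
                    "correct": int(np.trace(self.counts)),
                    "misclassified": misclassified_count(self),
                    "overall_accuracy": overall_accuracy(self),
                }
            )
        )


def confusion(
    true_labels, predicted_labels, class_order=ROAST_CLASSES
) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size != predicted_labels.size:
        raise ValueError("label vectors must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            unknown = t if t not in index else p
            raise ValueError(f"label {unknown!r} not in class order")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(class_order))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction correctly classified: trace / n_total."""
    if cm.n_total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.n_total


def misclassified_count(cm: ConfusionMatrix) -> int:
    """Off-diagonal total: n_total - trace."""
    return cm.n_total - int(np.trace(cm.counts))
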