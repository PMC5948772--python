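"""Sample-by-band reflectance matrix with class labels.

The central in-memory container: n samples (one mean spectrum per coffee-bean
sample) by p bands, with a wavelength grid and a seven-level roast-degree
label per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import WavelengthGrid

#: Roast-degree class names in roasting order: unroasted, light, moderately
#: light, light medium, medium, moderately dark, dark.
ROAST_CLASSES = ("RD-U", "RD-L", "RD-ML", "RD-LM", "RD-M", "RD-MD", "RD-D")


@dataclass
class SpectraMatrix:
    """Reflectance spectra (n x p) with aligned grid, labels and sample ids."""

    reflectance: np.ndarray
    grid: WavelengthGrid
    labels: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x bands)")
        n, p = self.reflectance.shape
        if p != self.grid.count:
            raise ValueError(
                f"reflectance has {p} bands but grid has {self.grid.count}"
            )
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per row")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"S{i:04d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != (n,):
                raise ValueError("sample_ids must have one entry per row")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def take_rows(self, indices) -> "SpectraMatrix":
        idx = np.asarray(indices)
        return SpectraMatrix(
            self.reflectance[idx], self.grid, self.labels[idx], self.sample_ids[idx]
        )

    def take_bands(self, indices) -> "SpectraMatrix":
        idx = np.asarray(indices)
        return SpectraMatrix(
            self.reflectance[:, idx], self.grid.subset(idx), self.labels, self.sample_ids
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.reflectance,
            columns=[f"{w:.4f}" for w in self.grid.centers],
        )
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV: sample_id, label, then one column per wavelength."""
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraMatrix":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        grid = WavelengthGrid(np.array([float(c) for c in wl_cols]))
        return cls(
            df[wl_cols].to_numpy(dtype=float),
            grid,
            df["label"].to_numpy(),
            df["sample_id"].to_numpy(),
        )
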