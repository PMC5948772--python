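"""Spectral band-center grid for the NIR imaging spectrograph range."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default instrument range: 874-1734 nm sampled at 256 band centers.
DEFAULT_RANGE_NM = (874.0, 1734.0)
DEFAULT_N_BANDS = 256

#: Working window after discarding the noisy detector edges.
WORKING_RANGE_NM = (930.0, 1700.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band-center wavelengths in nanometres.

    The default grid emulates a line-scan NIR imaging spectrograph covering
    874-1734 nm with 256 uniformly spaced bands.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.linspace(*DEFAULT_RANGE_NM, DEFAULT_N_BANDS)
    )

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("grid centers must be a non-empty 1-D array")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("grid centers must be strictly increasing")
        object.__setattr__(self, "centers", centers)

    @property
    def count(self) -> int:
        return int(self.centers.size)

    def __len__(self) -> int:
        return self.count

    def window_mask(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of bands with lo_nm <= center <= hi_nm (closed interval)."""
        return (self.centers >= lo_nm) & (self.centers <= hi_nm)

    def subset(self, indices: np.ndarray) -> "WavelengthGrid":
        return WavelengthGrid(self.centers[np.asarray(indices)])

    def nearest_index(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))
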