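"""Reflectance calibration, ROI spectral extraction and band trimming.

Raw digital numbers are converted to relative reflectance with dark-current
and white-reference frames:

    R = (I_raw - I_dark) / (I_white - I_dark)

Reference frames may be full cubes or a single scan line broadcast along the
transport axis (line-scan geometry).  Per-sample spectra are ROI means; the
working range discards the noisy detector edges (930-1700 nm by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import WavelengthGrid, WORKING_RANGE_NM
from .spectra import SpectraMatrix


@dataclass
class ReflectanceCube:
    """Calibrated relative-reflectance cube (lines x pixels x bands)."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("reflectance cube must be 3-D")
        if self.values.shape[2] != self.grid.count:
            raise ValueError("band axis does not match grid")


def _broadcast_reference(frame: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Accept a full cube or a single (pixels x bands) line reference."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape == shape:
        return frame
    if frame.ndim == 2 and frame.shape == shape[1:]:
        return np.broadcast_to(frame[None, :, :], shape)
    raise ValueError(
        f"reference frame shape {frame.shape} incompatible with cube {shape}"
    )


def calibrate_reflectance(
    raw_cube: np.ndarray,
    dark_frame: np.ndarray,
    white_frame: np.ndarray,
    grid: WavelengthGrid | None = None,
) -> ReflectanceCube:
    """R = (raw - dark) / (white - dark), elementwise.

    Any position where white == dark is a hard error (calibration frames are
    controlled inputs); the first offending (line, pixel, band) is named.
    """
    raw = np.asarray(raw_cube, dtype=float)
    if raw.ndim != 3:
        raise ValueError("raw cube must be 3-D (lines x pixels x bands)")
    dark = _broadcast_reference(dark_frame, raw.shape)
    white = _broadcast_reference(white_frame, raw.shape)
    denom = white - dark
    bad = denom <= 0
    if np.any(bad):
        line, pixel, band = (int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            "white reference must exceed dark reference everywhere; first "
            f"violation at (line={line}, pixel={pixel}, band={band})"
        )
    if grid is None:
        grid = WavelengthGrid(np.linspace(874.0, 1734.0, raw.shape[2]))
    return ReflectanceCube((raw - dark) / denom, grid)


def extract_roi_spectra(
    cube: ReflectanceCube,
    roi_masks,
    labels,
    sample_ids=None,
) -> SpectraMatrix:
    """Mean spectrum over each ROI mask; one row per sample, in mask order."""
    labels = np.asarray(labels)
    if len(roi_masks) != labels.size:
        raise ValueError("one label per ROI mask required")
    H, W, _ = cube.values.shape
    rows = []
    for i, mask in enumerate(roi_masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError(f"mask {i} shape {mask.shape} does not match cube")
        if not mask.any():
            raise ValueError(f"ROI mask {i} is empty")
        rows.append(cube.values[mask].mean(axis=0))
    if sample_ids is None:
        sample_ids = np.array([f"S{i:04d}" for i in range(labels.size)])
    return SpectraMatrix(np.vstack(rows), cube.grid, labels, np.asarray(sample_ids))


def trim_bands(
    matrix: SpectraMatrix,
    lo_nm: float = WORKING_RANGE_NM[0],
    hi_nm: float = WORKING_RANGE_NM[1],
) -> SpectraMatrix:
    """Keep exactly the bands with lo_nm <= center <= hi_nm (closed interval)."""
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be below hi_nm")
    keep = np.flatnonzero(matrix.grid.window_mask(lo_nm, hi_nm))
    if keep.size == 0:
        raise ValueError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
    return matrix.take_bands(keep)
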