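"""Synthetic NIR hyperspectral scenes of coffee-bean samples.

Generates raw hypercubes (digital numbers) with dark/white reference frames,
per-sample ROI masks and roast-degree labels, plus a fast path that emits the
extracted spectra matrix directly.  The forward model inverts the reflectance
calibration: raw = dark + R * (white - dark) + noise, so calibrating a
noiseless scene recovers each class signature exactly.

Class signatures follow the qualitative shape of NIR coffee-bean reflectance:
a smooth baseline rising from 930 nm, absorption valleys near 1210 nm (C-H
second overtone, tracks crude fat), 1350 nm (-CH2 stretch), 1450 nm (O-H
first overtone, water) and weaker features near 940 and 1660 nm, with the
between-class contrast concentrated in the 930-1350 nm region and the valley
depth at 1210 nm varying monotonically with roast degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import WavelengthGrid, WORKING_RANGE_NM
from .spectra import ROAST_CLASSES, SpectraMatrix

#: Absorption feature centers (nm), Gaussian widths (nm) and base depths
#: (reflectance units) of the NIR overtone bands the signatures emulate.
FEATURE_CENTERS_NM = (940.0, 1210.0, 1350.0, 1450.0, 1660.0)
FEATURE_WIDTHS_NM = (20.0, 25.0, 40.0, 35.0, 25.0)
FEATURE_BASE_DEPTHS = (0.03, 0.06, 0.08, 0.18, 0.05)

#: Extra 1210-nm depth of the darkest class relative to the lightest.
DEPTH_1210_CLASS_SPAN = 0.09
#: Center/width of the broad class-contrast lobe (930-1350 nm region).
CONTRAST_CENTER_NM = 1140.0
CONTRAST_WIDTH_NM = 180.0
CONTRAST_AMPLITUDE = 0.09

#: Digital-number scale of the simulated sensor (fixed, arbitrary).
DARK_COUNTS = 100.0
WHITE_COUNTS = 4000.0
BACKGROUND_REFLECTANCE = 0.15

# Bean/ellipse layout geometry (pixels).
_CELL = 9
_RADII = (2.8, 3.4)


def class_names(n_classes: int) -> list[str]:
    """Labels in roasting order; the seven canonical names when they fit."""
    if n_classes <= len(ROAST_CLASSES):
        return list(ROAST_CLASSES[:n_classes])
    return [f"C{i}" for i in range(n_classes)]


@dataclass(frozen=True)
class ClassSignature:
    """Mean reflectance curve of one roast-degree class over a grid."""

    class_index: int
    baseline: np.ndarray
    values: np.ndarray
    feature_depths: dict[float, float]

    def __post_init__(self) -> None:
        if np.any(self.values <= 0) or np.any(self.values >= 1):
            raise ValueError("signature reflectance must lie strictly in (0, 1)")


@dataclass
class SceneConfig:
    """Generator configuration mirroring the study layout: 7 roast classes,
    75 samples per class (525 total), ~30 beans imaged per sample."""

    n_classes: int = 7
    beans_per_sample: int = 30
    samples_per_class: int = 75
    image_height: int | None = None
    image_width: int | None = None
    noise_sd_interior: float = 0.004
    noise_sd_edge: float = 0.04
    edge_bounds: tuple[float, float] = WORKING_RANGE_NM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if min(self.beans_per_sample, self.samples_per_class) < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd_interior < 0 or self.noise_sd_edge < self.noise_sd_interior:
            raise ValueError("require 0 <= noise_sd_interior <= noise_sd_edge")

    @property
    def n_samples(self) -> int:
        return self.n_classes * self.samples_per_class


@dataclass
class RawScene:
    """Raw hypercube in digital numbers plus calibration frames and ROIs."""

    raw_cube: np.ndarray  # (lines, pixels, bands)
    dark_frame: np.ndarray
    white_frame: np.ndarray
    roi_masks: list[np.ndarray]  # boolean (lines, pixels) per sample
    labels: np.ndarray
    grid: WavelengthGrid

    @property
    def roi_label_image(self) -> np.ndarray:
        """Integer label image: 0 = background, i+1 = sample i."""
        out = np.zeros(self.raw_cube.shape[:2], dtype=np.uint16)
        for i, mask in enumerate(self.roi_masks):
            out[mask] = i + 1
        return out


def make_class_signatures(
    grid: WavelengthGrid | None = None,
    n_classes: int = 7,
    seed: int = 0,
    feature_depth_scale: float = 1.0,
) -> list[ClassSignature]:
    """Build per-class reflectance signatures over ``grid``.

    All classes share a smooth quadratic baseline; class contrast enters
    through a broad lobe centered at 1140 nm (largest between-class
    differences in 930-1350 nm) and through the 1210-nm valley depth, which
    deepens monotonically with roast degree.  ``feature_depth_scale=0``
    collapses every class onto the bare baseline (no-signal control).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if grid is None:
        grid = WavelengthGrid()
    rng = np.random.default_rng(seed)
    wl = grid.centers
    u = (wl - 874.0) / 860.0
    baseline = 0.42 + 0.45 * u - 0.30 * u**2 + rng.uniform(-0.01, 0.01)

    def gauss(center: float, width: float) -> np.ndarray:
        return np.exp(-(((wl - center) / width) ** 2))

    contrast_lobe = gauss(CONTRAST_CENTER_NM, CONTRAST_WIDTH_NM)
    signatures = []
    for c in range(n_classes):
        frac = c / (n_classes - 1)
        depths = dict(zip(FEATURE_CENTERS_NM, FEATURE_BASE_DEPTHS))
        depths[1210.0] = depths[1210.0] + DEPTH_1210_CLASS_SPAN * frac
        depths = {k: v * feature_depth_scale for k, v in depths.items()}
        # lighter roast -> higher reflectance in the contrast region
        delta = feature_depth_scale * CONTRAST_AMPLITUDE * (1.0 - 2.0 * frac)
        values = baseline + delta * contrast_lobe
        for (center, width), depth in zip(
            zip(FEATURE_CENTERS_NM, FEATURE_WIDTHS_NM),
            (depths[c_] for c_ in FEATURE_CENTERS_NM),
        ):
            values = values - depth * gauss(center, width)
        signatures.append(
            ClassSignature(
                class_index=c,
                baseline=baseline.copy(),
                values=values,
                feature_depths=depths,
            )
        )
    return signatures


def _bean_layout(config: SceneConfig) -> tuple[int, int, np.ndarray]:
    """Tile geometry: returns (tile_h, tile_w, ellipse boolean stamp)."""
    bcols = int(np.ceil(np.sqrt(config.beans_per_sample)))
    brows = int(np.ceil(config.beans_per_sample / bcols))
    tile_h, tile_w = brows * _CELL + 2, bcols * _CELL + 2
    yy, xx = np.mgrid[0:_CELL, 0:_CELL]
    cy = cx = (_CELL - 1) / 2.0
    ry, rx = _RADII
    stamp = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return tile_h, tile_w, stamp


def roi_pixels_per_sample(config: SceneConfig) -> int:
    """Pixels covered by one sample's ROI under the generator geometry."""
    _, _, stamp = _bean_layout(config)
    return int(stamp.sum()) * config.beans_per_sample


def generate_scene(
    config: SceneConfig, signatures: list[ClassSignature] | None = None
) -> RawScene:
    """Render a raw scene: each sample is a tile of elliptical beans whose
    true reflectance is its class signature; noise is Gaussian in reflectance
    units, 10x stronger (by default) outside the 930-1700 nm working range.
    """
    grid = WavelengthGrid()
    if signatures is None:
        signatures = make_class_signatures(grid, config.n_classes, seed=config.seed)
    if len(signatures) < config.n_classes:
        raise ValueError("signatures do not cover all classes")
    p = signatures[0].values.size
    if p != grid.count:
        raise ValueError("signatures must be defined on the default 256-band grid")

    n_samples = config.n_samples
    tile_h, tile_w, stamp = _bean_layout(config)
    scols = int(np.ceil(np.sqrt(n_samples)))
    srows = int(np.ceil(n_samples / scols))
    need_h, need_w = srows * tile_h, scols * tile_w
    H = config.image_height if config.image_height is not None else need_h
    W = config.image_width if config.image_width is not None else need_w
    if H < need_h or W < need_w:
        raise ValueError(
            f"image {H}x{W} too small for {n_samples} samples of "
            f"{config.beans_per_sample} beans (need {need_h}x{need_w})"
        )

    rng = np.random.default_rng(config.seed)
    wl = grid.centers
    lo, hi = config.edge_bounds
    sd_band = np.where(
        (wl >= lo) & (wl <= hi), config.noise_sd_interior, config.noise_sd_edge
    )

    reflectance = np.full((H, W, p), BACKGROUND_REFLECTANCE, dtype=np.float64)
    roi_masks: list[np.ndarray] = []
    labels = []
    names = class_names(config.n_classes)
    bcols = int(np.ceil(np.sqrt(config.beans_per_sample)))
    for s in range(n_samples):
        c = s // config.samples_per_class
        labels.append(names[c])
        r0 = (s // scols) * tile_h
        c0 = (s % scols) * tile_w
        mask = np.zeros((H, W), dtype=bool)
        for b in range(config.beans_per_sample):
            br, bc = divmod(b, bcols)
            y, x = r0 + 1 + br * _CELL, c0 + 1 + bc * _CELL
            mask[y : y + _CELL, x : x + _CELL] |= stamp
        reflectance[mask] = signatures[c].values
        roi_masks.append(mask)

    if config.noise_sd_interior > 0 or config.noise_sd_edge > 0:
        reflectance += rng.standard_normal(reflectance.shape) * sd_band

    scale = WHITE_COUNTS - DARK_COUNTS
    raw_cube = DARK_COUNTS + reflectance * scale
    dark_frame = np.full_like(raw_cube, DARK_COUNTS)
    white_frame = np.full_like(raw_cube, WHITE_COUNTS)
    return RawScene(
        raw_cube=raw_cube,
        dark_frame=dark_frame,
        white_frame=white_frame,
        roi_masks=roi_masks,
        labels=np.array(labels),
        grid=grid,
    )


def generate_spectra_matrix(
    config: SceneConfig, signatures: list[ClassSignature] | None = None
) -> SpectraMatrix:
    """Fast path: draw ROI-mean spectra directly, bypassing the image stage.

    Each row is its class signature plus Gaussian noise whose per-band SD is
    the pixel SD divided by sqrt(ROI pixel count) — the distribution of the
    ROI mean under the scene model.  Noiseless output is identical to
    generate_scene -> calibrate -> extract.
    """
    grid = WavelengthGrid()
    if signatures is None:
        signatures = make_class_signatures(grid, config.n_classes, seed=config.seed)
    if len(signatures) < config.n_classes:
        raise ValueError("signatures do not cover all classes")
    rng = np.random.default_rng(config.seed)
    wl = grid.centers
    lo, hi = config.edge_bounds
    sd_band = np.where(
        (wl >= lo) & (wl <= hi), config.noise_sd_interior, config.noise_sd_edge
    )
    sd_mean = sd_band / np.sqrt(roi_pixels_per_sample(config))

    names = class_names(config.n_classes)
    rows, labels, ids = [], [], []
    for c in range(config.n_classes):
        base = signatures[c].values
        noise = rng.standard_normal((config.samples_per_class, grid.count)) * sd_mean
        rows.append(base[None, :] + noise)
        labels.extend([names[c]] * config.samples_per_class)
        ids.extend(f"{names[c]}-{i:03d}" for i in range(config.samples_per_class))
    return SpectraMatrix(
        np.vstack(rows), grid, np.array(labels), np.array(ids)
    )


def make_planted_benchmark(
    n_classes: int = 7,
    samples_per_class: int = 75,
    n_bands: int = 100,
    planted_bands: tuple[int, ...] = (10, 30, 50, 70, 90),
    effect: float = 0.08,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[SpectraMatrix, np.ndarray]:
    """Benchmark spectra with a handful of informative bands planted among
    pure-noise bands, for validating wavelength selectors.

    Planted band k carries the pattern (linear roast trend + its own
    orthogonal class contrast) / sqrt(2): each band is individually
    predictive of the dummy-number response, yet no band is redundant given
    the others — the best k-band linear model explains a fraction k/(k+1)
    of the class-trend variance, so every additional planted band genuinely
    improves prediction.  The per-band effect amplitude (default 0.08
    reflectance RMS) dwarfs the noise SD (0.01).  Returns the matrix and the
    sorted planted band indices.
    """
    rng = np.random.default_rng(seed)
    planted = np.sort(np.asarray(planted_bands, dtype=int))
    if planted.size and (planted[0] < 0 or planted[-1] >= n_bands):
        raise ValueError("planted band indices out of range")
    n = n_classes * samples_per_class
    grid = WavelengthGrid(np.linspace(*WORKING_RANGE_NM, n_bands))
    X = 0.5 + rng.standard_normal((n, n_bands)) * noise_sd
    cls = np.repeat(np.arange(n_classes), samples_per_class)
    # orthonormal class contrasts: Legendre-style polynomials in class index
    u = (cls - cls.mean()) / (cls.std() if cls.std() else 1.0)
    lin = u.copy()  # unit RMS by construction
    basis = [np.ones(n) / np.sqrt(n), lin / np.linalg.norm(lin)]
    for k, band in enumerate(planted):
        contrast = u ** (k + 2)
        for b in basis:  # Gram-Schmidt against constant, linear, earlier contrasts
            contrast = contrast - (contrast @ b) * b
        norm = np.linalg.norm(contrast)
        if norm > 1e-12:
            contrast = contrast / norm
            basis.append(contrast)
        contrast = contrast * np.sqrt(n)  # unit RMS per sample
        X[:, band] += effect * (lin + contrast) / np.sqrt(2.0)
    names = class_names(n_classes)
    labels = np.array([names[c] for c in cls])
    ids = np.array([f"{labels[i]}-{i:03d}" for i in range(n)])
    return SpectraMatrix(X, grid, labels, ids), planted
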