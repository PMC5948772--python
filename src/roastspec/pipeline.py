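"""End-to-end orchestration: simulate -> calibrate -> extract -> trim ->
split -> select -> tune -> train -> evaluate, with a reproducible manifest.

Configuration is a validated pydantic model loadable from YAML; every stage
writes its artifact into the run directory and the manifest records the
config hash, seeds and a SHA-256 checksum per artifact, so identical
config + seed reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .calibration import calibrate_reflectance, extract_roi_spectra, trim_bands
from .chemometrics import pca_fit, response_vector
from .evaluation import confusion, misclassified_count, overall_accuracy
from .lssvm import LSSVMParams, cross_validate, lssvm_train_multiclass, tune
from .sampling import kennard_stone_split
from .selection import RFParams, random_frog, spa_select, top_k, xloading_select
from .spectra import SpectraMatrix
from .synthetic import SceneConfig, generate_scene, generate_spectra_matrix, make_class_signatures


class SceneSection(BaseModel):
    n_classes: int = 7
    samples_per_class: int = 75
    beans_per_sample: int = 30
    noise_sd_interior: float = 0.004
    noise_sd_edge: float = 0.04
    use_image_stage: bool = False


class SelectionSection(BaseModel):
    method: str = "rf"  # xloading | spa | rf | none
    k: int = 8
    rf_T: int = 1000
    rf_Q: int = 50
    rf_theta: float = 0.3
    rf_omega: int = 3
    rf_eta: float = 1.0
    rf_n_runs: int = 5
    rf_inner_latent: int = 10

    @field_validator("method")
    @classmethod
    def _known_method(cls, v: str) -> str:
        if v not in {"xloading", "spa", "rf", "none"}:
            raise ValueError(f"unknown selector {v!r}")
        return v


class LSSVMSection(BaseModel):
    tune_gamma: bool = True
    gamma: float = 10.0
    gamma_grid_points: int = 20
    cv_folds: int = 10


class RunConfig(BaseModel):
    """Full pipeline configuration; defaults give the reduced test profile
    (random frog T=1000 / 5 runs, 20-point gamma grid)."""

    output_dir: str = "runs/default"
    seed: int = 0
    scene: SceneSection = Field(default_factory=SceneSection)
    trim_lo_nm: float = 930.0
    trim_hi_nm: float = 1700.0
    cal_fraction: float = 2 / 3
    selection: SelectionSection = Field(default_factory=SelectionSection)
    lssvm: LSSVMSection = Field(default_factory=LSSVMSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate(config: RunConfig) -> SpectraMatrix:
    scene_cfg = SceneConfig(
        n_classes=config.scene.n_classes,
        samples_per_class=config.scene.samples_per_class,
        beans_per_sample=config.scene.beans_per_sample,
        noise_sd_interior=config.scene.noise_sd_interior,
        noise_sd_edge=config.scene.noise_sd_edge,
        seed=config.seed,
    )
    signatures = make_class_signatures(
        n_classes=scene_cfg.n_classes, seed=config.seed
    )
    if config.scene.use_image_stage:
        scene = generate_scene(scene_cfg, signatures)
        cube = calibrate_reflectance(
            scene.raw_cube, scene.dark_frame, scene.white_frame, scene.grid
        )
        return extract_roi_spectra(cube, scene.roi_masks, scene.labels)
    return generate_spectra_matrix(scene_cfg, signatures)


def _select(config: RunConfig, cal: SpectraMatrix, y: np.ndarray):
    method = config.selection.method
    if method == "none":
        return None
    if method == "xloading":
        pca = pca_fit(cal, k=2)
        return xloading_select(pca, cal.grid, n_select=config.selection.k)
    if method == "spa":
        return spa_select(cal, y, n_select=config.selection.k)
    params = RFParams(
        T=config.selection.rf_T,
        Q=min(config.selection.rf_Q, cal.n_bands),
        theta=config.selection.rf_theta,
        omega=config.selection.rf_omega,
        eta=config.selection.rf_eta,
        n_runs=config.selection.rf_n_runs,
        inner_latent=config.selection.rf_inner_latent,
        seed=config.seed,
    )
    return top_k(random_frog(cal, y, params), config.selection.k)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    manifest.json in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)

    matrix = _simulate(config)
    save("spectra.csv", matrix.to_csv)

    trimmed = trim_bands(matrix, config.trim_lo_nm, config.trim_hi_nm)
    split = kennard_stone_split(trimmed, config.cal_fraction)
    save("split.csv", lambda p: split.to_csv(p, trimmed.sample_ids))

    cal = trimmed.take_rows(split.calibration_indices)
    pred = trimmed.take_rows(split.prediction_indices)
    class_order = list(dict.fromkeys(matrix.labels))
    y_cal = response_vector(cal.labels, class_order)

    result = _select(config, cal, y_cal)
    if result is not None:
        save("selection.csv", result.to_csv)
        save("selection.json", result.to_json)
        cal = cal.take_bands(np.sort(result.selected_indices))
        pred = pred.take_bands(np.sort(result.selected_indices))

    # folds can never exceed the smallest per-class count in the calibration set
    min_class = int(min(np.sum(cal.labels == c) for c in class_order))
    folds = min(config.lssvm.cv_folds, min_class)
    params = LSSVMParams(
        gamma=config.lssvm.gamma,
        gamma_grid=np.logspace(0, 3, config.lssvm.gamma_grid_points),
        cv_folds=folds,
        seed=config.seed,
    )
    if config.lssvm.tune_gamma:
        params = tune(cal, params=params)
    model = lssvm_train_multiclass(cal, params=params, class_order=class_order)
    save("model.json", model.to_json)

    cv_accuracy = cross_validate(cal, params=params, folds=folds)
    predicted = model.predict(pred.reflectance)
    cm = confusion(pred.labels, predicted, class_order)
    save("confusion.csv", cm.to_csv)
    metrics = {
        "band_count": cal.n_bands,
        "n_calibration": cal.n_samples,
        "n_prediction": pred.n_samples,
        "gamma": params.gamma,
        "sigma2": model.sigma2,
        "cv_accuracy": cv_accuracy,
        "prediction_accuracy": overall_accuracy(cm),
        "misclassified": misclassified_count(cm),
    }
    save("metrics.json", lambda p: p.write_text(json.dumps(metrics, indent=2)))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "artifacts": artifacts,
        "metrics": metrics,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
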