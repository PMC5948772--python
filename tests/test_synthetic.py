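"""Synthetic scene generator: signature shape constraints, the forward-model
round trip, label balance and seed reproducibility."""

import numpy as np
import pytest

from roastspec import (
    SceneConfig,
    WavelengthGrid,
    calibrate_reflectance,
    extract_roi_spectra,
    generate_scene,
    generate_spectra_matrix,
    make_class_signatures,
)
from roastspec.synthetic import make_planted_benchmark, roi_pixels_per_sample


class TestClassSignatures:
    def test_rejects_single_class(self, default_grid):
        with pytest.raises(ValueError):
            make_class_signatures(default_grid, n_classes=1)

    def test_values_in_unit_interval(self, signatures7):
        for sig in signatures7:
            assert np.all(sig.values > 0) and np.all(sig.values < 1)

    def test_valley_near_1210_for_every_class(self, default_grid, signatures7):
        """Each class signature has a local minimum within 1190-1230 nm."""
        wl = default_grid.centers
        window = (wl >= 1190) & (wl <= 1230)
        for sig in signatures7:
            idx = np.flatnonzero(window)[np.argmin(sig.values[window])]
            # local minimum: strictly below both neighbors outside the argmin
            assert sig.values[idx] < sig.values[idx - 1]
            assert sig.values[idx] < sig.values[idx + 1]

    def test_valley_near_1450_for_every_class(self, default_grid, signatures7):
        wl = default_grid.centers
        window = (wl >= 1420) & (wl <= 1480)
        for sig in signatures7:
            inner_min = sig.values[window].min()
            assert inner_min < sig.values[default_grid.nearest_index(1550)]

    def test_max_separation_within_930_1350(self, default_grid, signatures7):
        """Brute-force scan: for any class pair the largest absolute
        difference falls in the 930-1350 nm region."""
        wl = default_grid.centers
        for i in range(7):
            for j in range(i + 1, 7):
                diff = np.abs(signatures7[i].values - signatures7[j].values)
                band = wl[int(np.argmax(diff))]
                assert 930 <= band <= 1350

    def test_1210_depth_monotone_with_roast_degree(self, signatures7):
        depths = [sig.feature_depths[1210.0] for sig in signatures7]
        assert np.all(np.diff(depths) > 0)

    def test_zero_feature_depth_collapses_to_baseline(self, default_grid):
        sigs = make_class_signatures(
            default_grid, n_classes=2, feature_depth_scale=0.0
        )
        np.testing.assert_allclose(sigs[0].values, sigs[0].baseline)
        np.testing.assert_allclose(sigs[0].values, sigs[1].values)


class TestGenerateScene:
    CFG = dict(n_classes=3, samples_per_class=2, beans_per_sample=4)

    def test_noiseless_roi_mean_equals_signature(self, default_grid):
        cfg = SceneConfig(**self.CFG, noise_sd_interior=0, noise_sd_edge=0, seed=5)
        sigs = make_class_signatures(default_grid, 3, seed=5)
        scene = generate_scene(cfg, sigs)
        cube = calibrate_reflectance(
            scene.raw_cube, scene.dark_frame, scene.white_frame, scene.grid
        )
        matrix = extract_roi_spectra(cube, scene.roi_masks, scene.labels)
        for row, label in zip(matrix.reflectance, matrix.labels):
            c = {"RD-U": 0, "RD-L": 1, "RD-ML": 2}[label]
            np.testing.assert_allclose(row, sigs[c].values, atol=1e-10)

    def test_roundtrip_matches_fast_path_noiseless(self, default_grid):
        cfg = SceneConfig(**self.CFG, noise_sd_interior=0, noise_sd_edge=0, seed=6)
        sigs = make_class_signatures(default_grid, 3, seed=6)
        scene = generate_scene(cfg, sigs)
        cube = calibrate_reflectance(
            scene.raw_cube, scene.dark_frame, scene.white_frame, scene.grid
        )
        via_scene = extract_roi_spectra(cube, scene.roi_masks, scene.labels)
        direct = generate_spectra_matrix(cfg, sigs)
        assert np.abs(via_scene.reflectance - direct.reflectance).max() < 1e-10

    def test_masks_disjoint_and_labels_balanced(self):
        cfg = SceneConfig(**self.CFG, seed=7)
        scene = generate_scene(cfg)
        total = np.zeros(scene.raw_cube.shape[:2], dtype=int)
        for mask in scene.roi_masks:
            total += mask
        assert total.max() == 1  # no overlaps
        _, counts = np.unique(scene.labels, return_counts=True)
        assert np.all(counts == cfg.samples_per_class)

    def test_rejects_too_small_image(self):
        cfg = SceneConfig(**self.CFG, image_height=5, image_width=5)
        with pytest.raises(ValueError, match="too small"):
            generate_scene(cfg)

    def test_dark_below_white_everywhere(self):
        scene = generate_scene(SceneConfig(**self.CFG, seed=8))
        assert np.all(scene.dark_frame < scene.white_frame)

    def test_roi_mean_noise_within_monte_carlo_bound(self, default_grid):
        """ROI-mean deviation stays below 3 * sd / sqrt(n_pixels) at >= 99%
        of bands, pooled over 20 seeds (Gaussian noise model check)."""
        sigs = make_class_signatures(default_grid, 2, seed=0)
        hits = total = 0
        for seed in range(20):
            cfg = SceneConfig(
                n_classes=2,
                samples_per_class=1,
                beans_per_sample=4,
                noise_sd_interior=0.01,
                noise_sd_edge=0.01,
                seed=seed,
            )
            scene = generate_scene(cfg, sigs)
            cube = calibrate_reflectance(
                scene.raw_cube, scene.dark_frame, scene.white_frame, scene.grid
            )
            matrix = extract_roi_spectra(cube, scene.roi_masks, scene.labels)
            bound = 3 * 0.01 / np.sqrt(roi_pixels_per_sample(cfg))
            for row, sig in zip(matrix.reflectance, sigs):
                hits += int(np.sum(np.abs(row - sig.values) < bound))
                total += row.size
        assert hits / total >= 0.99


class TestSpectraMatrixFastPath:
    def test_default_config_yields_525_by_256(self, signatures7):
        matrix = generate_spectra_matrix(SceneConfig(seed=1), signatures7)
        assert matrix.reflectance.shape == (525, 256)
        _, counts = np.unique(matrix.labels, return_counts=True)
        assert np.all(counts == 75)

    def test_single_sample_noiseless_rows_equal_signatures(self, signatures7):
        cfg = SceneConfig(
            samples_per_class=1, noise_sd_interior=0, noise_sd_edge=0
        )
        matrix = generate_spectra_matrix(cfg, signatures7)
        for row, sig in zip(matrix.reflectance, signatures7):
            np.testing.assert_allclose(row, sig.values)

    def test_same_seed_bit_identical(self, signatures7):
        cfg = SceneConfig(samples_per_class=3, seed=9)
        a = generate_spectra_matrix(cfg, signatures7)
        b = generate_spectra_matrix(cfg, signatures7)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.labels, b.labels)


class TestPlantedBenchmark:
    def test_shapes_and_planted_indices(self):
        matrix, planted = make_planted_benchmark(seed=1)
        assert matrix.reflectance.shape == (525, 100)
        assert list(planted) == [10, 30, 50, 70, 90]

    def test_planted_bands_correlate_with_roast_trend(self):
        from roastspec import response_vector
        from roastspec.spectra import ROAST_CLASSES

        matrix, planted = make_planted_benchmark(seed=2)
        cls = response_vector(matrix.labels, ROAST_CLASSES)
        X = matrix.reflectance - matrix.reflectance.mean(axis=0)
        u = (cls - cls.mean()) / cls.std()
        corr = (X.T @ u) / (np.linalg.norm(X, axis=0) * np.linalg.norm(u))
        noise = np.delete(np.abs(corr), planted)
        assert np.abs(corr[planted]).min() > 3 * noise.max()


def test_scene_config_validation():
    with pytest.raises(ValueError):
        SceneConfig(n_classes=1)
    with pytest.raises(ValueError):
        SceneConfig(noise_sd_interior=0.05, noise_sd_edge=0.01)


def test_grid_requires_strictly_increasing():
    with pytest.raises(ValueError):
        WavelengthGrid(np.array([900.0, 900.0, 1000.0]))
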