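"""Generate a small synthetic hyperspectral scene, calibrate it to relative
reflectance, and extract per-sample ROI mean spectra.

The scene holds 3 roast classes x 2 samples, each a dish of 4 elliptical
beans, imaged over 256 NIR bands (874-1734 nm) in digital numbers with
dark/white reference frames.  Calibration inverts the forward model, so the
extracted spectra match the class signatures up to noise.
"""

import numpy as np

from roastspec import (
    SceneConfig,
    calibrate_reflectance,
    extract_roi_spectra,
    generate_scene,
    make_class_signatures,
)

config = SceneConfig(
    n_classes=3, samples_per_class=2, beans_per_sample=4, seed=42
)
signatures = make_class_signatures(n_classes=3, seed=42)
scene = generate_scene(config, signatures)
print(f"raw cube: {scene.raw_cube.shape} (lines x pixels x bands)")

cube = calibrate_reflectance(
    scene.raw_cube, scene.dark_frame, scene.white_frame, scene.grid
)
matrix = extract_roi_spectra(cube, scene.roi_masks, scene.labels)
print(f"extracted spectra: {matrix.n_samples} samples x {matrix.n_bands} bands")

for row, label in zip(matrix.reflectance, matrix.labels):
    sig = signatures[{"RD-U": 0, "RD-L": 1, "RD-ML": 2}[label]]
    err = np.abs(row - sig.values).max()
    print(f"  {label}: max deviation from class signature = {err:.2e}")
# deviations are at the noise level (about 1e-3 after ROI averaging);
# rerun with noise_sd_interior=0 to see the exact round trip
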