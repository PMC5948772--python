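"""Partition the full synthetic study matrix with the Kennard-Stone
algorithm: 525 samples (7 roast degrees x 75), trimmed to the 930-1700 nm
working range, split 2:1 into calibration and prediction sets."""

from roastspec import (
    SceneConfig,
    generate_spectra_matrix,
    kennard_stone_split,
    trim_bands,
)

matrix = generate_spectra_matrix(SceneConfig(seed=0))
print(f"generated: {matrix.n_samples} samples x {matrix.n_bands} bands")

trimmed = trim_bands(matrix)  # closed interval [930, 1700] nm
print(f"after trimming: {trimmed.n_bands} bands")

split = kennard_stone_split(trimmed, cal_fraction=2 / 3)
print(
    f"Kennard-Stone 2:1 split -> {split.calibration_indices.size} calibration"
    f" / {split.prediction_indices.size} prediction samples"
)
# the split is deterministic: the two most distant spectra seed the
# calibration set, then the max-min-distance recursion fills it
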