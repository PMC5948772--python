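import numpy as np
import pytest

from roastspec import (
    SceneConfig,
    WavelengthGrid,
    generate_spectra_matrix,
    make_class_signatures,
    trim_bands,
)


@pytest.fixture(scope="session")
def default_grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def signatures7(default_grid):
    return make_class_signatures(default_grid, n_classes=7, seed=0)


@pytest.fixture(scope="session")
def small_matrix(signatures7):
    """Trimmed 7-class spectra with 10 samples per class, mild noise."""
    cfg = SceneConfig(samples_per_class=10, seed=3)
    return trim_bands(generate_spectra_matrix(cfg, signatures7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
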