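"""Reference fixtures: the published prediction-set confusion matrices of the
coffee roast-degree discrimination experiment (LS-SVM on wavelengths chosen
by X-loading, SPA and random frog; 175 prediction samples, 7 classes), and
the effective wavelengths each selector reported.

These are verbatim reference tables used as worked-example inputs — the raw
hyperspectral cubes behind them were never deposited.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix
from .spectra import ROAST_CLASSES

#: Effective wavelengths (nm) each selector reported, in importance /
#: selection order.
REFERENCE_WAVELENGTHS_NM = {
    "xloading": (948, 1116, 1217, 1247, 1328, 1442, 1663),
    "spa": (1666, 931, 1217, 1453, 1690),
    "rf": (931, 945, 1507, 1183, 1018, 1261, 1656, 1224),
}

_REFERENCE_COUNTS = {
    "xloading": [
        [5, 3, 0, 0, 0, 0, 0],
        [2, 15, 0, 0, 0, 0, 0],
        [0, 0, 20, 5, 0, 0, 0],
        [0, 0, 0, 28, 0, 0, 0],
        [0, 0, 0, 1, 24, 4, 0],
        [0, 0, 0, 0, 2, 32, 1],
        [0, 0, 0, 0, 0, 0, 33],
    ],
    "spa": [
        [7, 1, 0, 0, 0, 0, 0],
        [2, 15, 0, 0, 0, 0, 0],
        [0, 0, 16, 9, 0, 0, 0],
        [0, 1, 0, 27, 0, 0, 0],
        [0, 0, 0, 0, 24, 5, 0],
        [0, 0, 0, 1, 1, 33, 0],
        [0, 0, 0, 0, 0, 0, 33],
    ],
    "rf": [
        [8, 0, 0, 0, 0, 0, 0],
        [0, 17, 0, 0, 0, 0, 0],
        [0, 0, 17, 8, 0, 0, 0],
        [0, 0, 0, 28, 0, 0, 0],
        [0, 0, 0, 0, 22, 7, 0],
        [0, 0, 0, 1, 1, 33, 0],
        [0, 0, 0, 0, 0, 0, 33],
    ],
}


def reference_confusion(method: str) -> ConfusionMatrix:
    """Published 7x7 prediction-set confusion matrix for a selector
    ("xloading", "spa" or "rf")."""
    if method not in _REFERENCE_COUNTS:
        raise KeyError(f"unknown method {method!r}")
    return ConfusionMatrix(np.array(_REFERENCE_COUNTS[method]), ROAST_CLASSES)


def reference_confusions() -> dict[str, ConfusionMatrix]:
    return {m: reference_confusion(m) for m in _REFERENCE_COUNTS}
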