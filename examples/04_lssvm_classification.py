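"""Train a multiclass LS-SVM (RBF kernel, one-vs-one) on the calibration
rows, tune gamma by pointwise grid search, and evaluate on the prediction
set with a confusion matrix."""

from roastspec import (
    LSSVMParams,
    SceneConfig,
    confusion,
    cross_validate,
    generate_spectra_matrix,
    kennard_stone_split,
    lssvm_train_multiclass,
    misclassified_count,
    overall_accuracy,
    trim_bands,
    tune,
)
from roastspec.spectra import ROAST_CLASSES

import numpy as np

matrix = trim_bands(
    generate_spectra_matrix(SceneConfig(samples_per_class=15, seed=1))
)
split = kennard_stone_split(matrix, 2 / 3)
cal = matrix.take_rows(split.calibration_indices)
pred = matrix.take_rows(split.prediction_indices)

params = LSSVMParams(gamma_grid=np.logspace(0, 3, 20), cv_folds=5, seed=1)
params = tune(cal, params=params)
print(f"tuned gamma = {params.gamma:.2f}, sigma2 = {params.sigma2:.4f}")

cv_acc = cross_validate(cal, params=params, folds=5)
print(f"5-fold CV accuracy on calibration set: {100 * cv_acc:.2f}%")

model = lssvm_train_multiclass(cal, params=params, class_order=ROAST_CLASSES)
cm = confusion(pred.labels, model.predict(pred.reflectance), ROAST_CLASSES)
print("prediction-set confusion matrix (rows = true):")
print(cm.to_frame())
print(
    f"overall accuracy {100 * overall_accuracy(cm):.2f}% "
    f"({misclassified_count(cm)} of {cm.n_total} misclassified)"
)
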