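"""LS-SVM: kernel identities, the KKT linear system, one-vs-one multiclass
behavior, gamma grid search and stratified cross-validation."""

import numpy as np
import pytest

from roastspec import (
    LSSVMParams,
    SceneConfig,
    cross_validate,
    generate_spectra_matrix,
    lssvm_train_binary,
    lssvm_train_multiclass,
    median_heuristic_sigma2,
    rbf_kernel,
    trim_bands,
    tune,
)


class TestRBFKernel:
    def test_self_similarity_is_one(self, rng):
        X = rng.normal(size=(5, 3))
        K = rbf_kernel(X, X, sigma2=2.0)
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_large_sigma2_limit(self, rng):
        X = rng.normal(size=(4, 3))
        K = rbf_kernel(X, X, sigma2=1e12)
        np.testing.assert_allclose(K, 1.0, atol=1e-9)

    def test_hand_computed_3x3(self):
        A = np.array([[0.0], [1.0], [2.0]])
        K = rbf_kernel(A, A, sigma2=4.0)
        expected = np.exp(-np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]]) / 4.0)
        np.testing.assert_allclose(K, expected)

    def test_rejects_nonpositive_sigma2(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros((2, 2)), np.zeros((2, 2)), sigma2=0.0)


class TestBinary:
    def test_two_point_bisector(self):
        X = np.array([[0.0, 0.0], [2.0, 0.0]])
        y = np.array([1.0, -1.0])
        model = lssvm_train_binary(X, y, gamma=10.0, sigma2=1.0)
        assert model.predict(np.array([[0.1, 0.0]]))[0] == 1
        assert model.predict(np.array([[1.9, 0.0]]))[0] == -1
        # the midpoint decision value vanishes by symmetry
        assert abs(model.decision(np.array([[1.0, 0.0]]))[0]) < 1e-10

    def test_kkt_residual_small(self, rng):
        """The returned (b, alpha) satisfy the defining linear system."""
        for trial in range(3):
            X = rng.normal(size=(20, 4))
            y = np.where(rng.uniform(size=20) < 0.5, 1.0, -1.0)
            y[:2] = [1.0, -1.0]  # both classes present
            model = lssvm_train_binary(X, y, gamma=50.0, sigma2=2.0)
            K = rbf_kernel(X, X, 2.0)
            assert abs(np.sum(model.alpha)) < 1e-8
            resid = (K + np.eye(20) / 50.0) @ model.alpha + model.bias - y
            assert np.abs(resid).max() < 1e-8

    def test_agrees_with_generic_solver(self, rng):
        """Predictions match an independent dense solve of the same system
        on 5-point problems."""
        X = rng.normal(size=(5, 2))
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0])
        gamma, sigma2 = 7.0, 1.5
        model = lssvm_train_binary(X, y, gamma, sigma2)
        K = rbf_kernel(X, X, sigma2)
        A = np.block(
            [[np.zeros((1, 1)), np.ones((1, 5))],
             [np.ones((5, 1)), K + np.eye(5) / gamma]]
        )
        ref = np.linalg.lstsq(A, np.concatenate([[0.0], y]), rcond=None)[0]
        Xnew = rng.normal(size=(8, 2))
        ref_decision = rbf_kernel(Xnew, X, sigma2) @ ref[1:] + ref[0]
        np.testing.assert_allclose(model.decision(Xnew), ref_decision, atol=1e-8)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            lssvm_train_binary(np.zeros((3, 2)), np.ones(3), 1.0, 1.0)


class TestMulticlass:
    def test_two_classes_reduce_to_binary(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (10, 2)), rng.normal(3, 0.2, (10, 2))])
        labels = np.array(["RD-U"] * 10 + ["RD-D"] * 10)
        model = lssvm_train_multiclass(X, labels, LSSVMParams(gamma=10.0))
        assert len(model.models) == 1
        preds = model.predict(X)
        assert np.array_equal(preds, labels)

    def test_well_separated_seven_class_accuracy(self, signatures7):
        """>= 95% prediction accuracy on distinct roast signatures over
        20 seeds."""
        accs = []
        for seed in range(20):
            cfg = SceneConfig(samples_per_class=6, seed=seed)
            matrix = trim_bands(generate_spectra_matrix(cfg, signatures7))
            train = np.arange(matrix.n_samples) % 3 != 0
            model = lssvm_train_multiclass(
                matrix.take_rows(np.flatnonzero(train)),
                params=LSSVMParams(gamma=10.0),
            )
            preds = model.predict(matrix.reflectance[~train])
            accs.append(np.mean(preds == matrix.labels[~train]))
        assert np.mean(accs) >= 0.95

    def test_label_permutation_consistency(self, rng):
        X = np.vstack([rng.normal(i, 0.1, (6, 2)) for i in range(3)])
        labels = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        rename = {"a": "z", "b": "y", "c": "x"}
        model1 = lssvm_train_multiclass(X, labels, LSSVMParams(gamma=10.0))
        model2 = lssvm_train_multiclass(
            X, np.array([rename[l] for l in labels]), LSSVMParams(gamma=10.0)
        )
        p1 = model1.predict(X)
        p2 = model2.predict(X)
        assert np.array_equal(np.array([rename[l] for l in p1]), p2)

    def test_duplicating_training_samples_keeps_predictions(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (8, 2)), rng.normal(2, 0.3, (8, 2))])
        labels = np.array(["RD-U"] * 8 + ["RD-D"] * 8)
        params = LSSVMParams(gamma=5.0, sigma2=1.0)
        base = lssvm_train_multiclass(X, labels, params)
        doubled = lssvm_train_multiclass(
            np.vstack([X, X]), np.concatenate([labels, labels]), params
        )
        Xnew = rng.normal(1, 1, size=(20, 2))
        assert np.array_equal(base.predict(Xnew), doubled.predict(Xnew))

    def test_predictions_stay_in_codebook(self, rng):
        X = rng.normal(size=(12, 3))
        labels = np.array(["RD-U", "RD-L", "RD-M"] * 4)
        model = lssvm_train_multiclass(X, labels, LSSVMParams(gamma=2.0))
        preds = model.predict(rng.normal(size=(30, 3)) * 10)
        assert set(preds) <= {"RD-U", "RD-L", "RD-M"}

    def test_rejects_undersized_class(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            lssvm_train_multiclass(X, np.array(["a", "a", "b"]), LSSVMParams())

    def test_interpolation_limit_large_gamma(self, rng):
        """With gamma -> infinity LS-SVM interpolates distinct points."""
        X = rng.normal(size=(14, 3))
        labels = np.array(["RD-U", "RD-D"] * 7)
        model = lssvm_train_multiclass(X, labels, LSSVMParams(gamma=1e8, sigma2=1.0))
        assert np.array_equal(model.predict(X), labels)


class TestTuneAndCV:
    def _toy(self, rng, sep=4.0):
        X = np.vstack([rng.normal(0, 0.2, (12, 2)), rng.normal(sep, 0.2, (12, 2))])
        labels = np.array(["RD-U"] * 12 + ["RD-D"] * 12)
        return X, labels

    def test_single_point_grid_returned(self, rng):
        X, labels = self._toy(rng)
        params = LSSVMParams(gamma_grid=np.array([42.0]), cv_folds=3)
        tuned = tune(X, labels, params)
        assert tuned.gamma == 42.0

    def test_separable_data_tie_breaks_to_smallest_gamma(self, rng):
        X, labels = self._toy(rng)
        params = LSSVMParams(gamma_grid=np.array([1.0, 10.0, 100.0]), cv_folds=3)
        tuned = tune(X, labels, params)
        assert tuned.gamma == 1.0

    def test_grid_argmax_matches_reevaluation(self, rng):
        X, labels = self._toy(rng, sep=0.8)
        grid = np.array([1.0, 30.0, 1000.0])
        params = LSSVMParams(gamma_grid=grid, cv_folds=3, seed=1)
        tuned = tune(X, labels, params)
        # independent re-evaluation of every grid point
        from dataclasses import replace

        accs = {
            g: cross_validate(X, labels, replace(params, gamma=g), folds=3)
            for g in grid
        }
        best = max(accs.values())
        assert accs[tuned.gamma] == pytest.approx(best)

    def test_perfectly_separable_cv_is_100pct(self, rng):
        X, labels = self._toy(rng)
        acc = cross_validate(X, labels, LSSVMParams(gamma=10.0), folds=4)
        assert acc == 1.0

    def test_same_seed_same_folds(self, rng):
        X, labels = self._toy(rng, sep=0.5)
        params = LSSVMParams(gamma=5.0, seed=3)
        assert cross_validate(X, labels, params, folds=4) == cross_validate(
            X, labels, params, folds=4
        )

    def test_folds_exceeding_class_count_rejected(self, rng):
        X, labels = self._toy(rng)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, labels, LSSVMParams(), folds=13)

    def test_shuffled_labels_give_chance_accuracy(self, signatures7):
        """With labels independent of spectra, 7-class balanced CV accuracy
        sits near 1/7 (pooled over seeds)."""
        accs = []
        for seed in range(6):
            cfg = SceneConfig(samples_per_class=10, seed=seed)
            matrix = trim_bands(generate_spectra_matrix(cfg, signatures7))
            rng = np.random.default_rng(seed)
            shuffled = rng.permutation(matrix.labels)
            params = LSSVMParams(gamma=10.0, seed=seed)
            accs.append(cross_validate(matrix.reflectance, shuffled, params, folds=5))
        assert abs(np.mean(accs) - 1 / 7) < 0.06


def test_median_heuristic_positive(rng):
    X = rng.normal(size=(10, 4))
    assert median_heuristic_sigma2(X) > 0
    assert median_heuristic_sigma2(np.zeros((5, 3))) == 1.0
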