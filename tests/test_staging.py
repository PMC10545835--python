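import numpy as np
import pytest

from kiwitrts.staging import (
    assign_softening_classes,
    class_thresholds,
    fit_pca,
    pca_scores,
    select_components,
    train_classify_svm,
)

from _oracles import pca_loadings_bruteforce


class TestFitPca:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        base = rng.random(12)
        X = np.outer(rng.normal(size=9), base)
        model = fit_pca(X)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 5))
        model = fit_pca(X)
        scores = pca_scores(model, X)
        recon = scores @ model.loadings + model.mean_vector
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_match_covariance_eigenvectors(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 6))
        model = fit_pca(X, n_components=4)
        ref = pca_loadings_bruteforce(X, 4)
        for row, ref_row in zip(model.loadings, ref):
            dot = abs(np.dot(row, ref_row))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_and_centered(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 7))
        model = fit_pca(X)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        scores = pca_scores(model, X)
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 6))
        for row in fit_pca(X).loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.ones((1, 5)))
        with pytest.raises(ValueError):
            fit_pca(np.random.default_rng(0).normal(size=(4, 5)), n_components=6)


class TestSofteningClasses:
    def test_rank_order(self):
        np.testing.assert_array_equal(
            assign_softening_classes(np.array([30.0, 20.0, 10.0])), [1, 2, 3]
        )

    def test_equal_tertiles(self):
        labels = assign_softening_classes(np.arange(9.0, 0.0, -1.0))
        np.testing.assert_array_equal(labels, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_all_equal_warns_but_deterministic(self):
        with pytest.warns(UserWarning, match="equal"):
            labels = assign_softening_classes(np.full(6, 5.0))
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 3, 3])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            assign_softening_classes(np.array([1.0, 2.0]), n_classes=3)

    def test_thresholds_are_class_minima(self):
        f = np.array([30.0, 25.0, 20.0, 15.0, 10.0, 5.0])
        labels = assign_softening_classes(f)
        assert class_thresholds(f, labels) == [25.0, 15.0]


class TestSelectComponents:
    def test_separating_component_found(self):
        rng = np.random.default_rng(0)
        n = 30
        scores = rng.normal(scale=0.1, size=(n, 10))
        labels = np.repeat([1, 2, 3], n // 3)
        scores[:, 7] = labels * 5.0 + rng.normal(scale=0.1, size=n)
        pca = fit_pca(rng.normal(size=(n, 12)))  # only evr used in fallback
        sel = select_components(pca, scores, labels, k=3)
        assert sel[0] == 7

    def test_explicit_override_honored(self):
        rng = np.random.default_rng(1)
        pca = fit_pca(rng.normal(size=(10, 12)))
        scores = rng.normal(size=(10, 10))
        labels = np.repeat([1, 2], 5)
        assert select_components(pca, scores, labels, explicit=[1, 2, 7]) == [1, 2, 7]

    def test_degenerate_within_class_falls_back(self):
        rng = np.random.default_rng(2)
        pca = fit_pca(rng.normal(size=(10, 10)))
        scores = np.zeros((6, 10))
        labels = np.repeat([1, 2, 3], 2)
        with pytest.warns(UserWarning, match="degenerate"):
            sel = select_components(pca, scores, labels, k=3)
        assert len(sel) == 3


class TestTrainClassifySvm:
    @staticmethod
    def blobs(sep, n=60, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.repeat([1, 2, 3], n // 3)
        centers = np.array([[0, 0], [sep, 0], [0, sep]], dtype=float)
        X = centers[labels - 1] + rng.normal(size=(n, 2))
        return X, labels

    def test_separable_blobs_perfect(self):
        X, y = self.blobs(sep=10.0)
        report = train_classify_svm(X, y, seed=0)
        assert report.overall_accuracy == 1.0
        assert np.trace(report.confusion_matrix) == 60

    def test_shuffled_labels_at_chance(self):
        X, y = self.blobs(sep=10.0)
        rng = np.random.default_rng(99)
        y_shuffled = rng.permutation(y)
        report = train_classify_svm(X, y_shuffled, seed=0)
        # binomial 99% band around 1/3 with n=60
        assert 0.333 - 2.58 * np.sqrt(0.333 * 0.667 / 60) <= report.overall_accuracy
        assert report.overall_accuracy <= 0.333 + 2.58 * np.sqrt(0.333 * 0.667 / 60)

    def test_deterministic_given_seed(self):
        X, y = self.blobs(sep=2.0, seed=3)
        a = train_classify_svm(X, y, seed=11)
        b = train_classify_svm(X, y, seed=11)
        np.testing.assert_array_equal(a.confusion_matrix, b.confusion_matrix)
        assert a.fold_accuracies == b.fold_accuracies

    def test_confusion_margins_conserve_counts(self):
        X, y = self.blobs(sep=1.0, seed=5)
        report = train_classify_svm(X, y, seed=0)
        # columns are actual classes
        np.testing.assert_array_equal(report.confusion_matrix.sum(axis=0), [20, 20, 20])
        assert report.confusion_matrix.sum() == 60
        assert report.overall_accuracy == pytest.approx(
            np.trace(report.confusion_matrix) / 60
        )

    def test_starved_class_named_in_error(self):
        X = np.random.default_rng(0).normal(size=(13, 2))
        y = np.array([1] * 6 + [2] * 5 + [3] * 2)
        with pytest.raises(ValueError, match="class 3"):
            train_classify_svm(X, y, folds=5)
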