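import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from serds import classify, core, pipeline, synthetic
from serds.classify import (LabelledDataset, UndefinedMetricError,
                            binary_metrics, cross_validate, fit_fold,
                            predict_fold, restrict_range, roc_auc)


def _spectrum(axis, values, label="fat", locus="l1"):
    return core.PurifiedSpectrum(axis, values, locus_id=locus, label=label)


class TestRestrictRange:
    def test_fingerprint_window_inclusive(self):
        axis = np.arange(200.0, 2001.0, 1.0)
        out = restrict_range(_spectrum(axis, np.ones_like(axis)), 550, 1800)
        assert out.shift_cm1[0] == 550.0
        assert out.shift_cm1[-1] == 1800.0

    def test_single_bin_survives(self):
        axis = np.array([500.0, 1000.0, 1500.0])
        out = restrict_range(_spectrum(axis, axis * 0 + 1), 999.0, 1001.0)
        assert out.shift_cm1.tolist() == [1000.0]

    def test_disjoint_range_errors(self):
        axis = np.arange(200.0, 2001.0, 1.0)
        with pytest.raises(ValueError, match="no bins"):
            restrict_range(_spectrum(axis, np.ones_like(axis)), 2100, 2200)


def _gaussian_blobs(n_per_class=20, dim=10, separation=50.0, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(size=(n_per_class, dim))
    x1 = rng.normal(size=(n_per_class, dim)) + separation / np.sqrt(dim)
    X = np.vstack([x0, x1])
    y = np.array(["neurofibroma"] * n_per_class + ["skin"] * n_per_class)
    return X, y


class TestFoldModel:
    def test_separable_classes_classified_perfectly(self):
        X, y = _gaussian_blobs()
        model = fit_fold(X, y)
        pred, _ = predict_fold(model, X)
        assert np.all(pred == y)

    def test_duplicating_training_rows_changes_nothing(self):
        X, y = _gaussian_blobs(n_per_class=10)
        a = fit_fold(X, y)
        b = fit_fold(np.vstack([X, X]), np.concatenate([y, y]))
        test = np.random.default_rng(1).normal(size=(5, X.shape[1]))
        pa, sa = predict_fold(a, test)
        pb, sb = predict_fold(b, test)
        assert np.all(pa == pb)
        assert np.allclose(a.mean, b.mean)

    def test_basis_orthonormal_and_variance_fractions_valid(self):
        X, y = _gaussian_blobs()
        model = fit_fold(X, y)
        gram = model.components @ model.components.T
        assert np.max(np.abs(gram - np.eye(model.n_components))) < 1e-8
        assert np.all(model.explained_variance_ratio >= 0)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-8

    def test_component_cap(self):
        X, y = _gaussian_blobs(n_per_class=5)
        model = fit_fold(X, y, variance_target=1.0)
        assert model.n_components <= X.shape[0] - 2

    def test_test_rows_centred_with_training_mean(self):
        # shifted test distribution: projection must use the training mean
        X, y = _gaussian_blobs()
        model = fit_fold(X, y)
        X_test = np.random.default_rng(2).normal(size=(8, X.shape[1])) + 100.0
        assert not np.allclose(model.mean, X_test.mean(axis=0), atol=1.0)
        _, scores = predict_fold(model, X_test)
        expected = (X_test - model.mean) @ model.components.T
        direct = model.lda.predict_proba(expected)
        col = int(np.where(model.classes == "neurofibroma")[0][0])
        assert np.allclose(scores, direct[:, col])

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="two classes"):
            fit_fold(X, np.array(["fat"] * 10))

    def test_tiny_class_signals_stratification_failure(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        y = np.array(["fat"] * 9 + ["bone"])
        with pytest.raises(ValueError, match="stratification"):
            fit_fold(X, y)

    def test_no_leakage_from_test_rows(self):
        # the fold model is a pure function of its training rows
        X, y = _gaussian_blobs()
        a = fit_fold(X, y)
        b = fit_fold(X.copy(), y.copy())
        assert np.array_equal(a.components, b.components)
        assert np.array_equal(a.mean, b.mean)

    def test_permuting_test_rows_permutes_predictions(self):
        X, y = _gaussian_blobs()
        model = fit_fold(X, y)
        test = np.random.default_rng(3).normal(size=(6, X.shape[1]))
        perm = np.random.default_rng(4).permutation(6)
        pred, score = predict_fold(model, test)
        pred_p, score_p = predict_fold(model, test[perm])
        assert np.all(pred[perm] == pred_p)
        assert np.allclose(score[perm], score_p)


class TestBinaryMetrics:
    @pytest.mark.parametrize("counts, expected", [
        # neurofibroma vs pooled physiological tissue: 9/9 and 71/73 correct
        ((9, 2, 0, 71), (100.0, 97.3, 97.6, 2.4)),
        # vs mucosa: 9/9 and 25/27 correct
        ((9, 2, 0, 25), (100.0, 92.6, 94.4, 5.6)),
        # vs skin: 8/9 and 12/12 correct
        ((8, 0, 1, 12), (88.9, 100.0, 95.2, 4.8)),
    ])
    def test_reference_panels(self, counts, expected):
        m = binary_metrics(*counts)
        got = (round(m["sensitivity"], 1), round(m["specificity"], 1),
               round(m["accuracy"], 1), round(m["error"], 1))
        assert got == expected

    def test_error_is_complement_of_accuracy(self):
        m = binary_metrics(5, 3, 2, 10)
        assert m["error"] == pytest.approx(100.0 - m["accuracy"])

    def test_empty_positive_class_is_an_error_not_zero(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            binary_metrics(0, 0, 0, 10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics(-1, 0, 0, 10)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array(["neurofibroma", "neurofibroma", "skin", "skin"])
        assert roc_auc(scores, labels) == 100.0

    def test_negation_complements(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = np.where(rng.random(50) < 0.4, "neurofibroma", "skin")
        assert roc_auc(-scores, labels) == pytest.approx(
            100.0 - roc_auc(scores, labels))

    def test_null_scores_near_chance(self):
        # AUC lies in [45, 55] for at least 95% of independent-label draws
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=1000)
            labels = np.where(rng.random(1000) < 0.5, "neurofibroma", "skin")
            if 45.0 <= roc_auc(scores, labels) <= 55.0:
                inside += 1
        assert inside >= 95

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(7)
        scores = rng.integers(0, 5, size=200).astype(float)  # heavy ties
        labels = np.where(rng.random(200) < 0.3, "neurofibroma", "skin")
        expected = 100.0 * roc_auc_score(labels == "neurofibroma", scores)
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.array([1.0, 2.0]), np.array(["skin", "skin"]))


def _toy_dataset(n_per_class=10, seed=0):
    rng = np.random.default_rng(seed)
    axis = np.linspace(550, 1800, 32)
    rows, labels = [], []
    for i, name in enumerate(synthetic.CLASS_NAMES):
        center = 600 + 180 * i
        base = np.exp(-0.5 * ((axis - center) / 40) ** 2)
        for _ in range(n_per_class):
            rows.append(base + 0.05 * rng.normal(size=axis.size))
            labels.append(name)
    return LabelledDataset(np.vstack(rows), axis, np.array(labels),
                           np.array([f"l{i}" for i in range(len(labels))]),
                           np.array([""] * len(labels)))


class TestCrossValidation:
    def test_every_row_tested_once_fold_sizes_valid(self, purified_default_dataset):
        data = purified_default_dataset
        multiclass, reports = cross_validate(data, k=5, seed=0)
        folds = multiclass.assignments["fold"].to_numpy()
        assert len(folds) == 82
        sizes = sorted(np.bincount(folds).tolist())
        assert set(sizes) <= {16, 17} and sum(sizes) == 82
        # confusion conservation: counts sum to dataset size per comparison
        assert int(multiclass.confusion.to_numpy().sum()) == 82
        assert reports["all"].n_test == 82
        assert reports["skin"].n_test == 9 + 12
        assert reports["mucosa"].n_test == 9 + 27

    def test_same_seed_reproduces_reports(self):
        data = _toy_dataset()
        m1, r1 = cross_validate(data, k=5, seed=3)
        m2, r2 = cross_validate(data, k=5, seed=3)
        assert m1.accuracy == m2.accuracy
        for name in r1:
            assert (r1[name].tp, r1[name].fp, r1[name].fn, r1[name].tn) == \
                   (r2[name].tp, r2[name].fp, r2[name].fn, r2[name].tn)
            assert r1[name].auc == r2[name].auc

    def test_partitions_disjoint_and_exhaustive_across_seeds(self):
        data = _toy_dataset()
        for seed in range(3):
            multiclass, _ = cross_validate(data, k=5, seed=seed)
            assert sorted(multiclass.assignments["locus"]) == \
                sorted(data.locus_ids)

    def test_separable_toy_cohort_is_perfect(self):
        multiclass, reports = cross_validate(_toy_dataset(), k=5, seed=0)
        assert multiclass.accuracy == 100.0
        assert reports["all"].sensitivity == 100.0

    def test_validation_errors(self):
        data = _toy_dataset(n_per_class=4)
        with pytest.raises(ValueError, match="k"):
            cross_validate(_toy_dataset(), k=1)
        with pytest.raises(ValueError, match="at least k"):
            cross_validate(data, k=5)

    def test_contrast_ladder_accuracy_monotone(self, library):
        # more between-class contrast never hurts median CV accuracy
        counts = tuple((n, 6) for n in synthetic.CLASS_NAMES)
        medians = []
        for contrast in (0.25, 0.6, 1.0):
            blended = synthetic.blend_library(library, contrast)
            accs = []
            for seed in range(10):
                cohort = synthetic.generate_cohort(
                    synthetic.CohortConfig(seed=seed, locus_counts=counts),
                    blended)
                spectra = [core.classic_reconstruct(
                    pipeline.difference_for_pair(p)) for p in cohort]
                data = classify.assemble_dataset(spectra)
                pred, _, _ = classify._stratified_out_of_fold(
                    data.X, data.labels, 5, seed, 0.95)
                accs.append(float(np.mean(pred == data.labels)))
            medians.append(float(np.median(accs)))
        assert medians[0] <= medians[1] + 1e-9
        assert medians[1] <= medians[2] + 1e-9
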