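"""1-NN prediction, pooled-confusion metrics, CV protocol, benchmark."""

import numpy as np
import pytest

from pdfe import (
    CLASSIFIER_NAMES,
    ConfusionMatrix,
    ValidationError,
    benchmark_classifiers,
    compute_metrics,
    cross_validate,
    knn_predict,
)


class TestKnnPredict:
    def test_coincident_point_takes_its_label(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        y = np.array([1, 0])
        assert knn_predict(X, y, np.array([[5.0, 5.0]]), k=1)[0] == 0

    def test_nearest_by_absolute_distance_1d(self):
        X = np.array([[0.0], [10.0]])
        y = np.array([0, 1])
        preds = knn_predict(X, y, np.array([[4.0], [6.0]]), k=1)
        assert list(preds) == [0, 1]

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(0)
        Xtr = rng.standard_normal((30, 6))
        ytr = rng.integers(0, 2, 30)
        Xte = rng.standard_normal((12, 6))
        preds = knn_predict(Xtr, ytr, Xte, k=1)
        for i, x in enumerate(Xte):
            d = np.array([np.sqrt(((x - t) ** 2).sum()) for t in Xtr])
            assert preds[i] == ytr[int(np.argmin(d))]

    def test_distance_tie_goes_to_lower_training_index(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1, 0])
        assert knn_predict(X, y, np.array([[0.0]]), k=1)[0] == 1

    def test_even_vote_tie_goes_to_nearest_neighbor(self):
        X = np.array([[0.0], [3.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        # k=4: votes 2-2, nearest neighbor of 4.0 is x=3.0 with label 0
        assert knn_predict(X, y, np.array([[4.0]]), k=4)[0] == 0

    def test_majority_vote_k3(self):
        X = np.array([[0.0], [1.0], [2.0], [50.0]])
        y = np.array([1, 1, 0, 0])
        assert knn_predict(X, y, np.array([[0.5]]), k=3)[0] == 1

    def test_empty_or_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            knn_predict(np.empty((0, 2)), np.empty(0), np.zeros((1, 2)))
        with pytest.raises(ValidationError):
            knn_predict(np.zeros((3, 2)), np.zeros(3), np.zeros((1, 2)), k=4)

    def test_resubstitution_is_perfect_without_duplicate_conflicts(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((25, 4))
        y = rng.integers(0, 2, 25)
        assert np.array_equal(knn_predict(X, y, X, k=1), y)


class TestComputeMetrics:
    def test_all_correct_balanced_dataset_gives_100(self):
        """Pooled confusion of a perfect run on 159 + 165 samples."""
        m = compute_metrics(ConfusionMatrix(tp=159, tn=165, fp=0, fn=0))
        assert m == {
            "accuracy": 100.0,
            "recall": 100.0,
            "precision": 100.0,
            "f1": 100.0,
        }

    def test_hand_computed_case(self):
        m = compute_metrics(ConfusionMatrix(tp=1, tn=0, fp=0, fn=1))
        assert m["recall"] == pytest.approx(50.0)
        assert m["precision"] == pytest.approx(100.0)
        assert m["f1"] == pytest.approx(100 * 2 / 3)
        assert m["accuracy"] == pytest.approx(50.0)

    def test_undefined_precision_warns_and_returns_nan(self):
        with pytest.warns(RuntimeWarning, match="precision"):
            m = compute_metrics(ConfusionMatrix(tp=0, tn=3, fp=0, fn=2))
        assert np.isnan(m["precision"])
        assert m["accuracy"] == pytest.approx(60.0)

    def test_all_zero_confusion_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionMatrix())

    @pytest.mark.parametrize("tp,tn,fp,fn", [(5, 3, 2, 1), (10, 0, 4, 6), (7, 7, 7, 7)])
    def test_f1_is_harmonic_mean_of_precision_recall(self, tp, tn, fp, fn):
        m = compute_metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        harmonic = 2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        assert m["f1"] == pytest.approx(harmonic, abs=1e-9)


class _Always0:
    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.zeros(len(X), dtype=int)


class TestCrossValidate:
    def test_constant_classifier_on_balanced_labels(self):
        """Always predicting the positive class (large, label 0) forces
        accuracy 50%, recall 100%, precision 50% in the pooled confusion."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        rep = cross_validate(_Always0(), X, y, folds=10, seed=0)
        assert rep.accuracy == pytest.approx(50.0)
        assert rep.recall == pytest.approx(100.0)
        assert rep.precision == pytest.approx(50.0)

    def test_leaked_label_feature_is_perfect(self):
        y = np.repeat([0, 1], 20)
        X = y[:, None].astype(float)
        rep = cross_validate("kNN", X, y, folds=10, seed=1)
        assert (rep.confusion.tp, rep.confusion.tn) == (20, 20)
        assert (rep.confusion.fp, rep.confusion.fn) == (0, 0)
        assert rep.accuracy == rep.recall == rep.precision == rep.f1 == 100.0

    def test_same_seed_reproduces_report(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 4))
        y = np.repeat([0, 1], 20)
        a = cross_validate("kNN", X, y, folds=10, seed=7)
        b = cross_validate("kNN", X, y, folds=10, seed=7)
        assert a.as_dict() == b.as_dict()

    def test_per_fold_confusions_sum_to_pooled(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 4))
        y = np.repeat([0, 1], 20)
        rep = cross_validate("kNN", X, y, folds=10, seed=2)
        total = ConfusionMatrix()
        for cm in rep.per_fold_confusions:
            total.add(cm)
        assert total.as_dict() == rep.confusion.as_dict()
        assert rep.confusion.total == 40

    def test_class_smaller_than_folds_rejected(self):
        X = np.zeros((12, 2))
        y = np.array([0] * 3 + [1] * 9)
        with pytest.raises(ValidationError, match="folds"):
            cross_validate("kNN", X, y, folds=10, seed=0)


class TestBenchmark:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 25)
        X = rng.standard_normal((50, 4))
        X[:, 0] += np.where(y == 0, -4.0, 4.0)
        return X, y

    def test_nine_reports_with_expected_names(self, separable):
        X, y = separable
        reports = benchmark_classifiers(X, y, folds=10, seed=0)
        assert [r.classifier_name for r in reports] == list(CLASSIFIER_NAMES)
        assert len(reports) == 9

    def test_identical_fold_assignments_across_classifiers(self, separable):
        X, y = separable
        reports = benchmark_classifiers(X, y, folds=10, seed=4)
        sizes = [
            [cm.total for cm in r.per_fold_confusions] for r in reports
        ]
        assert all(s == sizes[0] for s in sizes)
        assert all(r.seed == 4 and r.folds == 10 for r in reports)

    def test_all_classifiers_beat_chance_on_separable_data(self, separable):
        X, y = separable
        for rep in benchmark_classifiers(X, y, folds=10, seed=0):
            assert rep.accuracy >= 50.0, rep.classifier_name
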