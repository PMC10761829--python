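"""Confusion-matrix metrics and the classifier evaluation harness."""

import numpy as np
import pytest
import sklearn.metrics as skm

from adstage import compute_metrics, make_classifier, split_and_evaluate
from adstage.evaluation import METRIC_NAMES


def expand_cm(cm):
    """Confusion matrix -> (y_true, y_pred) label arrays."""
    yt, yp = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            yt += [i] * int(cm[i, j])
            yp += [j] * int(cm[i, j])
    return np.array(yt), np.array(yp)


def sklearn_oracle(cm):
    """Independent metric computation through scikit-learn on expanded labels."""
    yt, yp = expand_cm(cm)
    labels = list(range(cm.shape[0]))
    recalls, specs = [], []
    for k in labels:
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = cm.sum() - tp - fn - fp
        recalls.append(tp / (tp + fn) if tp + fn else 0.0)
        specs.append(tn / (tn + fp) if tn + fp else 0.0)
    return dict(
        accuracy=skm.accuracy_score(yt, yp),
        recall=skm.recall_score(yt, yp, labels=labels, average="macro",
                                zero_division=0),
        specificity=float(np.mean(specs)),
        precision=skm.precision_score(yt, yp, labels=labels, average="macro",
                                      zero_division=0),
        f1=skm.f1_score(yt, yp, labels=labels, average="macro", zero_division=0),
        mcc=skm.matthews_corrcoef(yt, yp),
        kappa=skm.cohen_kappa_score(yt, yp, labels=labels),
    )


class TestComputeMetrics:
    def test_diagonal_matrix_all_ones(self):
        report = compute_metrics(np.diag([10, 10, 10, 10]))
        for name in METRIC_NAMES:
            assert getattr(report, name) == pytest.approx(1.0)

    def test_hand_checked_binary_matrix(self):
        report = compute_metrics(np.array([[40, 10], [20, 30]]))
        assert report.accuracy == pytest.approx(0.70)
        assert report.kappa == pytest.approx(0.40)
        assert report.recall == pytest.approx((0.8 + 0.6) / 2)
        assert report.specificity == pytest.approx((0.6 + 0.8) / 2)
        assert report.precision == pytest.approx((40 / 60 + 30 / 40) / 2)
        f1_0 = 2 * (40 / 60) * 0.8 / (40 / 60 + 0.8)
        f1_1 = 2 * 0.75 * 0.6 / (0.75 + 0.6)
        assert report.f1 == pytest.approx((f1_0 + f1_1) / 2)
        assert report.mcc == pytest.approx(1000 / np.sqrt(60 * 40 * 50 * 50))

    def test_uniform_matrix_zero_agreement(self):
        report = compute_metrics(np.full((4, 4), 7))
        assert report.kappa == pytest.approx(0.0)
        assert report.mcc == pytest.approx(0.0)

    def test_agrees_with_sklearn_on_random_matrices(self, rng):
        for _ in range(300):
            c = int(rng.integers(2, 6))
            cm = rng.integers(0, 25, (c, c))
            cm[np.arange(c), np.arange(c)] += 1  # every class present
            ours = compute_metrics(cm).as_dict()
            oracle = sklearn_oracle(cm)
            for name in METRIC_NAMES:
                assert ours[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_absent_class_excluded_with_warning(self):
        cm = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="absent"):
            report = compute_metrics(cm)
        assert report.recall == pytest.approx(1.0)

    def test_class_permutation_invariance(self, rng):
        cm = rng.integers(1, 20, (4, 4))
        perm = rng.permutation(4)
        permuted = cm[np.ix_(perm, perm)]
        a, b = compute_metrics(cm), compute_metrics(permuted)
        for name in ("accuracy", "kappa", "mcc"):
            assert getattr(a, name) == pytest.approx(getattr(b, name))

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((3, 3)))


@pytest.mark.filterwarnings("ignore::sklearn.exceptions.ConvergenceWarning")
class TestSplitAndEvaluate:
    def _blobs(self, rng, n=100, sep=10.0):
        X = np.vstack([rng.normal(sep * k, 1.0, size=(n, 3)) for k in range(4)])
        y = np.repeat(np.arange(4), n)
        return X, y

    def test_separable_blobs_near_perfect(self, rng):
        X, y = self._blobs(rng)
        result = split_and_evaluate(X, y, classifier="svm", seed=0)
        assert result.mean.accuracy >= 0.99

    def test_shuffled_labels_chance_level(self, rng):
        X, y = self._blobs(rng)
        y = rng.permutation(y)
        result = split_and_evaluate(X, y, classifier="knn", seed=0)
        assert abs(result.mean.accuracy - 0.25) < 0.12

    def test_same_seed_identical_reports(self, rng):
        X, y = self._blobs(rng, n=30)
        a = split_and_evaluate(X, y, classifier="tree", seed=7)
        b = split_and_evaluate(X, y, classifier="tree", seed=7)
        assert a.mean == b.mean and np.array_equal(a.confusion, b.confusion)

    def test_confusion_total_matches_test_fraction(self, rng):
        X, y = self._blobs(rng, n=50)
        result = split_and_evaluate(X, y, classifier="knn", seed=1)
        assert result.confusion.sum() == 10 * 40  # 10 reps x 20% of 200

    def test_kfold_mode(self, rng):
        X, y = self._blobs(rng, n=30)
        result = split_and_evaluate(X, y, classifier="lda", seed=0, mode="kfold")
        assert result.confusion.sum() == 120  # each sample tested once
        assert result.mean.accuracy >= 0.99

    def test_tiny_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0] * 8 + [1] * 2)
        with pytest.raises(ValueError):
            split_and_evaluate(X, y)

    @pytest.mark.parametrize("name", ["tree", "lda", "nb", "svm", "knn",
                                      "ensemble", "nn"])
    def test_all_classifier_families_instantiate(self, name, rng):
        model = make_classifier(name, seed=0)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(5, 1, (10, 2))])
        y = np.repeat([0, 1], 10)
        model.fit(X, y)
        assert model.predict(X).shape == (20,)

    def test_unknown_classifier(self):
        with pytest.raises(ValueError):
            make_classifier("cnn")
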