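"""Classifier evaluation with seven confusion-matrix metrics.

The protocol is ten repetitions of a stratified 60/20/20
train/validation/test split (the repetition count of ten-fold CV with
the stated partition fractions); metrics are computed on each held-out
test partition and summarised as mean and standard deviation.  A pure
stratified 10-fold CV mode is available as an alternative.

Metrics: accuracy, recall, specificity, precision, F1 (each per class
one-vs-rest, macro-averaged), the multiclass Matthews correlation
coefficient (R_K), and Cohen's kappa — all computed directly from the
C-by-C confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis)
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

METRIC_NAMES = ("accuracy", "recall", "specificity", "precision",
                "f1", "mcc", "kappa")


@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    kappa: float
    averaging: str = "macro"

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class EvaluationResult:
    """Aggregate over repetitions: per-metric mean/std and the pooled CM."""

    mean: MetricsReport
    std: dict[str, float]
    confusion: np.ndarray
    classes: np.ndarray
    per_repetition: list[MetricsReport] = field(repr=False, default_factory=list)


def compute_metrics(cm: np.ndarray) -> MetricsReport:
    """The seven metrics from a confusion matrix (rows true, cols predicted).

    Recall, specificity, precision and F1 are per-class one-vs-rest and
    macro-averaged; a class with no true and no predicted samples is
    excluded from the macro average (with a warning).  Zero-denominator
    per-class values count as 0.  MCC is the multiclass R_K statistic,
    kappa is Cohen's kappa; both fall back to 0 when their denominator
    vanishes (a single-class matrix carries no agreement information).
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm)
    row = cm.sum(axis=1)  # true counts
    col = cm.sum(axis=0)  # predicted counts
    present = (row > 0) | (col > 0)
    if not present.all():
        warnings.warn("classes absent from both rows and columns are "
                      "excluded from macro averages", stacklevel=2)
    fp = col - tp
    fn = row - tp
    tn = total - row - col + tp
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    precision = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc_den = np.sqrt(float(total**2 - (col @ col))) * \
        np.sqrt(float(total**2 - (row @ row)))
    mcc = ((total * tp.sum() - col @ row) / mcc_den) if mcc_den > 0 else 0.0
    pe = float(col @ row) / total**2
    po = tp.sum() / total
    kappa = (po - pe) / (1 - pe) if pe < 1 else 0.0
    return MetricsReport(
        accuracy=float(po),
        recall=float(recall[present].mean()),
        specificity=float(specificity[present].mean()),
        precision=float(precision[present].mean()),
        f1=float(f1[present].mean()),
        mcc=float(mcc),
        kappa=float(kappa),
    )


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(den)
    np.divide(num, den, out=out, where=den > 0)
    return out


#: classifier families from the comparison protocol; names follow the
#: kernel labels used there ("fine" KNN = 1-NN, "narrow" NN = 10 hidden
#: units, "quadratic" SVM = degree-2 polynomial kernel, ...)
def make_classifier(name: str, seed: int | None = None):
    name = name.lower()
    if name in ("tree", "decision_tree"):
        model = DecisionTreeClassifier(random_state=seed)
    elif name in ("lda", "discriminant"):
        model = QuadraticDiscriminantAnalysis(reg_param=1e-6)
    elif name in ("nb", "naive_bayes"):
        model = GaussianNB()
    elif name == "svm":
        model = SVC(kernel="poly", degree=2, coef0=1.0, C=1.0, random_state=seed)
    elif name == "knn":
        model = KNeighborsClassifier(n_neighbors=1)
    elif name == "ensemble":  # subspace discriminant
        model = BaggingClassifier(
            LinearDiscriminantAnalysis(), n_estimators=30,
            max_features=0.5, bootstrap=False, random_state=seed)
    elif name in ("nn", "mlp"):
        model = MLPClassifier(hidden_layer_sizes=(10,), max_iter=1000,
                              random_state=seed)
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return make_pipeline(StandardScaler(), model)


def split_and_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "svm",
    seed: int = 0,
    n_repeats: int = 10,
    mode: str = "repeated_split",
) -> EvaluationResult:
    """Train/evaluate a classifier under the repeated 60/20/20 protocol.

    ``mode="repeated_split"`` runs ``n_repeats`` stratified 60/20/20
    splits with seeds derived from ``seed`` (the validation fifth is
    held out of training and available for model selection; the fixed
    hyperparameters here need none, so metrics come from the untouched
    test fifth).  ``mode="kfold"`` runs a stratified 10-fold CV instead.
    The pooled confusion matrix sums the per-repetition test matrices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 3:
        raise ValueError("every class needs >= 3 samples for stratification")
    reports: list[MetricsReport] = []
    pooled = np.zeros((len(classes), len(classes)))
    if mode == "repeated_split":
        iterator = range(n_repeats)
    elif mode == "kfold":
        skf = StratifiedKFold(n_splits=n_repeats, shuffle=True, random_state=seed)
        iterator = skf.split(X, y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for i, item in enumerate(iterator):
        rep_seed = (seed + 1009 * i) % (2**31)
        if mode == "repeated_split":
            X_tr, X_rest, y_tr, y_rest = train_test_split(
                X, y, train_size=0.6, stratify=y, random_state=rep_seed)
            _, X_te, _, y_te = train_test_split(
                X_rest, y_rest, test_size=0.5, stratify=y_rest,
                random_state=rep_seed)
        else:
            tr_idx, te_idx = item
            X_tr, y_tr = X[tr_idx], y[tr_idx]
            X_te, y_te = X[te_idx], y[te_idx]
        model = clone(make_classifier(classifier, seed=rep_seed))
        model.fit(X_tr, y_tr)
        cm = confusion_matrix(y_te, model.predict(X_te), labels=classes)
        pooled += cm
        reports.append(compute_metrics(cm))
    mean = MetricsReport(**{m: float(np.mean([getattr(r, m) for r in reports]))
                            for m in METRIC_NAMES})
    std = {m: float(np.std([getattr(r, m) for r in reports]))
           for m in METRIC_NAMES}
    return EvaluationResult(mean=mean, std=std, confusion=pooled,
                            classes=classes, per_repetition=reports)
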