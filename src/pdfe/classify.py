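"""Final classification and evaluation: 1-NN under stratified tenfold CV,
confusion-matrix metrics, and the nine-classifier comparison harness.

The method classifier is k-nearest-neighbor with k=1, Euclidean distance
and plain majority voting (vacuous at k=1); distance ties go to the lower
training index and even-vote ties to the nearest neighbor's label.
Evaluation pools the per-fold confusion counts into one matrix and applies
the four standard metrics, as percentages:

    accuracy  = 100 (TP + TN) / (TP + TN + FP + FN)
    recall    = 100 TP / (TP + FN)
    precision = 100 TP / (TP + FP)
    F1        = 100 * 2 TP / (2 TP + FN + FP)

with the large-occlusion class (label 0) as positive by default. The
comparison harness runs nine classifiers (kNN plus eight off-the-shelf
scikit-learn baselines) under identical fold assignments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "knn_predict",
    "compute_metrics",
    "cross_validate",
    "benchmark_classifiers",
    "CLASSIFIER_NAMES",
    "reports_to_csv",
    "reports_to_json",
]

CLASSIFIER_NAMES = ("kNN", "DT", "RF", "LD", "QD", "LR", "NB", "SVM", "MLP")


@dataclass
class ConfusionMatrix:
    """Pooled binary confusion counts; positive class is configurable
    upstream (default: large occlusion, label 0)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def add(self, other: "ConfusionMatrix") -> None:
        self.tp += other.tp
        self.tn += other.tn
        self.fp += other.fp
        self.fn += other.fn

    def as_dict(self) -> dict:
        return {"TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn}


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = 0
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(confusion: ConfusionMatrix) -> dict[str, float]:
    """Accuracy/recall/precision/F1 in percent from pooled counts.

    A zero-denominator ratio is reported as NaN with a warning, never as a
    silent zero.
    """
    if confusion.total == 0:
        raise ValidationError("confusion matrix is all zeros; nothing was evaluated")
    tp, tn, fp, fn = confusion.tp, confusion.tn, confusion.fp, confusion.fn
    out: dict[str, float] = {
        "accuracy": 100.0 * (tp + tn) / (tp + tn + fp + fn)
    }
    for name, num, den in (
        ("recall", tp, tp + fn),
        ("precision", tp, tp + fp),
        ("f1", 2 * tp, 2 * tp + fn + fp),
    ):
        if den == 0:
            warnings.warn(
                f"{name} undefined: zero denominator (TP={tp}, FP={fp}, FN={fn})",
                RuntimeWarning,
                stacklevel=2,
            )
            out[name] = float("nan")
        else:
            out[name] = 100.0 * num / den
    return out


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int = 1,
) -> np.ndarray:
    """k-nearest-neighbor prediction, Euclidean distance, majority vote.

    Distance ties resolve to the lower training index (stable sort); an even
    vote split resolves to the nearest neighbor's label.
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y)
    test_X = np.asarray(test_X, dtype=np.float64)
    if train_X.ndim == 1:
        train_X = train_X[:, None]
    if test_X.ndim == 1:
        test_X = test_X[:, None]
    n_train = train_X.shape[0]
    if n_train == 0:
        raise ValidationError("training set is empty")
    if not 1 <= k <= n_train:
        raise ValidationError(f"k={k} must lie in [1, n_train={n_train}]")

    d2 = ((test_X[:, None, :] - train_X[None, :, :]) ** 2).sum(axis=2)
    if k == 1:
        return train_y[d2.argmin(axis=1)]
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    preds = np.empty(test_X.shape[0], dtype=train_y.dtype)
    for i, neigh in enumerate(order):
        labels, counts = np.unique(train_y[neigh], return_counts=True)
        winners = labels[counts == counts.max()]
        if len(winners) == 1:
            preds[i] = winners[0]
        else:
            preds[i] = train_y[neigh[0]]  # vote tie -> nearest neighbor
    return preds


class _OneNN:
    """Minimal fit/predict wrapper around :func:`knn_predict`."""

    def __init__(self, k: int = 1):
        self.k = k

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OneNN":
        self._X = np.asarray(X)
        self._y = np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return knn_predict(self._X, self._y, X, k=self.k)

    def __repr__(self) -> str:
        return f"kNN(k={self.k}, distance=euclidean, voting=none)"


def make_classifier(name: str, seed: int = 0):
    """Instantiate a benchmark classifier by short name.

    kNN is the method classifier (k=1, Euclidean, plain vote); the other
    eight are off-the-shelf scikit-learn baselines used for comparison,
    with their settings recorded in the report.
    """
    factories: dict[str, Callable[[], object]] = {
        "kNN": lambda: _OneNN(k=1),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "RF": lambda: RandomForestClassifier(random_state=seed),
        # lsqr+shrinkage / reg_param keep the discriminants defined when the
        # selected panel is wider than a class's sample count
        "LD": lambda: LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"),
        "QD": lambda: QuadraticDiscriminantAnalysis(solver="eigen", shrinkage="auto"),
        "LR": lambda: LogisticRegression(max_iter=1000),
        "NB": lambda: GaussianNB(),
        "SVM": lambda: SVC(random_state=seed),
        "MLP": lambda: MLPClassifier(random_state=seed, max_iter=1000),
    }
    if name not in factories:
        raise ValidationError(
            f"unknown classifier {name!r}; choose from {sorted(factories)}"
        )
    return factories[name]()


@dataclass
class EvaluationReport:
    classifier_name: str
    folds: int
    seed: int
    confusion: ConfusionMatrix
    accuracy: float
    recall: float
    precision: float
    f1: float
    per_fold_accuracy: list[float] = field(default_factory=list)
    per_fold_confusions: list[ConfusionMatrix] = field(default_factory=list)
    classifier_settings: str = ""

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier_name,
            "folds": self.folds,
            "seed": self.seed,
            "confusion": self.confusion.as_dict(),
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "per_fold_accuracy": self.per_fold_accuracy,
            "classifier_settings": self.classifier_settings,
        }


def cross_validate(
    classifier_spec: str | object,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    positive: int = 0,
) -> EvaluationReport:
    """Stratified k-fold evaluation with pooled confusion metrics.

    ``classifier_spec`` is a short name (see :data:`CLASSIFIER_NAMES`) or
    any fit/predict estimator. Fold assignment is fixed by ``seed``;
    standardization (off by default, matching the selection stages) is
    fitted on training folds only when enabled.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    counts = np.bincount(y.astype(np.int64))
    if counts[counts > 0].min() < folds:
        raise ValidationError(
            f"smallest class has {counts[counts > 0].min()} samples, "
            f"fewer than folds={folds}"
        )
    name = classifier_spec if isinstance(classifier_spec, str) else type(classifier_spec).__name__

    pooled = ConfusionMatrix()
    per_fold_acc: list[float] = []
    per_fold_cm: list[ConfusionMatrix] = []
    settings = ""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        clf = (
            make_classifier(classifier_spec, seed=seed)
            if isinstance(classifier_spec, str)
            else classifier_spec
        )
        settings = repr(clf)
        Xtr, Xte = X[train_idx], X[test_idx]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf.fit(Xtr, y[train_idx])
        preds = np.asarray(clf.predict(Xte))
        cm = confusion_from_labels(y[test_idx], preds, positive=positive)
        per_fold_cm.append(cm)
        per_fold_acc.append(100.0 * (cm.tp + cm.tn) / cm.total)
        pooled.add(cm)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        metrics = compute_metrics(pooled)
    return EvaluationReport(
        classifier_name=name,
        folds=folds,
        seed=seed,
        confusion=pooled,
        accuracy=metrics["accuracy"],
        recall=metrics["recall"],
        precision=metrics["precision"],
        f1=metrics["f1"],
        per_fold_accuracy=per_fold_acc,
        per_fold_confusions=per_fold_cm,
        classifier_settings=settings,
    )


def benchmark_classifiers(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    positive: int = 0,
) -> list[EvaluationReport]:
    """Evaluate all nine classifiers under identical fold assignments."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence etc. on tiny data
        return [
            cross_validate(name, X, y, folds=folds, seed=seed,
                           standardize=standardize, positive=positive)
            for name in CLASSIFIER_NAMES
        ]


def reports_to_csv(reports: Sequence[EvaluationReport], path: str | Path) -> Path:
    import pandas as pd

    rows = [
        {
            "classifier": r.classifier_name,
            "accuracy": r.accuracy,
            "recall": r.recall,
            "precision": r.precision,
            "f1": r.f1,
        }
        for r in reports
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def reports_to_json(reports: Sequence[EvaluationReport], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([r.as_dict() for r in reports], indent=2))
    return path
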