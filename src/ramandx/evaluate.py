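"""Experimental protocol: stratified 7:3 split, three-class and pairwise
binary evaluation, confusion matrices, sensitivity/specificity, ROC/AUC.

Conventions
-----------
* Confusion-matrix rows are true classes, columns predictions, in canonical
  (HC, BC, DCIS) order restricted to the task.
* In binary tasks the positive class is the second-listed one (disease over
  healthy, DCIS over BC): sensitivity is its recall, specificity the recall
  of the first class.
* The three-class AUC is the macro average of one-vs-rest trapezoidal AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

from .baselines import fit_knn, fit_rf, fit_svm
from .errors import ConfigError, DataError
from .models import CNNSpec, TrainedModel, fit_cnn
from .partition import SplitResult, stratified_split  # noqa: F401  (re-export)
from .preprocess import PreprocessConfig, preprocess_set
from .synth import GeneratorConfig, generate_dataset
from .types import CLASSES, SpectrumSet

FAMILIES: tuple[str, ...] = ("KNN", "RF", "SVM", "CNN")
CLASS_PAIRS: tuple[tuple[str, str], ...] = (("HC", "BC"), ("HC", "DCIS"), ("BC", "DCIS"))


@dataclass
class ConfusionMatrix:
    """K x K contingency table; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise DataError(f"counts shape {self.counts.shape} for {k} classes")
        if np.any(self.counts < 0):
            raise DataError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Accuracy, error count and (binary tasks) sensitivity/specificity/AUC.

    Undefined rates (a class absent from the truth) are reported as NaN with
    the affected quantity named in ``undefined``, never as a silent zero.
    """

    accuracy: float
    misdiagnoses: int
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    auc: Optional[float] = None
    roc_points: Optional[dict[str, list[list[float]]]] = None
    positive_class: Optional[str] = None
    undefined: list[str] = field(default_factory=list)


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    """Count (true, predicted) label pairs into a contingency table."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise DataError(f"{y_true.size} truths vs {y_pred.size} predictions")
    order = tuple(class_order)
    vocab = set(order)
    for lab in np.concatenate([y_true, y_pred]):
        if lab not in vocab:
            raise DataError(f"label {lab!r} outside class order {order}")
    counts = _sk_confusion(y_true, y_pred, labels=list(order))
    return ConfusionMatrix(counts=counts, class_order=order)


def metrics_from_cm(
    cm: ConfusionMatrix, positive_class: Optional[str] = None
) -> MetricsReport:
    """Accuracy and misdiagnosis count; sensitivity/specificity for 2x2 tables.

    Sensitivity is the recall of ``positive_class``; specificity the recall
    of the other class.
    """
    total = cm.total
    if total == 0:
        raise DataError("empty confusion matrix")
    trace = int(np.trace(cm.counts))
    report = MetricsReport(accuracy=trace / total, misdiagnoses=total - trace)
    if positive_class is not None:
        if len(cm.class_order) != 2:
            raise DataError("sensitivity/specificity need a 2x2 confusion matrix")
        if positive_class not in cm.class_order:
            raise DataError(f"positive class {positive_class!r} not in {cm.class_order}")
        pos = cm.class_order.index(positive_class)
        neg = 1 - pos
        report.positive_class = positive_class
        for name, row, diag in (("sensitivity", pos, pos), ("specificity", neg, neg)):
            denom = cm.counts[row].sum()
            if denom == 0:
                setattr(report, name, float("nan"))
                report.undefined.append(name)
            else:
                setattr(report, name, float(cm.counts[diag, diag] / denom))
    return report


def roc_auc(
    scores: np.ndarray,
    y_true: Sequence[str],
    class_order: Sequence[str],
    positive_class: Optional[str] = None,
) -> MetricsReport:
    """ROC/AUC from per-class probability scores.

    Two classes: standard trapezoidal AUC over the positive-class score
    ranking.  Three classes: macro-averaged one-vs-rest AUC, with one ROC
    curve per class.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=object)
    order = tuple(class_order)
    if scores.shape != (y_true.size, len(order)):
        raise DataError(f"scores shape {scores.shape} for {y_true.size} samples, {len(order)} classes")
    present = [c for c in order if np.any(y_true == c)]
    if len(present) < 2:
        raise DataError("ROC needs at least two classes present in y_true")

    points: dict[str, list[list[float]]] = {}
    if len(order) == 2:
        pos = positive_class or order[1]
        pi = order.index(pos)
        y_bin = (y_true == pos).astype(int)
        auc = float(roc_auc_score(y_bin, scores[:, pi]))
        fpr, tpr, _ = roc_curve(y_bin, scores[:, pi])
        points[pos] = np.column_stack([fpr, tpr]).tolist()
    else:
        aucs = []
        for ci, cls in enumerate(order):
            y_bin = (y_true == cls).astype(int)
            aucs.append(float(roc_auc_score(y_bin, scores[:, ci])))
            fpr, tpr, _ = roc_curve(y_bin, scores[:, ci])
            points[cls] = np.column_stack([fpr, tpr]).tolist()
        auc = float(np.mean(aucs))
        pos = None
    predicted = np.array([order[i] for i in scores.argmax(axis=1)], dtype=object)
    acc = float(np.mean(predicted == y_true))
    return MetricsReport(
        accuracy=acc,
        misdiagnoses=int(np.sum(predicted != y_true)),
        auc=auc,
        roc_points=points,
        positive_class=pos,
    )


# ---------------------------------------------------------------------------
# model fitting dispatch


@dataclass
class ModelGrids:
    """Hyperparameter search space per family plus the CNN architecture."""

    k_grid: Sequence[int] = (1, 3, 5, 7, 9, 11, 13, 15)
    n_trees_grid: Sequence[int] = (100, 200, 500)
    depth_grid: Sequence[Optional[int]] = (5, 10, None)
    c_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
    cnn: CNNSpec = field(default_factory=CNNSpec)
    cnn_cv: bool = True


def _fit_family(
    family: str, train_set: SpectrumSet, grids: ModelGrids, seed: int, run_cv: bool = True
):
    n_classes = len(set(train_set.labels))
    if family == "KNN":
        return fit_knn(train_set, grids.k_grid, seed=seed)
    if family == "RF":
        return fit_rf(train_set, grids.n_trees_grid, grids.depth_grid, seed=seed)
    if family == "SVM":
        return fit_svm(train_set, grids.c_grid, grids.gamma_grid, seed=seed)
    if family == "CNN":
        spec = replace(
            grids.cnn, input_len=train_set.n_points, n_classes=n_classes
        )
        return fit_cnn(
            train_set, spec, seed=seed, run_cv=run_cv and grids.cnn_cv
        )
    raise ConfigError(f"unknown model family {family!r}")


def _evaluate_model(
    model: TrainedModel, test_set: SpectrumSet, class_order: tuple[str, ...],
    positive_class: Optional[str] = None,
) -> dict[str, Any]:
    y_true = np.asarray(test_set.labels, dtype=object)
    y_pred = model.predict(test_set.intensities)
    cm = confusion(y_true, y_pred, class_order)
    metrics = metrics_from_cm(
        cm, positive_class=positive_class if len(class_order) == 2 else None
    )
    scores = model.predict_proba(test_set.intensities)
    roc = roc_auc(scores, y_true, model.classes, positive_class=positive_class)
    return {
        "class_order": list(class_order),
        "confusion": cm.counts.tolist(),
        "accuracy": metrics.accuracy,
        "misdiagnoses": metrics.misdiagnoses,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "positive_class": positive_class,
        "auc": roc.auc,
        "roc_points": roc.roc_points,
        "score_scheme": model.metadata.get("scores"),
    }


def run_binary_experiments(
    spectra: SpectrumSet,
    split: SplitResult,
    families: Sequence[str] = FAMILIES,
    grids: Optional[ModelGrids] = None,
    seed: int = 0,
) -> dict[str, dict[str, Any]]:
    """Pairwise two-class experiments on the *same* train/test partition.

    For each class pair the three-class split is restricted to the pair's
    members; each family is refit from scratch and evaluated with the
    second-listed class as positive.
    """
    grids = grids or ModelGrids()
    labels = np.asarray(spectra.labels, dtype=object)
    results: dict[str, dict[str, Any]] = {}
    for first, second in CLASS_PAIRS:
        mask = (labels == first) | (labels == second)
        tr = np.array([i for i in split.train_indices if mask[i]], dtype=int)
        te = np.array([i for i in split.test_indices if mask[i]], dtype=int)
        train_set, test_set = spectra.subset(tr), spectra.subset(te)
        pair_key = f"{first}_vs_{second}"
        results[pair_key] = {}
        for family in families:
            model, _cv = _fit_family(family, train_set, grids, seed=seed, run_cv=False)
            results[pair_key][family] = _evaluate_model(
                model, test_set, (first, second), positive_class=second
            )
    return results


def run_full_experiment(
    generator: Optional[GeneratorConfig] = None,
    preprocess: Optional[PreprocessConfig] = None,
    grids: Optional[ModelGrids] = None,
    train_frac: float = 0.7,
    seed: int = 0,
    families: Sequence[str] = FAMILIES,
    dataset: Optional[SpectrumSet] = None,
) -> dict[str, Any]:
    """The complete protocol: data -> preprocessing -> split -> CV -> fits ->
    three-class and pairwise evaluation.

    Returns a JSON-serialisable report with every confusion matrix, metric,
    CV table and the CNN training history.  Identical inputs (including the
    seed) give an identical report.
    """
    generator = generator if generator is not None else GeneratorConfig(seed=seed)
    preprocess_cfg = preprocess or PreprocessConfig()
    grids = grids or ModelGrids()

    if dataset is None:
        dataset = generate_dataset(generator)
    processed = preprocess_set(dataset, preprocess_cfg)
    split = stratified_split(processed.labels, train_frac=train_frac, seed=seed)
    train_set = processed.subset(split.train_indices)
    test_set = processed.subset(split.test_indices)
    class_order = tuple(c for c in CLASSES if np.any(processed.labels == c))

    report: dict[str, Any] = {
        "seed": int(seed),
        "train_frac": train_frac,
        "classes": list(class_order),
        "split": {
            "per_class": {c: list(v) for c, v in split.per_class_counts.items()},
            "n_train": split.n_train,
            "n_test": split.n_test,
        },
        "cv": {},
        "three_class": {},
        "binary": {},
        "history": None,
    }
    for family in families:
        model, cv = _fit_family(family, train_set, grids, seed=seed, run_cv=True)
        if cv is not None:
            report["cv"][family] = {
                "grid": cv.grid,
                "fold_scores": cv.fold_scores.tolist(),
                "best": cv.best,
                "best_cv_accuracy": cv.best_cv_accuracy,
            }
        report["three_class"][family] = _evaluate_model(model, test_set, class_order)
        if family == "CNN" and model.history is not None:
            report["history"] = {
                "train_loss": model.history.train_loss,
                "train_accuracy": model.history.train_accuracy,
                "val_loss": model.history.val_loss,
                "val_accuracy": model.history.val_accuracy,
            }
    report["binary"] = run_binary_experiments(
        processed, split, families=families, grids=grids, seed=seed
    )
    return report
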