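"""Classical baseline classifiers (KNN, random forest, RBF-kernel SVM) with
5-fold cross-validated hyperparameter search.

scikit-learn provides the estimators; this module owns the grid protocol:
stratified 5-fold accuracy per hyperparameter combination, best = argmax of
the fold mean with ties broken by grid order.  Labels are integer-encoded in
the canonical (HC, BC, DCIS) order before fitting so that any vote tie lands
on the smallest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigError, DataError
from .types import CLASSES, SpectrumSet
from .cnn import CNNClassifier, TrainingHistory

DEFAULT_K_GRID: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)
DEFAULT_TREES_GRID: tuple[int, ...] = (100, 200, 500)
DEFAULT_DEPTH_GRID: tuple[Optional[int], ...] = (5, 10, None)
DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)

N_FOLDS = 5


@dataclass
class CVResult:
    """Outcome of a grid search: per-fold accuracies and the winning combination."""

    grid: list[dict[str, Any]]
    fold_scores: np.ndarray  # (n_combinations, n_folds)
    best: dict[str, Any]
    best_cv_accuracy: float


@dataclass
class TrainedModel:
    """A fitted classifier of any family behind one prediction surface.

    ``predict`` returns string labels from ``classes``; ``predict_proba``
    rows are aligned with ``classes`` and sum to 1.
    """

    family: str
    model: Any
    classes: tuple[str, ...]
    history: Optional[TrainingHistory] = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if isinstance(self.model, CNNClassifier):
            return self.model.predict_proba(x)
        # sklearn orders columns by self.model.classes_ (sorted codes); the
        # canonical encoding makes that identical to our class order, but a
        # class can be absent from a degenerate training set.
        raw = self.model.predict_proba(x)
        out = np.zeros((x.shape[0], len(self.classes)))
        for col, code in enumerate(self.model.classes_):
            out[:, int(code)] = raw[:, col]
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        codes = self.predict_proba(x).argmax(axis=1)
        return np.array([self.classes[c] for c in codes], dtype=object)


def _encode(train_set: SpectrumSet) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Integer-encode labels over the classes present, in canonical order."""
    if any(lab is None for lab in train_set.labels):
        raise DataError("training set contains unlabelled spectra")
    classes = tuple(c for c in CLASSES if np.any(train_set.labels == c))
    index = {c: i for i, c in enumerate(classes)}
    y = np.array([index[lab] for lab in train_set.labels], dtype=int)
    return train_set.intensities, y, classes


def _grid_cv(
    factory: Callable[[dict[str, Any]], Any],
    grid: Sequence[dict[str, Any]],
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> CVResult:
    """Stratified 5-fold accuracy for every combination; argmax by fold mean."""
    if not grid:
        raise ConfigError("hyperparameter grid is empty")
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=int(seed) % (2**31))
    folds = list(skf.split(x, y))
    scores = np.zeros((len(grid), N_FOLDS))
    for gi, combo in enumerate(grid):
        for fi, (tr, va) in enumerate(folds):
            est = factory(combo)
            if hasattr(est, "n_neighbors"):  # a fold is smaller than the full set
                est.n_neighbors = min(est.n_neighbors, tr.size)
            est.fit(x[tr], y[tr])
            scores[gi, fi] = float(np.mean(est.predict(x[va]) == y[va]))
    means = scores.mean(axis=1)
    best_i = int(np.argmax(means))  # first maximum wins on ties
    return CVResult(
        grid=list(grid),
        fold_scores=scores,
        best=dict(grid[best_i]),
        best_cv_accuracy=float(means[best_i]),
    )


def fit_knn(
    train_set: SpectrumSet,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    seed: int = 0,
) -> tuple[TrainedModel, CVResult]:
    """K-nearest-neighbour classifier, Euclidean distance, CV-selected k.

    During cross-validation k is capped at the fold's training size (a fold
    holds only 4/5 of the samples).
    """
    x, y, classes = _encode(train_set)
    for k in k_grid:
        if not 1 <= k <= x.shape[0]:
            raise ConfigError(f"k={k} outside [1, n_train={x.shape[0]}]")
    factory = lambda c: KNeighborsClassifier(n_neighbors=c["k"], metric="euclidean")
    cv = _grid_cv(factory, [{"k": int(k)} for k in k_grid], x, y, seed)
    model = factory(cv.best).fit(x, y)
    return (
        TrainedModel("KNN", model, classes, metadata={"best": cv.best, "scores": "vote fractions"}),
        cv,
    )


def fit_rf(
    train_set: SpectrumSet,
    n_trees_grid: Sequence[int] = DEFAULT_TREES_GRID,
    depth_grid: Sequence[Optional[int]] = DEFAULT_DEPTH_GRID,
    seed: int = 0,
) -> tuple[TrainedModel, CVResult]:
    """Random-forest ensemble; tree count and depth selected by CV."""
    x, y, classes = _encode(train_set)
    grid = [
        {"n_trees": int(n), "max_depth": (None if d is None else int(d))}
        for n in n_trees_grid
        for d in depth_grid
    ]
    factory = lambda c: RandomForestClassifier(
        n_estimators=c["n_trees"],
        max_depth=c["max_depth"],
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    cv = _grid_cv(factory, grid, x, y, seed)
    model = factory(cv.best).fit(x, y)
    return (
        TrainedModel("RF", model, classes, metadata={"best": cv.best, "scores": "vote fractions"}),
        cv,
    )


def fit_svm(
    train_set: SpectrumSet,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> tuple[TrainedModel, CVResult]:
    """RBF-kernel SVM (one-vs-rest for 3 classes), grid-searched C and gamma.

    Probability scores for ROC come from Platt scaling on the final refit.
    """
    x, y, classes = _encode(train_set)
    for c in c_grid:
        if c <= 0:
            raise ConfigError(f"C must be positive, got {c}")
    for g in gamma_grid:
        if g <= 0:
            raise ConfigError(f"gamma must be positive, got {g}")
    grid = [{"C": float(c), "gamma": float(g)} for c in c_grid for g in gamma_grid]
    rs = int(seed) % (2**31)
    factory = lambda c: SVC(
        kernel="rbf",
        C=c["C"],
        gamma=c["gamma"],
        decision_function_shape="ovr",
        random_state=rs,
    )
    cv = _grid_cv(factory, grid, x, y, seed)
    # Platt-style sigmoid calibration of the decision values provides the
    # probability scores used for ROC curves.
    final = CalibratedClassifierCV(
        factory(cv.best), method="sigmoid", cv=N_FOLDS, ensemble=False
    ).fit(x, y)
    return (
        TrainedModel("SVM", final, classes, metadata={"best": cv.best, "scores": "Platt scaling"}),
        cv,
    )
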