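"""Facade over the four classifier families.

Re-exports the CNN (``cnn`` module) and the classical baselines
(``baselines`` module) and adds ``fit_cnn``, which wraps network
construction + training behind the same ``(TrainedModel, CVResult)`` surface
the other families use.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .baselines import (  # noqa: F401
    CVResult,
    TrainedModel,
    DEFAULT_C_GRID,
    DEFAULT_DEPTH_GRID,
    DEFAULT_GAMMA_GRID,
    DEFAULT_K_GRID,
    DEFAULT_TREES_GRID,
    N_FOLDS,
    fit_knn,
    fit_rf,
    fit_svm,
    _encode,
)
from .cnn import (  # noqa: F401
    CNNClassifier,
    CNNSpec,
    TrainingHistory,
    build_cnn,
    flattened_size,
    train_cnn,
)
from .errors import DataError
from .types import SpectrumSet

from sklearn.model_selection import StratifiedKFold


def fit_cnn(
    train_set: SpectrumSet,
    spec: Optional[CNNSpec] = None,
    seed: int = 0,
    val_fraction: float = 0.2,
    run_cv: bool = False,
) -> tuple[TrainedModel, Optional[CVResult]]:
    """Build and train the CNN; optionally score it by stratified 5-fold CV.

    The CV estimate (one combination — the fixed hyperparameters) retrains
    the network from scratch on each fold, which dominates the runtime; it is
    off by default and enabled for full experiment reports.
    """
    x, y, classes = _encode(train_set)
    if spec is None:
        spec = CNNSpec(input_len=x.shape[1], n_classes=len(classes))
    if spec.n_classes != len(classes):
        raise DataError(
            f"network has {spec.n_classes} output nodes but the training set "
            f"contains {len(classes)} classes"
        )

    cv: Optional[CVResult] = None
    if run_cv:
        skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=int(seed) % (2**31))
        scores = np.zeros((1, N_FOLDS))
        for fi, (tr, va) in enumerate(skf.split(x, y)):
            fold_model = build_cnn(spec, seed=seed + fi + 1)
            train_cnn(fold_model, x[tr], y[tr], val_fraction=0.0, seed=seed + fi + 1)
            scores[0, fi] = float(np.mean(fold_model.predict(x[va]) == y[va]))
        combo = {"batch_size": spec.batch_size, "epochs": spec.epochs,
                 "learning_rate": spec.learning_rate, "optimizer": spec.optimizer,
                 "activation": spec.hidden_activation}
        cv = CVResult(grid=[combo], fold_scores=scores, best=combo,
                      best_cv_accuracy=float(scores.mean()))

    model = build_cnn(spec, seed=seed)
    train_cnn(model, x, y, val_fraction=val_fraction, seed=seed)
    trained = TrainedModel(
        "CNN", model, classes, history=model.history, metadata={"scores": "softmax"}
    )
    return trained, cv
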