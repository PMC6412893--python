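"""Boosting K-Fold classification over a gradient-boosted-tree backend.

Stratified k-fold training is run *sequentially*: every sample misclassified
in fold f's validation set is duplicated once into fold f+1's training set
(the misjudged set is replaced each fold, never accumulated), so that the
next fold's model pays extra attention to the hard samples.  Prediction is a
hard majority vote over the k fold models, with ties broken toward the
smallest class index (bincount-argmax semantics over the documented
first-appearance label encoding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FoldPlan",
    "GBDTParams",
    "BoostKFoldModel",
    "stratified_folds",
    "fit_gbdt_backend",
    "train_boosting_kfold",
    "predict_majority_vote",
]


class _Classifier(Protocol):
    def predict(self, X: np.ndarray) -> np.ndarray: ...


def _quiet_predict(model: "_Classifier", X: np.ndarray) -> np.ndarray:
    """Hard predictions, silencing lightgbm's spurious feature-name warning
    (its sklearn wrapper records generated column names even for array input)."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*does not have valid feature names.*")
        return np.asarray(model.predict(X))


@dataclass
class FoldPlan:
    """k disjoint, exhaustive, stratified (train, validation) index pairs."""

    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"need k >= 2 folds, got {self.k}")
        if len(self.folds) != self.k:
            raise ValueError("fold count does not match k")
        val = np.concatenate([v for _, v in self.folds])
        if len(val) != len(set(val.tolist())):
            raise ValueError("validation sets overlap")

    @property
    def n_samples(self) -> int:
        return sum(len(v) for _, v in self.folds)


@dataclass(frozen=True)
class GBDTParams:
    """Backend hyperparameters: library defaults, 100 rounds, fixed seed."""

    backend: str = "lightgbm"  # or "xgboost"
    n_estimators: int = 100
    learning_rate: float = 0.1
    seed: int = 0
    extra: dict = field(default_factory=dict)


def stratified_folds(labels: Sequence, k: int = 5, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold plan over ``labels``."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} samples; smallest class has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        (tr.copy(), va.copy())
        for tr, va in skf.split(np.zeros((len(labels), 1)), labels)
    ]
    return FoldPlan(k=k, folds=folds)


def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous integer codes 0..M-1 in first-appearance order."""
    classes = pd.unique(pd.Series(y))
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[v] for v in y], dtype=int), np.asarray(classes)


def fit_gbdt_backend(X: np.ndarray, y: np.ndarray, params: GBDTParams | None = None) -> _Classifier:
    """Fit a multiclass gradient-boosted tree model exposing hard predictions.

    ``y`` must already be integer-coded 0..M-1.  Deterministic given params.
    """
    params = params or GBDTParams()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    if params.backend == "lightgbm":
        from lightgbm import LGBMClassifier

        model = LGBMClassifier(
            n_estimators=params.n_estimators,
            learning_rate=params.learning_rate,
            random_state=params.seed,
            deterministic=True,
            force_row_wise=True,
            verbosity=-1,
            n_jobs=1,
            **params.extra,
        )
    elif params.backend == "xgboost":
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=params.n_estimators,
            learning_rate=params.learning_rate,
            random_state=params.seed,
            n_jobs=1,
            verbosity=0,
            **params.extra,
        )
    else:
        raise ValueError(f"unknown backend {params.backend!r}")
    model.fit(X, y)
    return model


@dataclass
class BoostKFoldModel:
    """The k sequentially trained fold models plus bookkeeping."""

    models: list[_Classifier]
    classes: np.ndarray
    misjudged_counts: list[int]
    train_sizes: list[int]
    params: GBDTParams | None = None

    @property
    def k(self) -> int:
        return len(self.models)


def train_boosting_kfold(
    X: np.ndarray,
    y: Sequence,
    plan: FoldPlan,
    params: GBDTParams | None = None,
    fit_fn: Callable[[np.ndarray, np.ndarray], _Classifier] | None = None,
) -> BoostKFoldModel:
    """Sequential boosting-across-folds training.

    Fold f trains on its plan training indices plus one copy of every sample
    misclassified in fold f-1's validation set; fold 1 gets no extras.  After
    each fold the misjudged set is replaced by that fold's validation errors.
    ``fit_fn`` overrides the backend (used with stub classifiers in tests).
    """
    X = np.asarray(X, dtype=float)
    y_enc, classes = _encode_labels(np.asarray(y))
    if plan.n_samples != len(y_enc):
        raise ValueError("fold plan does not match the data")
    if fit_fn is None:
        params = params or GBDTParams()
        fit_fn = lambda Xt, yt: fit_gbdt_backend(Xt, yt, params)  # noqa: E731

    models: list[_Classifier] = []
    mis_counts: list[int] = []
    train_sizes: list[int] = []
    mis_x = np.empty((0, X.shape[1]))
    mis_y = np.empty((0,), dtype=int)
    for tr_idx, va_idx in plan.folds:
        tra_x, tra_y = X[tr_idx], y_enc[tr_idx]
        if len(mis_x):
            tra_x = np.vstack([tra_x, mis_x])
            tra_y = np.hstack([tra_y, mis_y])
        model = fit_fn(tra_x, tra_y)
        models.append(model)
        train_sizes.append(len(tra_y))
        val_x, val_y = X[va_idx], y_enc[va_idx]
        val_pred = _quiet_predict(model, val_x)
        wrong = val_y != val_pred
        mis_x = val_x[wrong]
        mis_y = val_y[wrong]
        mis_counts.append(int(wrong.sum()))
    return BoostKFoldModel(
        models=models,
        classes=classes,
        misjudged_counts=mis_counts,
        train_sizes=train_sizes,
        params=params,
    )


def predict_majority_vote(model: BoostKFoldModel, X_test: np.ndarray) -> np.ndarray:
    """Hard majority vote over the k fold models.

    Ties break toward the smallest class code, i.e. the class appearing
    earliest in the training labels.
    """
    X_test = np.asarray(X_test, dtype=float)
    votes = np.stack([_quiet_predict(m, X_test) for m in model.models], axis=0)
    n_classes = len(model.classes)
    winners = np.empty(votes.shape[1], dtype=int)
    for j in range(votes.shape[1]):
        winners[j] = np.argmax(np.bincount(votes[:, j], minlength=n_classes))
    return model.classes[winners]
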