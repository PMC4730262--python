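"""RBF-kernel support-vector classification with grid-searched C and gamma.

The classifier is a one-vs-one multiclass SVM with a radial basis
function kernel.  Hyperparameters follow the classic LIBSVM coarse
grid: C = 2^-5, 2^-3, ..., 2^15 and gamma = 2^-15, 2^-13, ..., 2^3,
scored by stratified cross-validated overall accuracy with ties broken
toward the simpler model (smaller C, then smaller gamma).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .features import LabeledDataset

MODEL_FORMAT_VERSION = "gapdpc-model-1"

DEFAULT_COST_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))  # 11 points
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))  # 10 points


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters: cost C and kernel width gamma.

    ``gamma`` may be the string ``"scale"`` (the 1 / (d * var(X))
    heuristic) or a positive real.
    """

    cost: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError(f"cost must be positive, got {self.cost}")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise ValueError(f"gamma must be a positive real or 'scale', got {self.gamma!r}")
        elif self.gamma <= 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported here")


@dataclass(frozen=True)
class TrainedModel:
    """A fitted multiclass SVM restricted to a fixed feature subset."""

    estimator: SVC
    feature_indices: np.ndarray
    classes: tuple[str, ...]
    config: SVMConfig
    source_dim: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_indices", np.asarray(self.feature_indices, dtype=int))


def train(
    data: LabeledDataset,
    config: SVMConfig | None = None,
    feature_indices: Sequence[int] | None = None,
) -> TrainedModel:
    """Fit a one-vs-one RBF-SVM on the given columns of the dataset."""
    if config is None:
        config = SVMConfig()
    y = np.asarray([str(l) for l in data.labels])
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    d = data.n_features
    if feature_indices is None:
        cols = np.arange(d)
    else:
        cols = np.asarray(feature_indices, dtype=int)
        if cols.size == 0:
            raise ValueError("feature_indices is empty")
        if cols.min() < 0 or cols.max() >= d:
            raise ValueError(
                f"feature index out of range: valid columns are 0..{d - 1}, "
                f"got {cols.min()}..{cols.max()}"
            )
    est = SVC(kernel="rbf", C=config.cost, gamma=config.gamma, decision_function_shape="ovo")
    est.fit(data.matrix[:, cols], y)
    return TrainedModel(est, cols, classes, config, source_dim=d)


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Predict one class label per row of a full-width feature matrix."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.source_dim:
        raise ValueError(
            f"feature width mismatch: model expects {model.source_dim} columns, "
            f"got {X.shape[1]}"
        )
    return model.estimator.predict(X[:, model.feature_indices])


def grid_search(
    data: LabeledDataset,
    cost_grid: Sequence[float] | None = None,
    gamma_grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
    feature_indices: Sequence[int] | None = None,
) -> SVMConfig:
    """Pick (C, gamma) maximizing stratified CV overall accuracy.

    Candidates are scanned in ascending (C, gamma) order and a new best
    must be strictly better, so ties resolve to the smallest C, then
    the smallest gamma.
    """
    from .evaluation import stratified_folds

    cost_grid = list(DEFAULT_COST_GRID if cost_grid is None else cost_grid)
    gamma_grid = list(DEFAULT_GAMMA_GRID if gamma_grid is None else gamma_grid)
    if not cost_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    if folds < 2:
        raise ValueError("grid search needs at least 2 folds")

    y = data.labels.astype(str)
    splits = stratified_folds(data.labels, folds, seed)
    best: tuple[float, float] | None = None
    best_acc = -1.0
    for c in sorted(cost_grid):
        for g in sorted(gamma_grid):
            cfg = SVMConfig(cost=c, gamma=g)
            correct = 0
            for train_idx, test_idx in splits:
                sub = LabeledDataset(
                    data.matrix[train_idx],
                    data.labels[train_idx],
                    tuple(data.ids[i] for i in train_idx),
                )
                model = train(sub, cfg, feature_indices)
                correct += int((predict(model, data.matrix[test_idx]) == y[test_idx]).sum())
            acc = correct / data.n
            if acc > best_acc:
                best_acc, best = acc, (c, g)
    assert best is not None
    return SVMConfig(cost=best[0], gamma=best[1])


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a trained model with a format-version tag."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "estimator": model.estimator,
        "feature_indices": model.feature_indices,
        "classes": model.classes,
        "config": {"cost": model.config.cost, "gamma": model.config.gamma},
        "source_dim": model.source_dim,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; refuse other versions."""
    payload = joblib.load(path)
    version = payload.get("format_version") if isinstance(payload, dict) else None
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model file version {version!r} (expected {MODEL_FORMAT_VERSION})"
        )
    cfg = SVMConfig(cost=payload["config"]["cost"], gamma=payload["config"]["gamma"])
    return TrainedModel(
        payload["estimator"],
        payload["feature_indices"],
        tuple(payload["classes"]),
        cfg,
        payload["source_dim"],
    )
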