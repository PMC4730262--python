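"""Jackknife and k-fold evaluation with per-class accuracy and MCC.

The jackknife (leave-one-out) test predicts every protein from a model
trained on all the others.  Performance is summarised per structural
class by one-vs-rest confusion counts:

    accuracy_j = TP_j / |C_j|
    MCC_j      = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and overall accuracy = sum_j TP_j / sum_j |C_j|.  MCC is the Matthews
correlation coefficient, a balanced measure in [-1, 1]; when any factor
of the denominator is zero the value is defined as 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import SVMConfig, grid_search, predict, train
from .features import LabeledDataset


def stratified_folds(
    labels: Sequence, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold index pairs (train, test).

    Class proportions per fold differ by at most one sample.  Raises
    when the fold count exceeds the smallest class size, which would
    leave some folds without that class.
    """
    y = np.asarray([str(l) for l in labels])
    n = len(y)
    if folds == n:  # limiting case: k-fold degenerates to leave-one-out
        idx = np.arange(n)
        return [(np.delete(idx, i), idx[i : i + 1]) for i in range(n)]
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"fold count {folds} exceeds smallest class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest counts derived from a C x C confusion matrix."""

    classes: tuple[str, ...]
    matrix: np.ndarray  # rows: truth, columns: prediction

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "classes", tuple(self.classes))
        c = len(self.classes)
        if m.shape != (c, c) or (m < 0).any():
            raise ValueError(f"confusion matrix must be {c}x{c} nonnegative")

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def class_size(self, cls: str) -> int:
        return int(self.matrix[self.classes.index(cls)].sum())

    def tp(self, cls: str) -> int:
        i = self.classes.index(cls)
        return int(self.matrix[i, i])

    def fn(self, cls: str) -> int:
        return self.class_size(cls) - self.tp(cls)

    def fp(self, cls: str) -> int:
        i = self.classes.index(cls)
        return int(self.matrix[:, i].sum()) - self.tp(cls)

    def tn(self, cls: str) -> int:
        return self.n - self.tp(cls) - self.fn(cls) - self.fp(cls)


def confusion(
    true_labels: Sequence, predicted_labels: Sequence, classes: Sequence[str] | None = None
) -> ConfusionCounts:
    """Confusion counts from aligned truth/prediction label vectors."""
    y_true = np.asarray([str(l) for l in true_labels])
    y_pred = np.asarray([str(l) for l in predicted_labels])
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"label vectors differ in length: {len(y_true)} vs {len(y_pred)}"
        )
    if classes is None:
        classes = sorted(set(y_true))
    classes = tuple(str(c) for c in classes)
    stray = sorted(set(np.concatenate([y_true, y_pred])) - set(classes))
    if stray:
        raise ValueError(f"labels outside the class set: {', '.join(stray)}")
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return ConfusionCounts(classes=classes, matrix=m)


def class_accuracy(counts: ConfusionCounts) -> dict[str, float | None]:
    """TP_j / |C_j| per class; None marks a class absent from the truth."""
    out: dict[str, float | None] = {}
    for cls in counts.classes:
        size = counts.class_size(cls)
        out[cls] = counts.tp(cls) / size if size else None
    return out


def mcc(counts: ConfusionCounts) -> dict[str, float]:
    """One-vs-rest Matthews correlation per class (0 on degenerate counts)."""
    out: dict[str, float] = {}
    for cls in counts.classes:
        tp, tn = counts.tp(cls), counts.tn(cls)
        fp, fn = counts.fp(cls), counts.fn(cls)
        denom = math.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        out[cls] = (tp * tn - fp * fn) / denom if denom else 0.0
    return out


def overall_accuracy(counts: ConfusionCounts) -> float:
    """Fraction of all samples whose class was predicted correctly."""
    if counts.n == 0:
        raise ValueError("empty confusion matrix")
    return sum(counts.tp(c) for c in counts.classes) / counts.n


@dataclass(frozen=True)
class EvalReport:
    """Evaluation summary: confusion counts, per-class metrics, protocol."""

    counts: ConfusionCounts
    protocol: dict

    @property
    def per_class_accuracy(self) -> dict[str, float | None]:
        return class_accuracy(self.counts)

    @property
    def per_class_mcc(self) -> dict[str, float]:
        return mcc(self.counts)

    @property
    def overall(self) -> float:
        return overall_accuracy(self.counts)

    @property
    def n(self) -> int:
        return self.counts.n

    def to_dict(self) -> dict:
        return {
            "classes": list(self.counts.classes),
            "confusion_matrix": self.counts.matrix.tolist(),
            "class_sizes": {c: self.counts.class_size(c) for c in self.counts.classes},
            "per_class_accuracy": self.per_class_accuracy,
            "per_class_mcc": self.per_class_mcc,
            "overall_accuracy": self.overall,
            "n": self.n,
            "protocol": self.protocol,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def to_text(self) -> str:
        """Human-readable table: per-class accuracy (%), MCC, overall."""
        acc, mc = self.per_class_accuracy, self.per_class_mcc
        width = max(len(c) for c in self.counts.classes)
        lines = [f"{'class':<{width}}  {'n':>5}  {'accuracy':>9}  {'MCC':>6}"]
        for c in self.counts.classes:
            a = f"{100 * acc[c]:.1f}%" if acc[c] is not None else "--"
            lines.append(
                f"{c:<{width}}  {self.counts.class_size(c):>5}  {a:>9}  {mc[c]:>6.2f}"
            )
        lines.append(
            f"{'overall':<{width}}  {self.n:>5}  {100 * self.overall:.1f}%".rstrip()
        )
        lines.append(f"protocol: {self.protocol.get('name', '?')}")
        return "\n".join(lines)


@dataclass(frozen=True)
class PipelineConfig:
    """What to do in each training split of an evaluation protocol.

    Non-nested (default): classify with the fixed ``feature_indices``
    and ``svm_config`` chosen beforehand on the full dataset — the
    rank-once / tune-once sequence, optimistic but simple.  Nested:
    re-run SVM-RFE (and, when ``tune_nested`` is set, the (C, gamma)
    grid search) inside every training split for selection-unbiased
    estimates.
    """

    feature_indices: np.ndarray | None = None
    svm_config: SVMConfig = field(default_factory=SVMConfig)
    nested: bool = False
    top_k: int | None = None
    rfe_step: float = 0.1
    c_linear: float = 1.0
    tune_nested: bool = False
    inner_folds: int = 3
    cost_grid: tuple[float, ...] | None = None
    gamma_grid: tuple[float, ...] | None = None
    seed: int = 0

    def describe(self) -> dict:
        return {
            "nested": self.nested,
            "top_k": self.top_k,
            "n_features": None
            if self.feature_indices is None
            else int(np.asarray(self.feature_indices).size),
            "svm": {"cost": self.svm_config.cost, "gamma": self.svm_config.gamma},
            "seed": self.seed,
        }


def _fit_and_predict(
    train_data: LabeledDataset, test_X: np.ndarray, cfg: PipelineConfig
) -> np.ndarray:
    from .selection import rank_features, select_top_k

    cols = cfg.feature_indices
    svm_cfg = cfg.svm_config
    if cfg.nested:
        if cfg.top_k is None:
            raise ValueError("nested evaluation requires top_k")
        ranking = rank_features(train_data, step=cfg.rfe_step, c_linear=cfg.c_linear)
        cols = select_top_k(ranking, min(cfg.top_k, ranking.n_features))
        if cfg.tune_nested:
            svm_cfg = grid_search(
                train_data,
                cfg.cost_grid,
                cfg.gamma_grid,
                folds=cfg.inner_folds,
                seed=cfg.seed,
                feature_indices=cols,
            )
    model = train(train_data, svm_cfg, cols)
    return predict(model, test_X)


def jackknife(data: LabeledDataset, config: PipelineConfig | None = None) -> EvalReport:
    """Leave-one-out evaluation: each sample is predicted by a model
    trained on the other n - 1.

    Training splits that lose a class entirely (a singleton class held
    out) are still evaluated but flagged in the report protocol.  When
    nested tuning is requested, singleton classes make the inner
    stratified search impossible and raise instead.
    """
    if config is None:
        config = PipelineConfig()
    y = data.labels.astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("jackknife requires at least 2 classes")
    if data.n < 3:
        raise ValueError("jackknife needs at least 3 samples")
    sizes = data.class_sizes()
    if config.nested and config.tune_nested and min(sizes.values()) < 2:
        raise ValueError(
            "nested stratified tuning impossible: some class has a single member"
        )
    preds = np.empty(data.n, dtype=object)
    degenerate: list[str] = []
    for i in range(data.n):
        mask = np.ones(data.n, dtype=bool)
        mask[i] = False
        sub = LabeledDataset(
            data.matrix[mask], data.labels[mask], tuple(np.array(data.ids)[mask])
        )
        if len(set(sub.labels.astype(str))) < len(classes):
            degenerate.append(data.ids[i])
        preds[i] = _fit_and_predict(sub, data.matrix[i : i + 1], config)[0]
    counts = confusion(y, preds.astype(str), classes=classes)
    protocol = {
        "name": "jackknife",
        **config.describe(),
        "degenerate_folds": degenerate,
    }
    return EvalReport(counts=counts, protocol=protocol)


def kfold(
    data: LabeledDataset,
    folds: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> EvalReport:
    """Stratified k-fold analogue of the jackknife test."""
    if config is None:
        config = PipelineConfig()
    y = data.labels.astype(str)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("k-fold evaluation requires at least 2 classes")
    preds = np.empty(data.n, dtype=object)
    for train_idx, test_idx in stratified_folds(data.labels, folds, seed):
        sub = LabeledDataset(
            data.matrix[train_idx],
            data.labels[train_idx],
            tuple(data.ids[i] for i in train_idx),
        )
        preds[test_idx] = _fit_and_predict(sub, data.matrix[test_idx], config)
    counts = confusion(y, preds.astype(str), classes=classes)
    protocol = {"name": f"{folds}-fold", "folds": folds, "cv_seed": seed, **config.describe()}
    return EvalReport(counts=counts, protocol=protocol)
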