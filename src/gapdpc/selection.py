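"""SVM-RFE feature ranking and top-K selection.

Recursive feature elimination with a linear support-vector machine:
fit a linear-kernel SVM on the surviving features, score each feature
by the sum over all one-vs-one binary classifiers of its squared
weight component (Guyon's w^2 criterion extended to multiclass),
eliminate the lowest-scoring block, and repeat until no features
remain.  The ranking is the elimination sequence reversed, so the most
relevant feature comes first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import LabeledDataset, decode_feature_index


@dataclass(frozen=True)
class FeatureRanking:
    """A permutation of feature indices, best first, with importances.

    ``scores[f]`` is the squared-weight importance feature ``f`` had in
    the elimination round that removed it: comparable within a round,
    only loosely across rounds.
    """

    order: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "order", order)
        object.__setattr__(self, "scores", scores)
        if sorted(order.tolist()) != list(range(len(order))):
            raise ValueError("order must be a permutation of 0..d-1")
        if scores.shape != order.shape:
            raise ValueError("scores must align with order")

    @property
    def n_features(self) -> int:
        return len(self.order)


def _n_to_eliminate(step: float, surviving: int) -> int:
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if step < 1:
        n = int(np.floor(step * surviving))
    else:
        n = int(step)
    return max(1, min(n, surviving))


def rank_features(
    data: LabeledDataset,
    step: float = 0.1,
    c_linear: float = 1.0,
    standardize: bool = False,
) -> FeatureRanking:
    """Rank features by recursive elimination with a linear SVM.

    Parameters
    ----------
    data
        Labeled feature matrix; needs at least two classes and four
        samples.
    step
        Features removed per round: a fraction of the surviving set
        when < 1 (floor, at least one), an absolute count otherwise.
        ``step=1`` is classic one-at-a-time RFE.
    c_linear
        Cost parameter of the linear SVM used for scoring.
    standardize
        Z-score features before ranking.  Off by default: features
        computed from sigmoid-scaled profiles are already bounded.

    Notes
    -----
    Ties in importance are broken in favour of the lower original
    index: among equally-scored features the higher index is
    eliminated first, so identical columns rank in index order.
    """
    X = data.matrix
    y = np.asarray([str(l) for l in data.labels])
    n, d = X.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples to rank, got {n}")
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking requires at least 2 classes")
    sizes = data.class_sizes()
    small = [c for c, s in sizes.items() if s < 2]
    if small:
        warnings.warn(
            f"classes with a single member ({', '.join(small)}): ranking proceeds "
            "but is unstable",
            stacklevel=2,
        )
    if standardize:
        X = StandardScaler().fit_transform(X)

    surviving = np.arange(d)
    eliminated: list[int] = []
    scores = np.zeros(d)
    while surviving.size:
        clf = SVC(kernel="linear", C=c_linear)
        clf.fit(X[:, surviving], y)
        importance = np.square(clf.coef_).sum(axis=0)
        k = _n_to_eliminate(step, surviving.size)
        # Worst first; on ties the higher original index goes first, so
        # lower indices survive longer and end up ranked ahead.
        batch_order = np.lexsort((-surviving, importance))[:k]
        for pos in batch_order:
            eliminated.append(int(surviving[pos]))
            scores[surviving[pos]] = importance[pos]
        surviving = np.delete(surviving, batch_order)

    order = np.array(eliminated[::-1], dtype=int)
    return FeatureRanking(order=order, scores=scores)


def select_top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """The K best-ranked feature indices, ascending-sorted for slicing."""
    d = ranking.n_features
    if not 1 <= k <= d:
        raise ValueError(f"K must be in 1..{d}, got {k}")
    return np.sort(ranking.order[:k])


def default_k_grid(d: int | None = None) -> list[int]:
    """K = 10, 20, ..., 500, truncated to the feature count if given."""
    grid = list(range(10, 501, 10))
    if d is not None:
        grid = [k for k in grid if k <= d]
    return grid


@dataclass(frozen=True)
class SweepResult:
    """Cross-validated accuracy per candidate K and the best K found."""

    table: pd.DataFrame  # columns: K, accuracy
    best_k: int

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def sweep_top_k(
    data: LabeledDataset,
    ranking: FeatureRanking,
    k_grid: Sequence[int] | None = None,
    folds: int = 5,
    seed: int = 0,
    config=None,
    nested: bool = False,
    rfe_step: float = 0.1,
    c_linear: float = 1.0,
) -> SweepResult:
    """Cross-validated overall accuracy for each candidate K.

    For every K in the grid, the top-K columns of ``ranking`` are fed
    to the RBF-SVM and scored by stratified ``folds``-fold
    cross-validation.  By default the ranking is the one computed once
    on the full dataset (the protocol implied by ranking before the
    sweep); ``nested=True`` re-runs RFE inside every training fold for
    a selection-unbiased estimate.  The best K is the accuracy argmax,
    smallest K on ties.
    """
    from .classifier import SVMConfig, train, predict
    from .evaluation import stratified_folds

    if config is None:
        config = SVMConfig()
    if k_grid is None:
        k_grid = default_k_grid(data.n_features)
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty K grid")
    if max(k_grid) > data.n_features:
        raise ValueError(f"max K {max(k_grid)} exceeds feature count {data.n_features}")

    splits = stratified_folds(data.labels, folds, seed)
    rows = []
    for k in k_grid:
        correct = 0
        for train_idx, test_idx in splits:
            sub = LabeledDataset(
                data.matrix[train_idx],
                data.labels[train_idx],
                tuple(data.ids[i] for i in train_idx),
            )
            rk = rank_features(sub, step=rfe_step, c_linear=c_linear) if nested else ranking
            cols = select_top_k(rk, k)
            model = train(sub, config, cols)
            pred = predict(model, data.matrix[test_idx])
            correct += int((pred == data.labels[test_idx].astype(str)).sum())
        rows.append((k, correct / data.n))
    table = pd.DataFrame(rows, columns=["K", "accuracy"])
    best_k = int(table.loc[table["accuracy"].idxmax(), "K"])  # idxmax: first max
    return SweepResult(table=table, best_k=best_k)


def write_ranking_tsv(
    ranking: FeatureRanking, path: str | Path, max_gap: int | None = None
) -> None:
    """Write the ranking as TSV: rank, flat_index, name, importance.

    Names decode to ``g{g}_{aa_i}{aa_j}`` when the feature count fits a
    full GapDPC layout (a multiple of 400), else ``f{idx}``.
    """
    d = ranking.n_features
    if max_gap is None and d % 400 == 0 and d > 0:
        max_gap = d // 400 - 1
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tflat_index\tname\timportance\n")
        for rank, idx in enumerate(ranking.order):
            if max_gap is not None:
                g, ai, aj = decode_feature_index(int(idx), max_gap)
                name = f"g{g}_{ai}{aj}"
            else:
                name = f"f{idx}"
            fh.write(f"{rank}\t{idx}\t{name}\t{float(ranking.scores[idx])!r}\n")


def read_ranking_tsv(path: str | Path) -> FeatureRanking:
    """Read a ranking written by :func:`write_ranking_tsv`."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("rank")
    order = df["flat_index"].to_numpy(dtype=int)
    scores = np.zeros(len(order))
    scores[order] = df["importance"].to_numpy(dtype=float)
    return FeatureRanking(order=order, scores=scores)
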