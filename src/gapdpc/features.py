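"""Gapped-dipeptide composition (GapDPC) features from scaled PSSM profiles.

For a sigmoid-scaled profile ``p`` of length L, the dipeptide
composition generalises from the sequence to the profile as

    x[i, j]    = sum_{k=1..L-1}   p[k, i] * p[k+1, j]

and, for two residues separated by a gap of ``g`` positions,

    y[i, j, g] = sum_{k=1..L-g-1} p[k, i] * p[k+g+1, j]

over all 20 x 20 amino-acid pairs.  ``g = 0`` recovers ordinary
dipeptide composition.  Concatenating the blocks for g = 0..G yields a
400 * (G + 1)-dimensional vector per protein; the default G = 8 gives
3600 features.

Flat feature indexing is frozen as g-major, then first residue, then
second residue: flat = g * 400 + i * 20 + j with 0-based i, j over
:data:`gapdpc.pssm.AA_ORDER`.  Feature names decode as ``g{g}_{aa_i}{aa_j}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .pssm import AA_ORDER, PSSMProfile

DEFAULT_MAX_GAP = 8


def _require_scaled(profile: PSSMProfile) -> None:
    if not profile.scaled:
        raise ValueError("profile must be sigmoid-scaled before feature extraction")


def dpc(profile: PSSMProfile) -> np.ndarray:
    """Profile-based dipeptide composition, a 400-vector.

    Entry (i, j), at flat index ``i * 20 + j``, sums the products of
    the column-i weight at each position with the column-j weight at
    the next position.
    """
    _require_scaled(profile)
    if profile.length < 2:
        raise ValueError("sequence too short for dipeptides (need L >= 2)")
    return gapdpc(profile, 0)


def gapdpc(profile: PSSMProfile, g: int) -> np.ndarray:
    """Gapped-dipeptide composition for gap ``g``, a 400-vector.

    Requires L >= g + 2; an empty sum would silently yield an all-zero
    block, so shorter profiles are refused.
    """
    _require_scaled(profile)
    if g < 0:
        raise ValueError(f"gap must be nonnegative, got {g}")
    L = profile.length
    if L < g + 2:
        raise ValueError(
            f"gap exceeds sequence capacity: g={g} needs L >= {g + 2}, got L={L}"
        )
    P = profile.matrix
    # y[i, j] = sum_k P[k, i] * P[k+g+1, j]; row-major flatten matches
    # the frozen i-major, j-minor index convention.
    return (P[: L - g - 1].T @ P[g + 1 :]).ravel()


@dataclass(frozen=True)
class FeatureVector:
    """The 400*(G+1)-dimensional GapDPC representation of one protein."""

    values: np.ndarray
    max_gap: int
    protein_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (400 * (self.max_gap + 1),):
            raise ValueError(
                f"expected {400 * (self.max_gap + 1)} values for G={self.max_gap}, "
                f"got shape {v.shape}"
            )

    def block(self, g: int) -> np.ndarray:
        """The 400-vector for gap g (block g of the concatenation)."""
        if not 0 <= g <= self.max_gap:
            raise IndexError(f"gap {g} outside 0..{self.max_gap}")
        return self.values[g * 400 : (g + 1) * 400]


def feature_vector(
    profile: PSSMProfile, max_gap: int = DEFAULT_MAX_GAP, normalize_by_length: bool = False
) -> FeatureVector:
    """Concatenate GapDPC blocks for g = 0..max_gap in ascending order.

    ``normalize_by_length`` divides block g by its number of summed
    terms (L - g - 1), removing the dependence of feature magnitude on
    sequence length; off by default since the raw sums are the defined
    representation.
    """
    _require_scaled(profile)
    if profile.length < max_gap + 2:
        raise ValueError(
            f"profile {profile.protein_id or '<unnamed>'} of length {profile.length} "
            f"too short for G={max_gap}: minimum admissible length is {max_gap + 2}"
        )
    blocks = []
    for g in range(max_gap + 1):
        b = gapdpc(profile, g)
        if normalize_by_length:
            b = b / (profile.length - g - 1)
        blocks.append(b)
    return FeatureVector(np.concatenate(blocks), max_gap, profile.protein_id)


def feature_names(max_gap: int) -> list[str]:
    """Column names ``g{g}_{aa_i}{aa_j}`` in frozen flat-index order."""
    return [
        f"g{g}_{ai}{aj}"
        for g in range(max_gap + 1)
        for ai in AA_ORDER
        for aj in AA_ORDER
    ]


def decode_feature_index(flat: int, max_gap: int) -> tuple[int, str, str]:
    """Map a flat feature index back to (gap, first residue, second residue)."""
    if not 0 <= flat < 400 * (max_gap + 1):
        raise IndexError(f"flat index {flat} outside 0..{400 * (max_gap + 1) - 1}")
    g, rest = divmod(flat, 400)
    i, j = divmod(rest, 20)
    return g, AA_ORDER[i], AA_ORDER[j]


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix with aligned structural-class labels and protein ids."""

    matrix: np.ndarray
    labels: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        y = np.asarray(self.labels)
        object.__setattr__(self, "matrix", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "ids", tuple(self.ids))
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not (X.shape[0] == len(y) == len(self.ids)):
            raise ValueError("matrix rows, labels and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("protein ids must be unique")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(map(str, self.labels)))

    def class_sizes(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return {str(l): int(c) for l, c in zip(labels, counts)}


def extract_dataset(
    profiles: Iterable[PSSMProfile],
    labels: Mapping[str, str],
    max_gap: int = DEFAULT_MAX_GAP,
    normalize_by_length: bool = False,
) -> LabeledDataset:
    """Build a labeled feature matrix from scaled profiles.

    Rows are ordered by sorted protein id so the matrix is a pure
    function of the input set.  Every profile must carry a unique id
    and a label; too-short profiles are reported by name.
    """
    profs = sorted(profiles, key=lambda p: p.protein_id)
    if not profs:
        raise ValueError("no profiles given")
    ids = [p.protein_id for p in profs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {', '.join(dupes)}")
    unlabeled = [i for i in ids if i not in labels]
    if unlabeled:
        raise ValueError(f"missing labels for: {', '.join(unlabeled)}")
    rows = [feature_vector(p, max_gap, normalize_by_length).values for p in profs]
    return LabeledDataset(
        matrix=np.vstack(rows),
        labels=np.array([labels[i] for i in ids], dtype=object),
        ids=tuple(ids),
    )


def write_dataset_tsv(data: LabeledDataset, path: str | Path, max_gap: int | None = None) -> None:
    """Write a feature matrix as TSV: protein_id, class label, then features.

    Feature columns are named ``g{g}_{aa_i}{aa_j}`` when the width is a
    multiple of 400 (a full GapDPC layout), else ``f{idx}``.
    """
    d = data.n_features
    if max_gap is None and d % 400 == 0 and d > 0:
        max_gap = d // 400 - 1
    names = feature_names(max_gap) if max_gap is not None else [f"f{i}" for i in range(d)]
    df = pd.DataFrame(data.matrix, columns=names)
    df.insert(0, "class", [str(l) if l is not None else "NA" for l in data.labels])
    df.insert(0, "protein_id", list(data.ids))
    df.to_csv(path, sep="\t", index=False)


def read_dataset_tsv(path: str | Path) -> LabeledDataset:
    """Read a feature matrix written by :func:`write_dataset_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "class": str})
    if list(df.columns[:2]) != ["protein_id", "class"]:
        raise ValueError(f"{path}: expected leading columns protein_id, class")
    return LabeledDataset(
        matrix=df.iloc[:, 2:].to_numpy(dtype=float),
        labels=df["class"].to_numpy(dtype=object),
        ids=tuple(df["protein_id"]),
    )
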