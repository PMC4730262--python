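"""Seeded synthetic profiles and datasets for exercising every stage.

Real inputs to this pipeline are PSI-BLAST profiles computed against a
large sequence database — slow to produce and impossible to ship in a
test suite.  The generators here emulate their two properties that
matter downstream: rows of a scaled profile live strictly in (0, 1)
with controllable contrast, and class information can be planted at
the gapped-dipeptide level, i.e. in correlated residue propensities at
position pairs (k, k + g + 1), which is exactly the signal the GapDPC
features are built to capture.  They make no attempt to model real
evolutionary profiles (no substitution-matrix sampling, no alignment
depth effects) or true structural-class signal.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .features import LabeledDataset
from .pssm import AA_ORDER, PSSMProfile, logit

#: The four coarse structural classes, in a fixed order.
CLASS_NAMES: tuple[str, ...] = ("all-α", "all-β", "α/β", "α+β")

_EPS = 1e-9


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _rows_to_open_interval(rows: np.ndarray) -> np.ndarray:
    """Clip rows away from {0, 1} and renormalize to unit sum."""
    rows = np.clip(rows, _EPS, None)
    return rows / rows.sum(axis=1, keepdims=True)


def make_pssm(
    length: int,
    seed: int | np.random.Generator | None = 0,
    sharpness: float = 1.0,
    protein_id: str = "",
) -> PSSMProfile:
    """A random sigmoid-scaled profile of the given length.

    Rows are Dirichlet draws with concentration 1 / sharpness, so each
    row sums to one and higher sharpness gives higher row contrast
    (sharpness -> infinity approaches one-hot rows).  The sequence
    letter at each position is the highest-weight amino acid.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if sharpness <= 0:
        raise ValueError(f"sharpness must be positive, got {sharpness}")
    rng = _rng(seed)
    rows = rng.dirichlet(np.full(20, 1.0 / sharpness), size=length)
    rows = _rows_to_open_interval(rows)
    seq = "".join(AA_ORDER[j] for j in rows.argmax(axis=1))
    return PSSMProfile(seq, rows, scaled=True, protein_id=protein_id)


def to_raw(profile: PSSMProfile) -> PSSMProfile:
    """Invert the sigmoid, producing a plausible raw (log-odds) profile.

    ``sigmoid_scale(to_raw(p))`` recovers ``p`` exactly, so synthetic
    profiles can exercise the raw -> scaled path end to end.
    """
    if not profile.scaled:
        raise ValueError("profile is already raw")
    from dataclasses import replace

    return replace(profile, matrix=logit(profile.matrix), scaled=False)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a classed synthetic profile collection.

    ``class_signal`` is the effect size: 0 makes classes
    indistinguishable, larger values mix planted dipeptide sites closer
    to pure indicator rows.  ``n_informative_pairs`` (i, j, g) triples
    per class carry the signal; the triples are disjoint across classes.
    """

    n_per_class: int = 30
    length_range: tuple[int, int] = (30, 60)
    n_classes: int = 4
    class_signal: float = 2.0
    n_informative_pairs: int = 10
    max_gap: int = 4
    sites_per_pair: int = 2
    sharpness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_informative_pairs < 1 or self.sites_per_pair < 1:
            raise ValueError("all counts must be positive")
        if not 2 <= self.n_classes <= 4:
            raise ValueError("n_classes must be 2..4")
        if self.class_signal < 0:
            raise ValueError("class_signal must be nonnegative")
        l_min, l_max = self.length_range
        if l_min < self.max_gap + 2 or l_max < l_min:
            raise ValueError(
                f"length_range must satisfy L_min >= G + 2 = {self.max_gap + 2} "
                f"and L_max >= L_min"
            )
        d = 400 * (self.max_gap + 1)
        if self.n_classes * self.n_informative_pairs > d:
            raise ValueError(
                f"infeasible: {self.n_classes} x {self.n_informative_pairs} informative "
                f"pairs exceed the {d} available (i, j, g) triples"
            )


def make_classed_profiles(
    spec: SyntheticSpec,
) -> tuple[list[PSSMProfile], dict[str, str], np.ndarray]:
    """Generate labeled scaled profiles with planted GapDPC class signal.

    For each class a private set of (i, j, g) dipeptide triples is
    chosen; in every profile of that class, ``sites_per_pair`` position
    pairs (k, k + g + 1) per triple are mixed toward the indicator rows
    of residues i and j with weight w = signal / (1 + signal).  The
    GapDPC features at those flat indices then have class-shifted
    means, with separation growing monotonically in the signal.

    Returns (profiles, labels by protein id, sorted informative flat
    indices over all classes).
    """
    rng = np.random.default_rng(spec.seed)
    d = 400 * (spec.max_gap + 1)
    all_triples = rng.permutation(d)[: spec.n_classes * spec.n_informative_pairs]
    per_class = all_triples.reshape(spec.n_classes, spec.n_informative_pairs)
    w = spec.class_signal / (1.0 + spec.class_signal)

    profiles: list[PSSMProfile] = []
    labels: dict[str, str] = {}
    eye = np.eye(20)
    n_digits = len(str(spec.n_per_class))
    for c in range(spec.n_classes):
        cls = CLASS_NAMES[c]
        for m in range(spec.n_per_class):
            L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            rows = rng.dirichlet(np.full(20, 1.0 / spec.sharpness), size=L)
            for flat in per_class[c]:
                g, rest = divmod(int(flat), 400)
                i, j = divmod(rest, 20)
                for _ in range(spec.sites_per_pair):
                    k = int(rng.integers(0, L - g - 1))
                    rows[k] = (1 - w) * rows[k] + w * eye[i]
                    rows[k + g + 1] = (1 - w) * rows[k + g + 1] + w * eye[j]
            rows = _rows_to_open_interval(rows)
            seq = "".join(AA_ORDER[j] for j in rows.argmax(axis=1))
            pid = f"syn_c{c}_{m:0{n_digits}d}"
            profiles.append(PSSMProfile(seq, rows, scaled=True, protein_id=pid))
            labels[pid] = cls
    return profiles, labels, np.sort(all_triples)


def make_feature_dataset(
    n_per_class: int = 40,
    d: int = 200,
    n_informative: int = 10,
    effect: float = 2.0,
    n_classes: int = 4,
    seed: int = 0,
) -> tuple[LabeledDataset, np.ndarray]:
    """A Gaussian feature table with class-shifted informative columns.

    Features are standard normal; each informative column gets a
    class-specific mean offset drawn once as ``effect`` times a standard
    normal, giving between-class separation of order ``effect`` on
    informative columns and none elsewhere.  The direct test bed for
    feature selection and classification.

    Returns (dataset, sorted informative column indices).
    """
    if n_informative > d:
        raise ValueError(f"n_informative {n_informative} exceeds d {d}")
    if not 2 <= n_classes <= len(CLASS_NAMES):
        raise ValueError(f"n_classes must be 2..{len(CLASS_NAMES)}")
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    rng = np.random.default_rng(seed)
    informative = np.sort(rng.permutation(d)[:n_informative])
    offsets = effect * rng.standard_normal((n_classes, n_informative))
    n = n_per_class * n_classes
    X = rng.standard_normal((n, d))
    labels = np.empty(n, dtype=object)
    for c in range(n_classes):
        rows = slice(c * n_per_class, (c + 1) * n_per_class)
        X[rows, informative] += offsets[c]
        labels[rows] = CLASS_NAMES[c]
    ids = tuple(f"p{i:04d}" for i in range(n))
    return LabeledDataset(X, labels, ids), informative


_PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative weight "
    "of gapless real matches to pseudocounts\n"
)


def write_ascii_pssm(profile: PSSMProfile, path: str | Path, round_scores: bool = True) -> None:
    """Write a raw profile in the PSI-BLAST ``-out_ascii_pssm`` layout.

    Scores are rounded to integers by default, matching real psiblast
    output; the percentage block is filled with zeros.  Intended for
    generating parser fixtures, not for interchange with BLAST tools.
    """
    if profile.scaled:
        raise ValueError("write raw (unscaled) profiles; apply to_raw() first")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_PSSM_HEADER)
        fh.write("            " + "  ".join(AA_ORDER) + "   " + "   ".join(AA_ORDER) + "\n")
        for k in range(profile.length):
            if round_scores:
                scores = " ".join(f"{int(round(v)):3d}" for v in profile.matrix[k])
            else:
                scores = " ".join(f"{v:.3f}" for v in profile.matrix[k])
            percents = " ".join("  0" for _ in range(20))
            fh.write(f"{k + 1:5d} {profile.sequence[k]}  {scores}  {percents}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1000     0.3000\n")


def write_fixture_tree(
    profiles: Iterable[PSSMProfile], labels: dict[str, str], out_dir: str | Path
) -> None:
    """Emit ASCII PSSM files plus a labels.tsv mapping into a directory.

    Scaled profiles are converted back to raw log-odds (via the inverse
    sigmoid) before writing, so the files exercise the parse -> scale
    path; scores are written unrounded to keep the round trip faithful.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "labels.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein_id\tclass\n")
        for prof in profiles:
            raw = to_raw(prof) if prof.scaled else prof
            write_ascii_pssm(raw, out / f"{prof.protein_id}.pssm", round_scores=False)
            fh.write(f"{prof.protein_id}\t{labels[prof.protein_id]}\n")
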