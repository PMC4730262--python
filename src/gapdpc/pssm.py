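"""Reading and scaling of PSI-BLAST position-specific scoring matrices.

A PSSM (position-specific scoring matrix) is the L x 20 evolutionary
profile that PSI-BLAST writes with ``-out_ascii_pssm``: one row per
query position, one column per amino-acid type, holding integer
log-odds scores (first block) and rounded observed percentages
(second block).  Downstream feature extraction works on profiles whose
entries have been squashed into (0, 1) with the logistic sigmoid
``f(x) = 1 / (1 + exp(-x))``; the sigmoid only makes sense for signed
log-odds scores, so the score block is the default input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable

import numpy as np

#: Amino-acid column order used by the PSI-BLAST ASCII header.  All
#: feature indices downstream are defined against this ordering.
AA_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM stream cannot be parsed."""


@dataclass(frozen=True)
class PSSMProfile:
    """An L x 20 profile matrix together with its query sequence.

    Parameters
    ----------
    sequence
        Query residues, one letter per profile row.  Non-standard
        letters (X, B, Z, U, ...) are accepted: PSI-BLAST emits score
        rows for them and those rows carry information.
    matrix
        Shape ``(L, 20)``; columns follow :data:`AA_ORDER`.  Raw
        log-odds scores, or values in (0, 1) after sigmoid scaling.
    scaled
        True once :func:`sigmoid_scale` has been applied.
    protein_id
        Optional identifier used when assembling datasets.
    """

    sequence: str
    matrix: np.ndarray
    scaled: bool = False
    protein_id: str = ""
    column_order: str = field(default=AA_ORDER)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 20:
            raise ValueError(f"profile matrix must be L x 20, got shape {m.shape}")
        if len(self.sequence) != m.shape[0] or m.shape[0] < 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"matrix row count {m.shape[0]} (need L >= 1)"
            )
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError("column_order must be a permutation of the 20 standard amino acids")
        if self.scaled and not ((m > 0.0).all() and (m < 1.0).all()):
            raise ValueError("scaled profile entries must lie strictly within (0, 1)")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.length


def sigmoid_scale(profile: PSSMProfile) -> PSSMProfile:
    """Map every profile entry x to 1 / (1 + exp(-x)).

    Scores of 0 map to 0.5 and the map is strictly monotone, so the
    relative ordering of scores at each position is preserved while the
    range becomes (0, 1).  Scaling an already-scaled profile is refused:
    a second pass would silently compress all values into (0.5, 0.74).
    """
    if profile.scaled:
        raise ValueError("profile is already sigmoid-scaled; refusing to scale twice")
    with np.errstate(over="ignore"):
        scaled = 1.0 / (1.0 + np.exp(-profile.matrix))
    # Guard the open-interval invariant against float saturation at |x| >~ 37.
    tiny = np.finfo(float).tiny
    scaled = np.clip(scaled, tiny, 1.0 - np.finfo(float).epsneg)
    return replace(profile, matrix=scaled, scaled=True)


def _open_text(source: str | Path | IO[str]) -> Iterable[str]:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) else str(source)
    return text.splitlines(keepends=True)


def parse_pssm(
    source: str | Path | IO[str],
    block: str = "scores",
    protein_id: str = "",
) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a raw profile.

    Parameters
    ----------
    source
        Path, open text handle, or the file content itself (a string
        containing newlines).
    block
        ``"scores"`` (default) keeps the first 20-column block of
        log-odds scores; ``"percent"`` keeps the second block of
        weighted observed percentages.
    protein_id
        Identifier attached to the returned profile.

    Returns
    -------
    PSSMProfile
        Unscaled profile; sequence assembled from the residue column.
    """
    if block not in ("scores", "percent"):
        raise ValueError(f"block must be 'scores' or 'percent', got {block!r}")

    lines = list(_open_text(source))
    header_idx = None
    for i, line in enumerate(lines):
        parts = line.split()
        # The column-header line lists the 20 amino acids once or twice.
        if len(parts) in (20, 40) and "".join(parts[:20]) == AA_ORDER:
            header_idx = i
            break
    if header_idx is None:
        raise PSSMParseError("malformed header: amino-acid column line not found")

    rows: list[np.ndarray] = []
    residues: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        parts = line.split()
        if not parts:
            break  # blank line terminates the data block
        if not parts[0].isdigit():
            break  # trailing K/Lambda statistics
        if len(parts) < 22:
            raise PSSMParseError(
                f"line {lineno}: expected position, residue and 20 score columns, "
                f"got {len(parts)} fields"
            )
        pos, residue = int(parts[0]), parts[1]
        if pos != expected_pos:
            raise PSSMParseError(f"line {lineno}: position {pos}, expected {expected_pos}")
        if len(residue) != 1 or not residue.isalpha():
            raise PSSMParseError(f"line {lineno}: invalid residue field {residue!r}")
        if block == "percent" and len(parts) < 42:
            raise PSSMParseError(f"line {lineno}: percentage block absent ({len(parts)} fields)")
        raw = parts[2:22] if block == "scores" else parts[22:42]
        try:
            rows.append(np.array([float(v) for v in raw]))
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score ({exc})") from None
        residues.append(residue)
        expected_pos += 1

    if not rows:
        raise PSSMParseError("no positions: PSSM body is empty")
    return PSSMProfile(
        sequence="".join(residues),
        matrix=np.vstack(rows),
        scaled=False,
        protein_id=protein_id,
    )


def write_profile_tsv(profile: PSSMProfile, path: str | Path) -> None:
    """Dump a profile as TSV (position, residue, 20 score columns)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("position\tresidue\t" + "\t".join(AA_ORDER) + "\n")
        for k in range(profile.length):
            vals = "\t".join(repr(float(v)) for v in profile.matrix[k])
            fh.write(f"{k + 1}\t{profile.sequence[k]}\t{vals}\n")


def read_profile_tsv(path: str | Path, scaled: bool = False, protein_id: str = "") -> PSSMProfile:
    """Read a profile previously written by :func:`write_profile_tsv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t")[2:] != list(AA_ORDER):
        raise PSSMParseError(f"{path}: not a profile TSV (bad header)")
    residues, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != 22:
            raise PSSMParseError(f"{path}: expected 22 TSV columns, got {len(parts)}")
        residues.append(parts[1])
        rows.append([float(v) for v in parts[2:]])
    return PSSMProfile("".join(residues), np.array(rows), scaled=scaled, protein_id=protein_id)


def check_against_fasta(profiles: Iterable[PSSMProfile], fasta_path: str | Path) -> None:
    """Verify that profile sequences match the query FASTA records.

    Raises ``ValueError`` listing every profile whose sequence differs
    from the FASTA record of the same id.  Profiles without a matching
    record are reported too.
    """
    from Bio import SeqIO

    with open(fasta_path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    bad = []
    for prof in profiles:
        expected = records.get(prof.protein_id)
        if expected is None:
            bad.append(f"{prof.protein_id}: no FASTA record")
        elif expected != prof.sequence.upper():
            bad.append(f"{prof.protein_id}: sequence mismatch")
    if bad:
        raise ValueError("FASTA consistency check failed: " + "; ".join(bad))


def psiblast_command(
    query_fasta: str | Path,
    database: str,
    out_pssm: str | Path,
    iterations: int = 3,
    evalue: float = 0.001,
) -> list[str]:
    """Return the psiblast invocation that produces a profile for a query.

    Convenience only — building profiles requires a local BLAST protein
    database (typically NR) and is run outside this package:

    ``psiblast -query q.fasta -db nr -num_iterations 3 -evalue 0.001
    -out_ascii_pssm q.pssm``
    """
    return [
        "psiblast",
        "-query", str(query_fasta),
        "-db", database,
        "-num_iterations", str(iterations),
        "-evalue", str(evalue),
        "-out_ascii_pssm", str(out_pssm),
    ]


def logit(p: np.ndarray) -> np.ndarray:
    """Inverse of the sigmoid: log(p / (1 - p)) elementwise."""
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)
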