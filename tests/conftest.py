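from pathlib import Path

import numpy as np
import pytest

from gapdpc import PSSMProfile

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def psiblast_pssm_path() -> Path:
    """A real `psiblast -out_ascii_pssm` output for a 22-residue query."""
    return DATA_DIR / "psiblast_query.pssm"


@pytest.fixture
def query_fasta_path() -> Path:
    return DATA_DIR / "query.fasta"


def random_scaled_profile(rng: np.random.Generator, length: int, protein_id: str = "") -> PSSMProfile:
    """A scaled profile with i.i.d. uniform entries in (0, 1)."""
    m = rng.uniform(1e-6, 1 - 1e-6, size=(length, 20))
    seq = "".join("ARNDCQEGHILKMFPSTWYV"[j] for j in rng.integers(0, 20, size=length))
    return PSSMProfile(seq, m, scaled=True, protein_id=protein_id)


def naive_gapdpc(matrix: np.ndarray, g: int) -> np.ndarray:
    """Brute-force triple-loop gapped-dipeptide composition oracle."""
    L = matrix.shape[0]
    out = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            for k in range(L - g - 1):
                out[i, j] += matrix[k, i] * matrix[k + g + 1, j]
    return out.ravel()
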