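"""Parse a PSI-BLAST ASCII PSSM and sigmoid-scale it.

Writes a small synthetic profile in the `-out_ascii_pssm` layout,
reads it back, and applies the logistic scaling that maps log-odds
scores into (0, 1) for feature extraction.
"""

import tempfile
from pathlib import Path

from gapdpc import make_pssm, parse_pssm, sigmoid_scale, to_raw, write_ascii_pssm

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.pssm"
    write_ascii_pssm(to_raw(make_pssm(15, seed=4, sharpness=20.0)), path)

    profile = parse_pssm(path, protein_id="demo")
    print(f"query sequence ({profile.length} residues): {profile.sequence}")
    print(f"raw score range: {profile.matrix.min():.0f} .. {profile.matrix.max():.0f}")

    scaled = sigmoid_scale(profile)
    print(f"scaled range:    {scaled.matrix.min():.3f} .. {scaled.matrix.max():.3f}")
    print("a score of 0 maps to 0.5; more favourable substitutions map closer to 1.")
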