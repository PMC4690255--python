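"""The 20-letter canonical amino-acid alphabet and integer encoding.

Profiles carry one log-odds entry per canonical residue plus a 21st
zero-scoring slot for the ambiguity residue X.  Any letter outside the
canonical set (B, Z, J, U, O, ...) is normalised to X on input: it scores
zero against every profile column and never satisfies a motif character
class, but does match motif wildcard positions.
"""

from __future__ import annotations

import numpy as np

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
X_INDEX = len(CANONICAL)  # 20

AA_TO_INDEX = {aa: i for i, aa in enumerate(CANONICAL)}
AA_TO_INDEX["X"] = X_INDEX

# byte-level lookup table: ASCII code -> residue index (unknown -> X)
_LUT = np.full(256, X_INDEX, dtype=np.int64)
for _aa, _i in AA_TO_INDEX.items():
    _LUT[ord(_aa)] = _i
    _LUT[ord(_aa.lower())] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as an int array (canonical 0-19, X/other 20)."""
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _LUT[raw]


def normalize(sequence: str) -> str:
    """Uppercase a sequence and collapse non-canonical letters to X."""
    return "".join(CANONICAL[i] if i < X_INDEX else "X" for i in encode(sequence))


def uniform_background() -> np.ndarray:
    """Uniform frequency over the 20 canonical residues."""
    return np.full(len(CANONICAL), 1.0 / len(CANONICAL))
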