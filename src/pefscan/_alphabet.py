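"""The amino-acid alphabet and residue encoding shared across the package.

The 20 canonical residues are indexed 0..19 in the fixed order below.
Ambiguity codes (X, B, Z) and the rare translated residues U (selenocysteine)
and O (pyrrolysine) are accepted in sequences and encoded as index 20; the
scoring layer treats that index as "emit from the background" (log-odds 0).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_AA: int = 20

#: letters legal in a ProteinSequence beyond the canonical 20
AMBIGUITY_LETTERS: str = "XBZUO"

#: index used for ambiguity letters in encoded sequences
AMBIG_INDEX: int = 20

GAP_CHARS: str = "-."

_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
for letter in AMBIGUITY_LETTERS:
    _INDEX[letter] = AMBIG_INDEX

LEGAL_LETTERS = frozenset(AMINO_ACIDS + AMBIGUITY_LETTERS)


def encode(residues: str) -> np.ndarray:
    """Encode a residue string into integer indices (ambiguity -> 20)."""
    try:
        return np.fromiter(
            (_INDEX[c] for c in residues), dtype=np.int64, count=len(residues)
        )
    except KeyError as exc:  # pragma: no cover - guarded by sequence validation
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None


def uniform_background() -> np.ndarray:
    """Uniform 1/20 background composition (package default)."""
    return np.full(N_AA, 1.0 / N_AA)


def validate_background(background: np.ndarray) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (N_AA,):
        raise ValueError(f"background must have {N_AA} entries, got {bg.shape}")
    if np.any(bg <= 0):
        raise ValueError("background probabilities must be strictly positive")
    if abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must sum to 1")
    return bg / bg.sum()
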