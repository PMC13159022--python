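"""Amino-acid alphabet constants and validation helpers.

All probability vectors in this package are ordered by :data:`AMINO_ACIDS`
(the 20 canonical one-letter codes, alphabetical). Ambiguity codes and the
gap character are recognised on input but excluded from every profile
computation.
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical amino acids, alphabetical; fixes the axis order of every
#: probability vector in the package.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / non-standard codes tolerated in input alignments but excluded
#: from column multisets: X (any), B (D/N), Z (E/Q), J (I/L), U (Sec), O (Pyl).
AMBIGUITY_CODES: str = "XBZJUO"

GAP: str = "-"

ALLOWED_ALIGNMENT_CHARS = frozenset(AMINO_ACIDS + AMBIGUITY_CODES + GAP)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AA: int = len(AMINO_ACIDS)


def is_canonical(residue: str) -> bool:
    return residue in AA_INDEX


def validate_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and validate an ungapped sequence of canonical residues.

    Raises ValueError naming the offending position for gaps, ambiguity
    codes or foreign characters.
    """
    if not seq:
        raise ValueError(f"{context}: empty sequence")
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in AA_INDEX:
            raise ValueError(
                f"{context}: non-canonical residue {ch!r} at position {pos + 1}"
            )
    return seq


def encode(seq: str) -> np.ndarray:
    """Map a canonical sequence to integer indices over AMINO_ACIDS."""
    return np.fromiter((AA_INDEX[ch] for ch in seq), dtype=np.int64, count=len(seq))


def decode(indices: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in indices)
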