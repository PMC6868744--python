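"""Amino-acid alphabets shared across the package.

The motif alphabet is the 20 natural amino acids plus ``X``, the
gap-filling residue used for positions beyond a protein terminus and for
non-standard residues (B, J, O, U, Z, ``*`` ...).
"""

from __future__ import annotations

# 20 natural amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Gap-filling residue for terminal padding and non-standard letters.
GAP: str = "X"

#: Encoder alphabet: 20 amino acids followed by the gap residue.
MOTIF_ALPHABET: str = AMINO_ACIDS + GAP

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
MOTIF_INDEX = {aa: i for i, aa in enumerate(MOTIF_ALPHABET)}


def sanitize_residue(ch: str) -> str:
    """Map a residue letter into the motif alphabet (unknown -> ``X``)."""
    ch = ch.upper()
    return ch if ch in AA_INDEX else GAP
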