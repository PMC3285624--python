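"""The 20-letter amino-acid alphabet used throughout the package.

All pocket-specificity vectors and motif matrices index amino acids
alphabetically by one-letter code: ``ACDEFGHIKLMNPQRSTVWY``.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residue code treated as "unknown" in peptides; contributes zero to scores.
UNKNOWN_RESIDUE: str = "X"


def is_standard(residue: str) -> bool:
    """True if *residue* is one of the 20 standard one-letter codes."""
    return residue in AA_INDEX


def validate_sequence(seq: str, *, what: str = "sequence") -> None:
    """Raise ``ValueError`` if *seq* contains a non-standard residue."""
    for i, ch in enumerate(seq):
        if ch not in AA_INDEX:
            raise ValueError(
                f"non-standard residue {ch!r} at position {i + 1} of {what}"
            )
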