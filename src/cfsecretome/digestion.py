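"""In-silico tryptic digestion and theoretical-peptide counting for iBAQ.

Cleavage follows the Keil rule: after every lysine (K) or arginine (R)
except when the next residue is proline (P), with zero missed cleavages.
iBAQ divides a protein's summed intensity by its number of theoretical
tryptic peptides within configurable length bounds (default 6-30 residues,
the convention of the original iBAQ definition).
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MIN_PEPTIDE_LEN = 6
DEFAULT_MAX_PEPTIDE_LEN = 30

# Keil rule: cleave after K or R unless followed by P.
_CLEAVAGE_RE = re.compile(r"(?<=[KR])(?!P)")


def digest_tryptic(sequence: str) -> list[str]:
    """Fully digest ``sequence`` with trypsin (Keil rule, 0 missed cleavages).

    Returns the ordered peptides; their concatenation is the input sequence
    (digestion is a lossless partition).  Raises ``ValueError`` on an empty
    sequence or non-canonical residues.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical residues in sequence: {sorted(bad)}")
    peptides = _CLEAVAGE_RE.split(sequence)
    # a C-terminal K/R yields a zero-width split at the end of the string
    if peptides and peptides[-1] == "":
        peptides.pop()
    return peptides


def count_theoretical_peptides(
    sequence: str,
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> int:
    """Number of tryptic peptides of ``sequence`` with length in [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) exceeds max_len ({max_len})")
    return sum(min_len <= len(p) <= max_len for p in digest_tryptic(sequence))


def peptide_universe(
    sequences: Iterable[str],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> set[str]:
    """All in-bounds tryptic peptides occurring in any of ``sequences``."""
    out: set[str] = set()
    for seq in sequences:
        out.update(p for p in digest_tryptic(seq) if min_len <= len(p) <= max_len)
    return out


def build_shared_peptide_set(
    cell_db: Mapping[str, str],
    serum_db: Mapping[str, str],
    min_len: int = DEFAULT_MIN_PEPTIDE_LEN,
    max_len: int = DEFAULT_MAX_PEPTIDE_LEN,
) -> set[str]:
    """Tryptic peptides occurring in both the cell and the serum species.

    ``cell_db`` / ``serum_db`` map accession -> sequence.  Peptides in the
    intersection cannot be attributed to the cultured cells (the serum
    supplement is from another species) and are excluded from
    quantification downstream.
    """
    return peptide_universe(cell_db.values(), min_len, max_len) & peptide_universe(
        serum_db.values(), min_len, max_len
    )
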