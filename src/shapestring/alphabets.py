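"""Shared alphabets and residue/atom naming conventions.

Three alphabets run through the toolkit:

* the 20 standard one-letter amino-acid codes;
* the 8-letter shape-string alphabet ``S R U V K A T G`` (plus ``X`` for
  positions with no defined backbone conformation);
* the 10-letter discretization alphabet ``L A D C Q M V W P G`` used for
  binned chemical-shift and profile features, plus ``N`` for vacancies.
"""

from __future__ import annotations

# One-letter amino-acid codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

# Three-letter -> one-letter mapping for input tolerance.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# The six backbone chemical-shift atom types, in canonical feature order.
ATOMS: tuple[str, ...] = ("HA", "H", "N", "CA", "CB", "C")

# Shape-string state letters in canonical (box) order, plus the undefined mark.
SHAPE_LETTERS: str = "SRUVKATG"
UNDEFINED: str = "X"

# Collapse of the 8 shape states onto sheet-like / helix-like / turn-like.
SHAPE_8_TO_3: dict[str, str] = {
    "S": "S", "R": "S", "U": "S", "V": "S",
    "A": "H", "K": "H",
    "T": "T", "G": "T",
    UNDEFINED: UNDEFINED,
}

# Ten bin letters for discretized [0, 1] values, ascending-bin order,
# plus the vacancy letter.
BIN_LETTERS: str = "LADCQMVWPG"
VACANCY_LETTER: str = "N"
FEATURE_LETTERS: str = BIN_LETTERS + VACANCY_LETTER  # the 11-letter feature alphabet


def shape_index(letter: str) -> int:
    """Index of a shape letter in the canonical ``SRUVKATG`` box order."""
    i = SHAPE_LETTERS.find(letter)
    if i < 0:
        raise ValueError(f"not a shape letter: {letter!r}")
    return i
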