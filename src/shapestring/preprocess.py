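"""Chemical-shift normalization and alphabetization.

Raw shifts live on very different ppm scales per atom type and amino acid,
so each of the 20 x 6 (amino acid, atom) combinations gets its own linear
rescaling x_new = (x - x_min) / (x_max - x_min), with x_min/x_max the
training-set extremes for that combination (120 min/max pairs in total).
Query values outside the training range are clipped to the boundary.  The
rescaled [0, 1] value is then discretized into ten equal bins lettered
``L A D C Q M V W P G`` in ascending order; a vacant cell becomes ``N``,
giving an 11-letter feature alphabet per atom.  Binning deliberately
tolerates the small shift perturbations caused by pH/temperature differences
between experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .alphabets import AMINO_ACIDS, ATOMS, BIN_LETTERS, VACANCY_LETTER
from .shifty import ShiftRecordSeq, VACANT

logger = logging.getLogger(__name__)

# Per-residue alphabetized shift features: one string of 6 letters per residue.
AlphabetizedSeq = list


class ScaleConfigError(ValueError):
    """A lookup hit a degenerate or absent scale-table entry."""


@dataclass
class ScaleTable:
    """Per-(amino acid, atom) shift extremes used for linear rescaling.

    ``entries`` maps ``(aa, atom)`` to ``(x_min, x_max)``.  A combination
    never observed in the training corpus is simply absent; a combination
    observed exactly once is present but degenerate (``x_min == x_max``).
    """

    entries: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (aa, atom), (lo, hi) in self.entries.items():
            if aa not in AMINO_ACIDS or atom not in ATOMS:
                raise ValueError(f"bad scale-table key {(aa, atom)!r}")
            if lo > hi:
                raise ValueError(f"x_min > x_max for {(aa, atom)!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def degenerate(self) -> list[tuple[str, str]]:
        return [k for k, (lo, hi) in self.entries.items() if lo == hi]

    def missing(self) -> list[tuple[str, str]]:
        return [
            (aa, atom)
            for aa in AMINO_ACIDS
            for atom in ATOMS
            if (aa, atom) not in self.entries
        ]

    # -- serialization: versioned TSV so trained models are portable --------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#shapestring-scale-table\tv1\n")
            fh.write("aa\tatom\tx_min\tx_max\n")
            for (aa, atom) in sorted(self.entries):
                lo, hi = self.entries[(aa, atom)]
                fh.write(f"{aa}\t{atom}\t{lo!r}\t{hi!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "ScaleTable":
        entries: dict[tuple[str, str], tuple[float, float]] = {}
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#shapestring-scale-table"):
                raise ValueError(f"{path}: not a scale-table file")
            header = fh.readline().strip().split("\t")
            if header != ["aa", "atom", "x_min", "x_max"]:
                raise ValueError(f"{path}: unexpected scale-table columns")
            for line in fh:
                aa, atom, lo, hi = line.strip().split("\t")
                entries[(aa, atom)] = (float(lo), float(hi))
        return cls(entries=entries)


def fit_scale_table(corpus: list[ShiftRecordSeq]) -> ScaleTable:
    """Learn per-(aa, atom) min/max over all non-vacant shifts in ``corpus``.

    Vacant cells never enter the statistics.  Combinations with no
    observation are left absent (flagged via :meth:`ScaleTable.missing`),
    not treated as errors, so sparse corpora remain usable.
    """
    if not corpus:
        raise ValueError("empty corpus")
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    for rec in corpus:
        for res in rec.residues:
            for atom in ATOMS:
                x = res.shifts[atom]
                if x is VACANT:
                    continue
                key = (res.aa, atom)
                if key in entries:
                    lo, hi = entries[key]
                    entries[key] = (min(lo, x), max(hi, x))
                else:
                    entries[key] = (x, x)
    table = ScaleTable(entries=entries)
    if table.missing():
        logger.warning("scale table missing %d (aa, atom) combinations", len(table.missing()))
    return table


def normalize(x, aa: str, atom: str, table: ScaleTable):
    """Rescale one shift to [0, 1] using the (aa, atom) training extremes.

    Out-of-range values are clipped to the nearer extreme before the linear
    transform.  ``VACANT`` passes through.  A degenerate or absent table
    entry raises :class:`ScaleConfigError` (prediction-time code that wants
    a vacancy instead should use :func:`alphabetize_record`).
    """
    if x is VACANT:
        return VACANT
    key = (aa, atom)
    if key not in table.entries:
        raise ScaleConfigError(f"no scale entry for {key}")
    lo, hi = table.entries[key]
    if lo == hi:
        raise ScaleConfigError(f"degenerate scale entry for {key}")
    x = min(max(float(x), lo), hi)
    return (x - lo) / (hi - lo)


def alphabetize(v) -> str:
    """Discretize a [0, 1] value into the ten bin letters; ``VACANT`` -> ``N``.

    Bins are half-open ``[k/10, (k+1)/10)`` with the last bin closed at 1.0,
    so the bin index is ``min(floor(10 v), 9)``.
    """
    if v is VACANT:
        return VACANCY_LETTER
    v = float(v)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"value {v} outside [0, 1]; normalize first")
    return BIN_LETTERS[min(int(10 * v), 9)]


def alphabetize_record(rec: ShiftRecordSeq, table: ScaleTable) -> AlphabetizedSeq:
    """Alphabetize all six atoms of every residue.

    Returns one 6-letter string per residue in atom order ``HA H N CA CB C``.
    Degenerate/absent table entries at prediction time yield ``N`` with a
    logged warning rather than aborting, so sparse corpora stay usable.
    """
    out: AlphabetizedSeq = []
    warned: set[tuple[str, str]] = set()
    for res in rec.residues:
        letters = []
        for atom in ATOMS:
            try:
                letters.append(alphabetize(normalize(res.shifts[atom], res.aa, atom, table)))
            except ScaleConfigError:
                key = (res.aa, atom)
                if key not in warned:
                    logger.warning("unusable scale entry for %s; emitting vacancy", key)
                    warned.add(key)
                letters.append(VACANCY_LETTER)
        out.append("".join(letters))
    return out
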