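"""Reading and writing SHIFTY-dialect chemical-shift files and predictor output.

The dialect implemented here is a single, strictly parsed convention:

* lines starting with ``#`` are headers/comments; ``#CHAIN <id>`` names the
  chain and ``#SEQUENCE <letters>`` carries the one-letter sequence (the
  payload of repeated ``#SEQUENCE`` lines is concatenated, so long sequences
  may be wrapped);
* the data table is whitespace-delimited and begins with the column-name row
  ``NUM AA HA H N CA CB C``;
* a vacant (unassigned) shift cell is written as the literal token ``N``.

Residues listed in the sequence header but absent from the table are treated
as all-vacant rows: BMRB depositions routinely omit unassigned residues, and
silently dropping them would desynchronize the features from the structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .alphabets import AMINO_ACIDS, ATOMS, THREE_TO_ONE, SHAPE_LETTERS

#: Marker object semantics: a vacant shift cell is ``None``.
VACANT = None

MISSING_TOKEN = "N"
_COLUMNS = ("NUM", "AA") + ATOMS

PathOrStream = Union[str, Path, IO[str]]


class ShiftyFormatError(ValueError):
    """Raised for structurally malformed input files."""


class ShiftyValidationError(ValueError):
    """Raised for well-formed input violating record invariants."""


@dataclass
class Residue:
    """One residue: 1-based index, one-letter code, six shift slots (ppm)."""

    index: int
    aa: str
    shifts: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aa not in AMINO_ACIDS:
            raise ShiftyValidationError(f"unknown amino-acid code {self.aa!r}")
        for atom in ATOMS:
            self.shifts.setdefault(atom, VACANT)
        extra = set(self.shifts) - set(ATOMS)
        if extra:
            raise ShiftyValidationError(f"unknown atom types {sorted(extra)}")

    def n_vacant(self) -> int:
        return sum(1 for a in ATOMS if self.shifts[a] is VACANT)


@dataclass
class ShiftRecordSeq:
    """A chain's per-residue chemical shifts plus its amino-acid sequence."""

    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ShiftyValidationError("residue indices must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftRecordSeq):
            return NotImplemented
        if self.chain_id != other.chain_id or len(self) != len(other):
            return False
        for a, b in zip(self.residues, other.residues):
            if a.index != b.index or a.aa != b.aa or a.shifts != b.shifts:
                return False
        return True


def _open(path_or_stream: PathOrStream, mode: str) -> tuple[IO[str], bool]:
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, mode), True
    return path_or_stream, False


def _parse_aa(token: str) -> str:
    token = token.upper()
    if len(token) == 3:
        if token not in THREE_TO_ONE:
            raise ShiftyValidationError(f"unknown three-letter code {token!r}")
        return THREE_TO_ONE[token]
    if len(token) == 1 and token in AMINO_ACIDS:
        return token
    raise ShiftyValidationError(f"unknown amino-acid code {token!r}")


def read_shifty(path_or_stream: PathOrStream) -> ShiftRecordSeq:
    """Parse one SHIFTY-dialect file into a :class:`ShiftRecordSeq`.

    Raises :class:`ShiftyFormatError` on malformed headers or cells and
    :class:`ShiftyValidationError` on duplicate indices or unknown residue
    codes.  A cell counts as vacant only when it holds the declared missing
    token; any other unparseable cell is an error, never silently dropped.
    """
    fh, close = _open(path_or_stream, "r")
    try:
        chain_id = ""
        seq_parts: list[str] = []
        rows: dict[int, Residue] = {}
        saw_columns = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.upper().startswith("CHAIN"):
                    chain_id = body[5:].strip()
                elif body.upper().startswith("SEQUENCE"):
                    seq_parts.append(body[8:].strip())
                continue
            fields = line.split()
            if not saw_columns:
                if tuple(f.upper() for f in fields) != _COLUMNS:
                    raise ShiftyFormatError(
                        f"line {lineno}: expected column header {' '.join(_COLUMNS)}"
                    )
                saw_columns = True
                continue
            if len(fields) != len(_COLUMNS):
                raise ShiftyFormatError(
                    f"line {lineno}: expected {len(_COLUMNS)} fields, got {len(fields)}"
                )
            try:
                num = int(fields[0])
            except ValueError as exc:
                raise ShiftyFormatError(f"line {lineno}: bad residue number") from exc
            if num in rows:
                raise ShiftyValidationError(f"line {lineno}: duplicate residue index {num}")
            aa = _parse_aa(fields[1])
            shifts: dict[str, float | None] = {}
            for atom, cell in zip(ATOMS, fields[2:]):
                if cell == MISSING_TOKEN:
                    shifts[atom] = VACANT
                else:
                    try:
                        value = float(cell)
                    except ValueError as exc:
                        raise ShiftyFormatError(
                            f"line {lineno}: unparseable {atom} value {cell!r}"
                        ) from exc
                    if not math.isfinite(value):
                        raise ShiftyFormatError(f"line {lineno}: non-finite {atom} value")
                    shifts[atom] = value
            rows[num] = Residue(index=num, aa=aa, shifts=shifts)
        sequence = "".join(seq_parts)
        if sequence:
            residues: list[Residue] = []
            for i, aa in enumerate(sequence, start=1):
                if aa not in AMINO_ACIDS:
                    raise ShiftyValidationError(f"sequence letter {aa!r} at {i}")
                if i in rows:
                    if rows[i].aa != aa:
                        raise ShiftyValidationError(
                            f"residue {i}: table says {rows[i].aa}, sequence says {aa}"
                        )
                    residues.append(rows[i])
                else:
                    residues.append(Residue(index=i, aa=aa))
            orphan = set(rows) - set(range(1, len(sequence) + 1))
            if orphan:
                raise ShiftyValidationError(
                    f"table rows outside sequence range: {sorted(orphan)}"
                )
        else:
            residues = [rows[i] for i in sorted(rows)]
        return ShiftRecordSeq(chain_id=chain_id, residues=residues)
    finally:
        if close:
            fh.close()


def _format_value(v: float | None) -> str:
    return MISSING_TOKEN if v is VACANT else repr(float(v))


def write_shifty(rec: ShiftRecordSeq, path_or_stream: PathOrStream) -> None:
    """Write a record in the dialect of :func:`read_shifty` (bit-stable)."""
    fh, close = _open(path_or_stream, "w")
    try:
        if rec.chain_id:
            fh.write(f"#CHAIN {rec.chain_id}\n")
        seq = rec.sequence
        for i in range(0, len(seq), 60):
            fh.write(f"#SEQUENCE {seq[i:i + 60]}\n")
        fh.write(" ".join(_COLUMNS) + "\n")
        for r in rec.residues:
            cells = [str(r.index), r.aa] + [_format_value(r.shifts[a]) for a in ATOMS]
            fh.write(" ".join(cells) + "\n")
    finally:
        if close:
            fh.close()


def read_fasta(path_or_stream: PathOrStream) -> list[tuple[str, str]]:
    """Read plain (id, sequence) pairs from FASTA; also used for shape strings."""
    from Bio import SeqIO

    fh, close = _open(path_or_stream, "r")
    try:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    finally:
        if close:
            fh.close()


def write_fasta(records: Iterable[tuple[str, str]], path_or_stream: PathOrStream) -> None:
    fh, close = _open(path_or_stream, "w")
    try:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    finally:
        if close:
            fh.close()


_PRED_HEADER = ["pos", "aa", "shape"] + [f"p_{s}" for s in SHAPE_LETTERS]


def write_prediction(
    seq: str,
    pred: str,
    marginals,
    path_or_stream: PathOrStream,
    tol: float = 1e-6,
) -> None:
    """Write a prediction table: position, residue, shape letter, 8 marginals.

    ``marginals`` is an (L, 8) array-like of per-residue state probabilities
    in ``SRUVKATG`` order; each row must sum to 1 within ``tol``.
    """
    import numpy as np

    marg = np.asarray(marginals, dtype=float)
    if not (len(seq) == len(pred) == marg.shape[0]) or marg.ndim != 2 or marg.shape[1] != 8:
        raise ShiftyValidationError("sequence, prediction and marginals lengths differ")
    sums = marg.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise ShiftyValidationError("marginal rows must sum to 1")
    fh, close = _open(path_or_stream, "w")
    try:
        fh.write("\t".join(_PRED_HEADER) + "\n")
        for i, (aa, s) in enumerate(zip(seq, pred), start=1):
            probs = "\t".join(f"{p:.6f}" for p in marg[i - 1])
            fh.write(f"{i}\t{aa}\t{s}\t{probs}\n")
    finally:
        if close:
            fh.close()


def read_prediction(path_or_stream: PathOrStream) -> tuple[str, str, "list[list[float]]"]:
    """Read back a prediction table; returns (sequence, shapes, marginals)."""
    fh, close = _open(path_or_stream, "r")
    try:
        header = fh.readline().strip().split("\t")
        if header != _PRED_HEADER:
            raise ShiftyFormatError("unexpected prediction header")
        seq, shapes, marg = [], [], []
        for line in fh:
            fields = line.strip().split("\t")
            if len(fields) != len(_PRED_HEADER):
                raise ShiftyFormatError("short prediction row")
            seq.append(fields[1])
            shapes.append(fields[2])
            marg.append([float(x) for x in fields[3:]])
        return "".join(seq), "".join(shapes), marg
    finally:
        if close:
            fh.close()
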