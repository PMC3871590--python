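"""Shape strings: torsion-space assignment, 8->3 collapse, record alignment.

A shape string classifies each residue's (phi, psi) backbone torsion pair
into one of eight named regions of the Ramachandran plane: A (alpha helix),
S (beta sheet), K (helix ends / 3-10 helix), R (polyproline II), T (turn),
U and V (bridge regions), and G, which is reserved for glycine's
positive-phi conformations.  ``X`` marks positions with no defined
conformation (disorder, chain breaks).

The exact region boundaries of the original shape-string definition are not
published in a machine-readable form; the table shipped in
``data/torsion_regions.tsv`` is a documented approximation — a set of
disjoint rectangles covering the full torus, with a glycine-only override
checked first — and is data, not code: tests and the synthetic generator
treat the configured table itself as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .alphabets import SHAPE_LETTERS, SHAPE_8_TO_3, UNDEFINED
from .shifty import ShiftRecordSeq


class ShapeValidationError(ValueError):
    pass


def validate_shape_string(s: str) -> str:
    bad = set(s) - set(SHAPE_LETTERS + UNDEFINED)
    if bad:
        raise ShapeValidationError(f"invalid shape letters {sorted(bad)}")
    return s


def map8to3(s: str) -> str:
    """Collapse the 8 shape states onto {S, H, T}; ``X`` is preserved.

    ``[S, R, U, V] -> S`` (sheet-like), ``[A, K] -> H`` (helix-like),
    ``[T, G] -> T`` (turn-like).  Input letters outside the 8+X alphabet are
    rejected — in particular a 3-state string is not valid input.
    """
    validate_shape_string(s)
    return "".join(SHAPE_8_TO_3[c] for c in s)


@dataclass(frozen=True)
class TorsionRegion:
    letter: str
    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float
    gly_only: bool
    core: bool  # canonical rectangle used when sampling within this letter

    def _contains_1d(self, x: float, lo: float, hi: float) -> bool:
        # lower bound inclusive, upper exclusive, except the torus edge +180
        if hi >= 180.0:
            return lo <= x <= 180.0
        return lo <= x < hi

    def contains(self, phi: float, psi: float) -> bool:
        return self._contains_1d(phi, self.phi_lo, self.phi_hi) and self._contains_1d(
            psi, self.psi_lo, self.psi_hi
        )


@dataclass
class TorsionRegionTable:
    """Ordered rectangular partition of the Ramachandran plane.

    Rows are checked in listed order; glycine-only rows are skipped for
    other residues.  Bounds are lower-inclusive / upper-exclusive with the
    +180 deg edge closed, so every (phi, psi) maps to exactly one letter.
    """

    regions: list[TorsionRegion]

    def assign(self, phi: float, psi: float, aa: str) -> str:
        if not (-180.0 <= phi <= 180.0 and -180.0 <= psi <= 180.0):
            raise ShapeValidationError(f"torsion ({phi}, {psi}) outside [-180, 180]")
        is_gly = aa == "G"
        for region in self.regions:
            if region.gly_only and not is_gly:
                continue
            if region.contains(phi, psi):
                return region.letter
        raise ShapeValidationError(
            f"torsion table does not cover ({phi}, {psi})"
        )  # unreachable with the shipped table

    def core_rectangle(self, letter: str) -> TorsionRegion:
        for region in self.regions:
            if region.letter == letter and region.core:
                return region
        raise KeyError(f"no core rectangle for letter {letter!r}")

    @classmethod
    def from_tsv(cls, path) -> "TorsionRegionTable":
        regions: list[TorsionRegion] = []
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#shapestring-torsion-regions"):
                raise ValueError(f"{path}: not a torsion-region file")
            header = fh.readline().strip().split("\t")
            expect = ["letter", "phi_lo", "phi_hi", "psi_lo", "psi_hi", "gly_only", "core"]
            if header != expect:
                raise ValueError(f"{path}: unexpected columns {header}")
            for line in fh:
                f = line.strip().split("\t")
                if len(f) != 7:
                    continue
                if f[0] not in SHAPE_LETTERS:
                    raise ValueError(f"{path}: unknown shape letter {f[0]!r}")
                regions.append(
                    TorsionRegion(
                        letter=f[0],
                        phi_lo=float(f[1]),
                        phi_hi=float(f[2]),
                        psi_lo=float(f[3]),
                        psi_hi=float(f[4]),
                        gly_only=bool(int(f[5])),
                        core=bool(int(f[6])),
                    )
                )
        return cls(regions=regions)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#shapestring-torsion-regions\tv1\n")
            fh.write("letter\tphi_lo\tphi_hi\tpsi_lo\tpsi_hi\tgly_only\tcore\n")
            for r in self.regions:
                fh.write(
                    f"{r.letter}\t{r.phi_lo:g}\t{r.phi_hi:g}\t{r.psi_lo:g}\t"
                    f"{r.psi_hi:g}\t{int(r.gly_only)}\t{int(r.core)}\n"
                )


def default_torsion_table() -> TorsionRegionTable:
    """The torsion-region table shipped with the package."""
    with resources.as_file(
        resources.files("shapestring.data").joinpath("torsion_regions.tsv")
    ) as path:
        return TorsionRegionTable.from_tsv(path)


def assign_shape(phi: float, psi: float, aa: str, table: TorsionRegionTable) -> str:
    """Shape letter of the region containing (phi, psi) for residue type ``aa``."""
    return table.assign(phi, psi, aa)


def assign_shape_string(
    torsions: list[tuple[float, float]], sequence: str, table: TorsionRegionTable
) -> str:
    if len(torsions) != len(sequence):
        raise ShapeValidationError("torsion list / sequence length mismatch")
    return "".join(
        assign_shape(phi, psi, aa, table) for (phi, psi), aa in zip(torsions, sequence)
    )


def align_records(
    rec: ShiftRecordSeq,
    observed_seq: str,
    observed_shape: str,
) -> tuple[str, str]:
    """Transfer observed shape labels onto a shift record across chain breaks.

    The two amino-acid sequences are globally aligned with identity scoring
    hostile to substitutions (match +1, mismatch -10, gap open -5, extend
    -1), so only insertions/deletions — chain breaks and disordered
    termini — are tolerated.  Each shift-record residue inherits the shape
    letter of its aligned partner, or ``X`` when aligned to a gap.

    Returns ``(labels, status)`` with ``status`` either ``"ok"`` or
    ``"unalignable"``.  An entry is unalignable when any aligned residue
    pair differs, or when both sequences skip residues between (or outside)
    aligned blocks — a substitution region that the optimizer may render
    either as a mismatch or as a double gap (labels are still returned for
    inspection).
    """
    from Bio import Align

    if not rec.residues or not observed_seq:
        raise ShapeValidationError("empty sequence")
    if len(observed_seq) != len(observed_shape):
        raise ShapeValidationError("observed sequence/shape length mismatch")
    validate_shape_string(observed_shape)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -10.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0

    rec_seq = rec.sequence
    alignment = aligner.align(rec_seq, observed_seq)[0]
    blocks = list(zip(*alignment.aligned))
    labels = [UNDEFINED] * len(rec_seq)
    mismatched = False
    prev_t, prev_q = 0, 0
    for (t0, t1), (q0, q1) in blocks:
        if t0 > prev_t and q0 > prev_q:
            mismatched = True  # both chains skipped residues: substitution region
        prev_t, prev_q = t1, q1
        for off in range(t1 - t0):
            i, j = t0 + off, q0 + off
            if rec_seq[i] != observed_seq[j]:
                mismatched = True
            else:
                labels[i] = observed_shape[j]
    if prev_t < len(rec_seq) and prev_q < len(observed_seq):
        mismatched = True
    if not blocks:
        mismatched = True
    return "".join(labels), ("unalignable" if mismatched else "ok")
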