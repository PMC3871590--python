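"""Synthetic (sequence, shape string, chemical shift, torsion) corpora.

The generator emulates the statistical structure the predictor assumes in
real data: shape states form segments (a first-order Markov chain with a
self-transition bias), the state distribution is imbalanced (helix-state A
dominant, bridge/glycine states rare), chemical shifts depend on both the
amino-acid type and the shape state (Gaussian emissions whose state offsets
scale with a separation parameter ``s``), assignments have vacancies
(per-cell missingness), and torsions fall inside the Ramachandran region of
their state so shape assignment round-trips exactly.

What it does *not* emulate: real shift physics (no nearest-neighbour or
secondary-shift effects), glycine's missing CB, referencing errors, or
sequence-family structure, so sequence-similarity hits between unrelated
synthetic chains are rare and profile features carry signal mainly for
queries related to the reference corpus.

Glycine is emitted iff the shape state is G: shape G is defined only for
glycine and its torsion region overlaps the turn region, so any other
placement of glycine would break the assignment round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabets import AMINO_ACIDS, ATOMS, SHAPE_LETTERS
from .shape import TorsionRegionTable, default_torsion_table
from .shifty import Residue, ShiftRecordSeq, VACANT

# Typical ppm location and spread per atom type (coarse literature values).
ATOM_BASE: dict[str, tuple[float, float]] = {
    "HA": (4.5, 0.4),
    "H": (8.3, 0.5),
    "N": (119.0, 4.0),
    "CA": (58.0, 2.0),
    "CB": (33.0, 2.5),
    "C": (176.0, 1.5),
}

# Imbalanced stationary distribution: helix state dominant, sheet and
# polyproline mid-range, bridge/glycine states thin.
DEFAULT_STATIONARY: dict[str, float] = {
    "A": 0.40, "S": 0.20, "R": 0.12, "T": 0.10,
    "K": 0.07, "U": 0.04, "V": 0.04, "G": 0.03,
}

_STRUCTURE_SEED = 20131223  # fixes the per-(aa, atom) base means and state offsets


@dataclass
class SynthConfig:
    """Parameters of the synthetic corpus.

    ``separation`` scales the shape-state mean offsets in units of the
    per-atom SD: 0 makes shifts uninformative about shape (null corpus),
    values >= 2 make states well separated.  ``self_bias`` is the Markov
    self-transition probability mass (segmented strings); the off-diagonal
    mass is spread proportionally to ``stationary``, which is then also the
    chain's stationary distribution.  ``student_t_df`` switches emissions
    to a heavy-tailed Student-t to stress the min/max clipping path.
    """

    n_chains: int = 50
    length_range: tuple[int, int] = (50, 150)
    self_bias: float = 0.8
    stationary: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATIONARY)
    )
    separation: float = 3.0
    missingness: float = 0.1
    seed: int = 0
    student_t_df: Optional[float] = None

    def validate(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("bad length_range")
        if not 0 <= self.self_bias < 1:
            raise ValueError("self_bias must be in [0, 1)")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        probs = np.array([self.stationary.get(s, 0.0) for s in SHAPE_LETTERS])
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("stationary must be a distribution over the 8 states")

    def transition_matrix(self) -> np.ndarray:
        """P = b*I + (1-b) * 1 pi^T; rows sum to 1, stationary equals pi."""
        self.validate()
        pi = np.array([self.stationary.get(s, 0.0) for s in SHAPE_LETTERS])
        return self.self_bias * np.eye(8) + (1 - self.self_bias) * pi[None, :]


def _structure_params() -> tuple[dict, np.ndarray]:
    """Deterministic per-(aa, atom) base means/SDs and per-(state, atom) offsets."""
    rng = np.random.default_rng(_STRUCTURE_SEED)
    base: dict[tuple[str, str], tuple[float, float]] = {}
    for aa in AMINO_ACIDS:
        for atom in ATOMS:
            mean, sd = ATOM_BASE[atom]
            base[(aa, atom)] = (mean + rng.normal(0.0, 1.5 * sd), sd)
    offsets = rng.normal(0.0, 1.0, size=(len(SHAPE_LETTERS), len(ATOMS)))
    return base, offsets


def generate(
    cfg: SynthConfig, torsion_table: Optional[TorsionRegionTable] = None
) -> list[tuple[ShiftRecordSeq, str, list[tuple[float, float]]]]:
    """Sample a corpus of (shift record, shape string, torsion list) triples.

    Deterministic given ``cfg.seed``.  Torsions are drawn uniformly inside
    the core rectangle of each state (half-degree inset from the boundary),
    so re-assigning shapes from the torsions reproduces the shape string.
    """
    cfg.validate()
    table = torsion_table or default_torsion_table()
    base, offsets = _structure_params()
    trans = cfg.transition_matrix()
    pi = np.array([cfg.stationary.get(s, 0.0) for s in SHAPE_LETTERS])
    rng = np.random.default_rng(cfg.seed)
    non_gly = [a for a in AMINO_ACIDS if a != "G"]

    out = []
    for chain in range(cfg.n_chains):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        states = np.empty(L, dtype=int)
        states[0] = rng.choice(8, p=pi)
        for t in range(1, L):
            states[t] = rng.choice(8, p=trans[states[t - 1]])
        shape = "".join(SHAPE_LETTERS[i] for i in states)

        residues: list[Residue] = []
        torsions: list[tuple[float, float]] = []
        for t, si in enumerate(states):
            letter = SHAPE_LETTERS[si]
            aa = "G" if letter == "G" else non_gly[rng.integers(len(non_gly))]
            shifts: dict[str, float | None] = {}
            for ai, atom in enumerate(ATOMS):
                mean, sd = base[(aa, atom)]
                mean = mean + cfg.separation * sd * offsets[si, ai]
                if cfg.student_t_df is not None:
                    value = mean + sd * rng.standard_t(cfg.student_t_df)
                else:
                    value = rng.normal(mean, sd)
                if cfg.missingness > 0 and rng.random() < cfg.missingness:
                    shifts[atom] = VACANT
                else:
                    shifts[atom] = round(float(value), 3)
            residues.append(Residue(index=t + 1, aa=aa, shifts=shifts))
            rect = table.core_rectangle(letter)
            phi = rng.uniform(rect.phi_lo + 0.5, rect.phi_hi - 0.5)
            psi = rng.uniform(rect.psi_lo + 0.5, rect.psi_hi - 0.5)
            torsions.append((float(phi), float(psi)))
        rec = ShiftRecordSeq(chain_id=f"synth_{chain + 1:04d}", residues=residues)
        out.append((rec, shape, torsions))
    return out


def generate_split(
    cfg: SynthConfig, train_frac: float, seed: int
) -> tuple[list, list]:
    """Disjoint chain-level train/test split of a generated corpus.

    The corpus itself is generated with ``cfg.seed``; ``seed`` controls
    only the split permutation, so the same chains can be re-split.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    corpus = generate(cfg)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(train_frac * len(corpus)))
    train = [corpus[i] for i in sorted(order[:n_train])]
    test = [corpus[i] for i in sorted(order[n_train:])]
    return train, test


def write_corpus(corpus, out_dir) -> None:
    """Write a generated corpus in the formats the toolkit reads.

    One SHIFTY file per chain, a FASTA-like ``shapes.txt`` of shape
    strings, and a ``torsions.tsv`` of per-residue phi/psi.
    """
    from pathlib import Path

    from .shifty import write_fasta, write_shifty

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shapes = []
    with open(out / "torsions.tsv", "w") as tors:
        tors.write("chain\tpos\tphi\tpsi\n")
        for rec, shape, torsions in corpus:
            write_shifty(rec, out / f"{rec.chain_id}.shifty")
            shapes.append((rec.chain_id, shape))
            for i, (phi, psi) in enumerate(torsions, start=1):
                tors.write(f"{rec.chain_id}\t{i}\t{phi:.3f}\t{psi:.3f}\n")
    write_fasta(shapes, out / "shapes.txt")


def read_corpus(in_dir) -> list[tuple[ShiftRecordSeq, str]]:
    """Read back (shift record, shape string) pairs written by :func:`write_corpus`."""
    from pathlib import Path

    from .shifty import read_fasta, read_shifty

    in_path = Path(in_dir)
    shapes = dict(read_fasta(in_path / "shapes.txt"))
    out = []
    for chain_id in sorted(shapes):
        rec = read_shifty(in_path / f"{chain_id}.shifty")
        out.append((rec, shapes[chain_id]))
    return out
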