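"""Hallmark-pattern mining and per-residue shape-string profiles.

A *hallmark pattern* is a short (2-4 residue) amino-acid substring whose
occurrences across a structure-annotated corpus carry statistically
conserved shape letters: at a pattern position with support n, modal shape
letter count k and corpus background frequency p0 of that letter, the
one-sided binomial upper-tail p-value P[X >= k], X ~ Binomial(n, p0), is
small.  Patterns capture remote homology that sequence similarity alone
misses.

A *shape profile* (8-box vector per query residue) tallies the shape
letters of similarity hits: primary hits come from a pluggable hit source
(the built-in source is an exact k-mer matcher standing in for a database
search at desk scale), and uncovered stretches are rescued by scanning the
hallmark library, whose conserved letters contribute with the same unit
weight.  Box order is the canonical ``S R U V K A T G``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .alphabets import SHAPE_LETTERS, UNDEFINED, VACANCY_LETTER
from .preprocess import alphabetize

Corpus = Sequence[tuple[str, str]]  # (amino-acid sequence, shape string) pairs

PATTERN_LENGTHS = (2, 3, 4)


@dataclass(frozen=True)
class HallmarkPattern:
    """A mined pattern with per-position modal letters and p-values.

    ``letters[i]`` is the modal shape letter at position ``i`` (``None`` if
    every occurrence is undefined there); ``p_values[i]`` its binomial
    upper-tail p-value; ``conserved[i]`` whether it met the significance
    cutoff used at mining time.
    """

    pattern: str
    letters: tuple[Optional[str], ...]
    p_values: tuple[float, ...]
    conserved: tuple[bool, ...]
    support: int

    def conserved_letters(self) -> tuple[Optional[str], ...]:
        return tuple(
            l if c else None for l, c in zip(self.letters, self.conserved)
        )


def background_frequencies(corpus: Corpus) -> dict[str, float]:
    """Shape-letter frequencies over all defined (non-X) corpus positions."""
    counts = Counter()
    for _, shape in corpus:
        for c in shape:
            if c != UNDEFINED:
                counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("corpus has no defined shape positions")
    return {c: counts.get(c, 0) / total for c in SHAPE_LETTERS}


def binomial_tail(k: int, n: int, p0: float) -> float:
    """One-sided upper-tail P[X >= k] for X ~ Binomial(n, p0)."""
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


def mine_patterns(
    corpus: Corpus,
    min_support: int = 100,
    max_p: float = 0.01,
    lengths: tuple[int, ...] = PATTERN_LENGTHS,
) -> list[HallmarkPattern]:
    """Traversal search for conserved sequence/shape patterns.

    Enumerates every length-2..4 substring of every corpus sequence,
    keeps those with corpus-wide occurrence count >= ``min_support``, and
    scores each position's modal shape letter with the binomial upper tail
    against the corpus background frequency of that letter.  A pattern is
    retained when at least one position is conserved at ``max_p``.
    Occurrence counting includes overlapping and repeated occurrences
    within one sequence.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    bg = background_frequencies(corpus)
    occurrences: dict[str, list[str]] = defaultdict(list)
    for seq, shape in corpus:
        if len(seq) != len(shape):
            raise ValueError("sequence/shape length mismatch in corpus")
        for width in lengths:
            for start in range(len(seq) - width + 1):
                occurrences[seq[start:start + width]].append(shape[start:start + width])

    results: list[HallmarkPattern] = []
    for pattern in sorted(occurrences):
        shapes = occurrences[pattern]
        support = len(shapes)
        if support < min_support:
            continue
        letters: list[Optional[str]] = []
        pvals: list[float] = []
        flags: list[bool] = []
        for pos in range(len(pattern)):
            col = Counter(sh[pos] for sh in shapes if sh[pos] != UNDEFINED)
            if not col:
                letters.append(None)
                pvals.append(1.0)
                flags.append(False)
                continue
            # deterministic tie-break: highest count, then box order
            modal, k = max(
                col.items(), key=lambda kv: (kv[1], -SHAPE_LETTERS.index(kv[0]))
            )
            p = binomial_tail(k, support, bg[modal])
            letters.append(modal)
            pvals.append(p)
            flags.append(p <= max_p)
        if any(flags):
            results.append(
                HallmarkPattern(
                    pattern=pattern,
                    letters=tuple(letters),
                    p_values=tuple(pvals),
                    conserved=tuple(flags),
                    support=support,
                )
            )
    return results


class Hit(NamedTuple):
    """One unit of shape evidence at a query position from one subject."""

    query_pos: int
    shape_letter: str
    subject: int


class HitSource:
    """Contract for producers of per-position shape evidence.

    Implementations return a list of :class:`Hit` for a query sequence.
    The built-in reference implementation is :class:`KmerHitSource`; an
    adapter for externally produced tabular hits is
    :class:`TabularHitSource`.
    """

    def hits(self, query: str) -> list[Hit]:  # pragma: no cover - interface
        raise NotImplementedError


class KmerHitSource(HitSource):
    """Exact k-mer matcher against an annotated corpus (default k=6).

    A desk-scale stand-in for a database similarity search: every exact
    k-mer shared between query and corpus contributes the matched corpus
    residues' shape letters, one hit per covered query position per match.
    Undefined (X) corpus positions contribute nothing.
    """

    def __init__(self, corpus: Corpus, k: int = 6, exclude: Optional[int] = None):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.corpus = list(corpus)
        self.k = k
        self.exclude = exclude
        self._index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, (seq, _) in enumerate(self.corpus):
            for p in range(len(seq) - k + 1):
                self._index[seq[p:p + k]].append((si, p))

    def hits(self, query: str) -> list[Hit]:
        out: list[Hit] = []
        k = self.k
        for q in range(len(query) - k + 1):
            for si, p in self._index.get(query[q:q + k], ()):
                if si == self.exclude:
                    continue
                shape = self.corpus[si][1]
                for off in range(k):
                    letter = shape[p + off]
                    if letter != UNDEFINED:
                        out.append(Hit(q + off, letter, si))
        return out


class TabularHitSource(HitSource):
    """Adapter for externally produced hits: rows of (query_pos, letter, subject)."""

    def __init__(self, rows: Iterable[tuple[int, str, int]]):
        self._hits = [Hit(int(q), s, int(sub)) for q, s, sub in rows]

    @classmethod
    def from_tsv(cls, path) -> "TabularHitSource":
        """Load hits from a TSV with columns query_pos, shape_letter, subject."""
        rows = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["query_pos", "shape_letter", "subject"]:
                raise ValueError(f"{path}: unexpected hit-table columns {header}")
            for line in fh:
                q, letter, subject = line.strip().split("\t")
                if letter not in SHAPE_LETTERS:
                    raise ValueError(f"{path}: bad shape letter {letter!r}")
                rows.append((int(q), letter, int(subject)))
        return cls(rows)

    def hits(self, query: str) -> list[Hit]:
        bad = [h for h in self._hits if not 0 <= h.query_pos < len(query)]
        if bad:
            raise ValueError(f"hit positions outside query: {bad[:3]}")
        return list(self._hits)


def kmer_hits(query: str, corpus: Corpus, k: int = 6) -> list[Hit]:
    """Functional form of :class:`KmerHitSource` for one-off queries."""
    return KmerHitSource(corpus, k=k).hits(query)


def build_profile(
    query: str,
    hits: Sequence[Hit],
    patterns: Sequence[HallmarkPattern] = (),
    top_n: int = 10,
    flank: int = 5,
) -> np.ndarray:
    """Assemble the per-residue 8-box shape profile for ``query``.

    Primary hits from the ``top_n`` best subjects (most covered positions;
    ties broken by subject id) are tallied into the boxes.  Positions left
    without any primary evidence are scanned against the hallmark library:
    each pattern occurrence contributes its conserved letters (unit weight,
    same as a primary hit) at still-uncovered positions.  ``flank`` records
    the +/- context width reserved for secondary hit sources that anchor
    pattern matches in a corpus; the built-in scan contributes the library's
    conserved letters directly.

    Returns an (L, 8) integer array in ``S R U V K A T G`` box order;
    positions with no evidence are all-zero rows.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    boxes = np.zeros((len(query), len(SHAPE_LETTERS)), dtype=int)

    coverage = Counter(h.subject for h in hits)
    top_subjects = {
        s for s, _ in sorted(coverage.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    }
    for h in hits:
        if h.subject in top_subjects:
            boxes[h.query_pos, SHAPE_LETTERS.index(h.shape_letter)] += 1

    uncovered = boxes.sum(axis=1) == 0
    if patterns and uncovered.any():
        for pat in patterns:
            width = len(pat.pattern)
            start = query.find(pat.pattern)
            while start != -1:
                for off, letter in enumerate(pat.conserved_letters()):
                    pos = start + off
                    if letter is not None and uncovered[pos]:
                        boxes[pos, SHAPE_LETTERS.index(letter)] += 1
                start = query.find(pat.pattern, start + 1)
    return boxes


def alphabetize_profile(profile: np.ndarray) -> list[str]:
    """Discretize each position's box fractions into eight bin letters.

    Each box count is divided by the position total and binned with the
    same ten-letter scheme used for chemical shifts; a position with no
    evidence emits eight vacancy letters.
    """
    profile = np.asarray(profile)
    if profile.ndim != 2 or profile.shape[1] != len(SHAPE_LETTERS):
        raise ValueError("profile must be (L, 8)")
    out: list[str] = []
    for row in profile:
        total = row.sum()
        if total == 0:
            out.append(VACANCY_LETTER * len(SHAPE_LETTERS))
        else:
            out.append("".join(alphabetize(c / total) for c in row))
    return out


# -- hallmark library serialization (TSV) ----------------------------------

_LIB_HEADER = ["pattern", "length", "position", "letter", "support", "p_value"]


def write_pattern_library(patterns: Sequence[HallmarkPattern], path) -> None:
    """Write conserved positions of a pattern library as TSV."""
    with open(path, "w") as fh:
        fh.write("#shapestring-hallmarks\tv1\n")
        fh.write("\t".join(_LIB_HEADER) + "\n")
        for pat in patterns:
            for pos, (letter, conserved) in enumerate(zip(pat.letters, pat.conserved)):
                if conserved:
                    fh.write(
                        f"{pat.pattern}\t{len(pat.pattern)}\t{pos}\t{letter}\t"
                        f"{pat.support}\t{pat.p_values[pos]!r}\n"
                    )


def read_pattern_library(path) -> list[HallmarkPattern]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#shapestring-hallmarks"):
            raise ValueError(f"{path}: not a hallmark-library file")
        header = fh.readline().strip().split("\t")
        if header != _LIB_HEADER:
            raise ValueError(f"{path}: unexpected columns")
        for line in fh:
            pattern, length, pos, letter, support, p = line.strip().split("\t")
            entry = rows.setdefault(
                pattern, {"length": int(length), "support": int(support), "cols": {}}
            )
            entry["cols"][int(pos)] = (letter, float(p))
    out: list[HallmarkPattern] = []
    for pattern in sorted(rows):
        entry = rows[pattern]
        width = entry["length"]
        letters = [None] * width
        pvals = [1.0] * width
        flags = [False] * width
        for pos, (letter, p) in entry["cols"].items():
            letters[pos] = letter
            pvals[pos] = p
            flags[pos] = True
        out.append(
            HallmarkPattern(
                pattern=pattern,
                letters=tuple(letters),
                p_values=tuple(pvals),
                conserved=tuple(flags),
                support=entry["support"],
            )
        )
    return out
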