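"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by the most literal method available
(explicit loops, exhaustive enumeration, exact rational arithmetic) and is
kept free of any code path from the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

SHAPE_LETTERS = "SRUVKATG"


def naive_accuracy(pred: str, ref: str, states: str) -> tuple[dict, float]:
    """Per-position accuracy by explicit counting; reference X excluded."""
    correct = {s: 0 for s in states}
    total = {s: 0 for s in states}
    for i in range(len(ref)):
        r = ref[i]
        if r == "X":
            continue
        total[r] += 1
        if pred[i] == r:
            correct[r] += 1
    per = {s: (100.0 * correct[s] / total[s] if total[s] else None) for s in states}
    denom = sum(total.values())
    overall = 100.0 * sum(correct.values()) / denom if denom else float("nan")
    return per, overall


def naive_segments(s: str, state: str) -> list[tuple[int, int]]:
    """Maximal runs of ``state`` found by scanning indices one at a time."""
    segs = []
    i = 0
    while i < len(s):
        if s[i] == state:
            j = i
            while j < len(s) and s[j] == state:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def naive_sov(pred: str, ref: str, states: str) -> tuple[dict, float]:
    """Segment-overlap score by explicit pairwise segment enumeration.

    Contract shared with the implementation under test: reference-X
    positions are excluded, splitting segments on both strings.
    """
    pred = "".join("X" if r == "X" else p for p, r in zip(pred, ref))
    per = {}
    num_all = 0.0
    den_all = 0.0
    for state in states:
        num = 0.0
        den = 0.0
        for (a0, a1) in naive_segments(ref, state):
            len1 = a1 - a0
            partners = []
            for (b0, b1) in naive_segments(pred, state):
                ov = min(a1, b1) - max(a0, b0)
                if ov > 0:
                    partners.append((b0, b1, ov))
            if not partners:
                den += len1
                continue
            for (b0, b1, minov) in partners:
                len2 = b1 - b0
                maxov = max(a1, b1) - min(a0, b0)
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                num += len1 * (minov + delta) / maxov
                den += len1
        per[state] = 100.0 * num / den if den else None
        num_all += num
        den_all += den
    return per, (100.0 * num_all / den_all if den_all else float("nan"))


def exact_binomial_tail(k: int, n: int, p0: Fraction) -> Fraction:
    """P[X >= k] for X ~ Binomial(n, p0) in exact rational arithmetic."""
    if k <= 0:
        return Fraction(1)
    q = 1 - p0
    return sum(
        Fraction(comb(n, j)) * p0**j * q ** (n - j) for j in range(k, n + 1)
    )


def brute_force_substrings(corpus, lengths=(2, 3, 4)):
    """All substrings with their per-occurrence shape windows, by double loop."""
    out: dict[str, list[str]] = {}
    for seq, shape in corpus:
        for start in range(len(seq)):
            for width in lengths:
                if start + width <= len(seq):
                    out.setdefault(seq[start:start + width], []).append(
                        shape[start:start + width]
                    )
    return out


def brute_force_kmer_hits(query: str, corpus, k: int):
    """Hit multiset by comparing every query window to every corpus window."""
    hits = []
    for q in range(len(query) - k + 1):
        window = query[q:q + k]
        for si, (seq, shape) in enumerate(corpus):
            for p in range(len(seq) - k + 1):
                if seq[p:p + k] == window:
                    for off in range(k):
                        if shape[p + off] != "X":
                            hits.append((q + off, shape[p + off], si))
    return hits


def enumerate_paths(L: int, n_labels: int = 8) -> np.ndarray:
    """All label paths of length L as an (n_labels**L, L) index array."""
    idx = np.arange(n_labels**L)
    return np.array(np.unravel_index(idx, (n_labels,) * L)).T


def brute_force_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log sum over all paths of exp(score) by full enumeration."""
    L, K = emissions.shape
    paths = enumerate_paths(L, K)
    scores = emissions[np.arange(L), paths].sum(axis=1)
    if L > 1:
        scores = scores + transitions[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    m = scores.max()
    return float(m + np.log(np.exp(scores - m).sum()))


def brute_force_viterbi(emissions: np.ndarray, transitions: np.ndarray) -> tuple[float, np.ndarray]:
    """(max path score, argmax path) by full enumeration."""
    L, K = emissions.shape
    paths = enumerate_paths(L, K)
    scores = emissions[np.arange(L), paths].sum(axis=1)
    if L > 1:
        scores = scores + transitions[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    best = int(np.argmax(scores))
    return float(scores[best]), paths[best]
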