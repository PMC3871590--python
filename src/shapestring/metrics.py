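"""Accuracy (S8/S3), segment-overlap (SOV) scoring and bootstrap intervals.

S8 is per-residue accuracy over the 8 shape states, S3 the same after
collapsing to sheet-like/helix-like/turn-like.  Both are residue-weighted:
total = 100 * sum_i n_i / sum_i m_i with n_i the correctly predicted and
m_i the total residues of state i; positions where the reference is X are
excluded.

SOV follows the 1999 segment-overlap convention: for each state i and each
pair of overlapping reference/predicted segments (s1, s2),

    contribution = len(s1) * (minov + delta) / maxov,
    delta = min(maxov - minov, minov, floor(len(s1)/2), floor(len(s2)/2)),

with normalization N(i) counting len(s1) once per overlapping pair plus
len(s1) for reference segments with no overlapping partner.  The delta
allowance forgives small boundary shifts, so SOV rewards getting segments
right rather than individual residues.  X splits segments and is excluded
from the normalization.

Bootstrap: a fraction of the evaluation targets (chains) is resampled
without replacement many times; the metric is recomputed over the pooled
residues of each sample and the mean and standard deviation of the
resulting distribution are reported (the +/- values of the tables this
module mirrors).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import groupby
from typing import Callable, Optional, Sequence

import numpy as np

from .alphabets import SHAPE_LETTERS, UNDEFINED
from .shape import map8to3

THREE_STATES = "SHT"

Pair = tuple[str, str]  # (predicted, reference)


class MetricError(ValueError):
    pass


def _check_pair(pred: str, ref: str) -> None:
    if len(pred) != len(ref):
        raise MetricError(f"length mismatch: {len(pred)} vs {len(ref)}")


def accuracy(pred: str, ref: str, states: str = SHAPE_LETTERS) -> tuple[dict, float]:
    """Per-class and total percent accuracy; reference-X positions excluded.

    Returns ``(per_class, total)`` with ``per_class[state] = 100 n_i / m_i``
    (``None`` for states absent from the reference).
    """
    _check_pair(pred, ref)
    n = {s: 0 for s in states}
    m = {s: 0 for s in states}
    for p, r in zip(pred, ref):
        if r == UNDEFINED:
            continue
        if r not in m:
            raise MetricError(f"reference letter {r!r} outside states {states!r}")
        m[r] += 1
        if p == r:
            n[r] += 1
    per_class = {s: (100.0 * n[s] / m[s] if m[s] else None) for s in states}
    total_m = sum(m.values())
    total = 100.0 * sum(n.values()) / total_m if total_m else float("nan")
    return per_class, total


def _segments(s: str, state: str) -> list[tuple[int, int]]:
    """Maximal runs of ``state`` as half-open (start, stop); X splits runs."""
    out = []
    pos = 0
    for key, grp in groupby(s):
        width = sum(1 for _ in grp)
        if key == state:
            out.append((pos, pos + width))
        pos += width
    return out


def sov(pred: str, ref: str, states: str = SHAPE_LETTERS) -> tuple[dict, float]:
    """Segment-overlap score per state and in total (percent).

    Positions where the reference is X are excluded: they split segments on
    both strings and never enter the normalization.  States absent from the
    reference report ``None``.
    """
    _check_pair(pred, ref)
    # mask the prediction wherever the reference is undefined
    pred = "".join(UNDEFINED if r == UNDEFINED else p for p, r in zip(pred, ref))
    per_state: dict[str, Optional[float]] = {}
    grand_sum = 0.0
    grand_norm = 0.0
    for state in states:
        ref_segs = _segments(ref, state)
        pred_segs = _segments(pred, state)
        total = 0.0
        norm = 0.0
        for a0, a1 in ref_segs:
            len1 = a1 - a0
            overlapping = [
                (b0, b1) for b0, b1 in pred_segs if min(a1, b1) > max(a0, b0)
            ]
            if not overlapping:
                norm += len1
                continue
            for b0, b1 in overlapping:
                len2 = b1 - b0
                minov = min(a1, b1) - max(a0, b0)
                maxov = max(a1, b1) - min(a0, b0)
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                total += len1 * (minov + delta) / maxov
                norm += len1
        per_state[state] = 100.0 * total / norm if norm > 0 else None
        grand_sum += total
        grand_norm += norm
    grand = 100.0 * grand_sum / grand_norm if grand_norm > 0 else float("nan")
    return per_state, grand


@dataclass
class EvalReport:
    """Totals and per-class breakdown for one prediction/reference pool."""

    s8: float
    sov8: float
    s3: float
    sov3: float
    acc8_per_class: dict = field(default_factory=dict)
    sov8_per_class: dict = field(default_factory=dict)
    acc3_per_class: dict = field(default_factory=dict)
    sov3_per_class: dict = field(default_factory=dict)
    n_residues: int = 0
    bootstrap: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_table(self) -> str:
        """Human-readable per-state table (accuracy / SOV, 8- and 3-state)."""
        lines = ["state\taccuracy\tSOV\tstate3\taccuracy3\tSOV3"]

        def fmt(v):
            return "-" if v is None else f"{v:.2f}"

        from .alphabets import SHAPE_8_TO_3

        for s in SHAPE_LETTERS:
            s3 = SHAPE_8_TO_3[s]
            lines.append(
                f"{s}\t{fmt(self.acc8_per_class.get(s))}\t{fmt(self.sov8_per_class.get(s))}"
                f"\t{s3}\t{fmt(self.acc3_per_class.get(s3))}\t{fmt(self.sov3_per_class.get(s3))}"
            )
        lines.append(
            f"Total\t{self.s8:.2f}\t{self.sov8:.2f}\t\t{self.s3:.2f}\t{self.sov3:.2f}"
        )
        return "\n".join(lines)


def evaluate(pred: str, ref: str) -> EvalReport:
    """Full report for one pair: S8/SOV8 plus the 3-state collapse."""
    acc8, s8 = accuracy(pred, ref)
    sov8_pc, sov8 = sov(pred, ref)
    pred3, ref3 = map8to3(pred), map8to3(ref)
    acc3, s3 = accuracy(pred3, ref3, states=THREE_STATES)
    sov3_pc, sov3 = sov(pred3, ref3, states=THREE_STATES)
    n = sum(1 for c in ref if c != UNDEFINED)
    return EvalReport(
        s8=s8, sov8=sov8, s3=s3, sov3=sov3,
        acc8_per_class=acc8, sov8_per_class=sov8_pc,
        acc3_per_class=acc3, sov3_per_class=sov3_pc,
        n_residues=n,
    )


def pool(pairs: Sequence[Pair]) -> Pair:
    """Join chains with an X separator so segments never merge across chains."""
    for p, r in pairs:
        _check_pair(p, r)
    return UNDEFINED.join(p for p, _ in pairs), UNDEFINED.join(r for _, r in pairs)


def pooled_accuracy(pairs: Sequence[Pair], states: str = SHAPE_LETTERS) -> float:
    return accuracy(*pool(pairs), states=states)[1]


def pooled_sov(pairs: Sequence[Pair], states: str = SHAPE_LETTERS) -> float:
    return sov(*pool(pairs), states=states)[1]


def evaluate_corpus(
    pairs: Sequence[Pair],
    bootstrap_frac: float = 0.8,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Pooled report over many chains with bootstrap mean +/- SE per total."""
    pred, ref = pool(pairs)
    report = evaluate(pred, ref)
    if len(pairs) >= 2 and bootstrap_reps > 0:
        metrics: dict[str, Callable[[Sequence[Pair]], float]] = {
            "s8": pooled_accuracy,
            "sov8": pooled_sov,
            "s3": lambda ps: pooled_accuracy(_collapse(ps), states=THREE_STATES),
            "sov3": lambda ps: pooled_sov(_collapse(ps), states=THREE_STATES),
        }
        for name, fn in metrics.items():
            mean, se = bootstrap(
                fn, pairs, frac=bootstrap_frac, reps=bootstrap_reps, seed=seed
            )
            report.bootstrap[name] = {"mean": mean, "se": se}
    return report


def _collapse(pairs: Sequence[Pair]) -> list[Pair]:
    return [(map8to3(p), map8to3(r)) for p, r in pairs]


def bootstrap(
    metric: Callable[[Sequence[Pair]], float],
    targets: Sequence[Pair],
    frac: float = 0.8,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Resample ``frac`` of the targets (without replacement) ``reps`` times.

    Returns the mean and standard deviation (reported as the standard
    error) of the metric over the resampled pools.  Deterministic given
    ``seed``.
    """
    n = len(targets)
    if n < 2:
        raise MetricError("bootstrap needs at least 2 targets")
    if not 0 < frac <= 1:
        raise MetricError("frac must be in (0, 1]")
    m = math.ceil(frac * n)
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        values[r] = metric([targets[i] for i in idx])
    return float(values.mean()), float(values.std(ddof=1))
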