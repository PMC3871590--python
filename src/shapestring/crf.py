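"""Linear-chain conditional random field over windowed categorical features.

Each residue carries a fixed number of categorical base features drawn from
the 11-letter feature alphabet (six binned chemical shifts and/or eight
binned profile boxes).  Window expansion replicates every base feature at
every offset in ``[-window, +window]``; offsets falling outside the chain
emit a dedicated boundary token.  The model scores a label sequence y by

    score(y) = sum_t  w_obs[slot, letter(t, slot), y_t]  +  sum_t  w_trans[y_{t-1}, y_t]

and is trained by maximizing the L2-penalized conditional log-likelihood
with L-BFGS; gradients come from forward-backward marginals.  Decoding is
Viterbi; per-position marginals come from forward-backward.  Everything is
deterministic: the objective is smooth and convex and the optimizer is
started from zero weights.

Sequences are trained in a padded batch so the forward/backward recursions
loop over time steps, not over chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, sparse

from .alphabets import FEATURE_LETTERS, SHAPE_LETTERS, UNDEFINED

BOUNDARY_TOKEN = "#"
_LETTERS = FEATURE_LETTERS + BOUNDARY_TOKEN  # 11 feature letters + boundary
_LETTER_INDEX = {c: i for i, c in enumerate(_LETTERS)}
N_LETTER_VALUES = len(_LETTERS)  # 12
N_LABELS = len(SHAPE_LETTERS)  # 8


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSequence:
    """Per-residue categorical features with window expansion.

    ``letters[t]`` is a string of ``n_base`` letters from the 11-letter
    feature alphabet for residue ``t``; ``window`` gives the offset range
    used when the sequence is presented to a CRF.
    """

    letters: tuple[str, ...]
    window: int

    def __post_init__(self) -> None:
        if self.window < 0:
            raise FeatureError("window must be >= 0")
        if self.letters:
            n = len(self.letters[0])
            for row in self.letters:
                if len(row) != n:
                    raise FeatureError("ragged feature rows")
                bad = set(row) - set(FEATURE_LETTERS)
                if bad:
                    raise FeatureError(f"letters outside feature alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def n_base(self) -> int:
        return len(self.letters[0]) if self.letters else 0

    @property
    def n_observations(self) -> int:
        """Observation features per position after window expansion."""
        return self.n_base * (2 * self.window + 1)

    def observation_indices(self) -> np.ndarray:
        """(L, n_observations) letter-value indices, boundary token padded."""
        L, nb, w = len(self), self.n_base, self.window
        base = np.full((L, nb), 0, dtype=np.int64)
        for t, row in enumerate(self.letters):
            for f, c in enumerate(row):
                base[t, f] = _LETTER_INDEX[c]
        offsets = range(-w, w + 1)
        cols = []
        boundary = np.full((1, nb), _LETTER_INDEX[BOUNDARY_TOKEN], dtype=np.int64)
        for off in offsets:
            shifted = np.full((L, nb), _LETTER_INDEX[BOUNDARY_TOKEN], dtype=np.int64)
            lo, hi = max(0, -off), min(L, L - off)
            if hi > lo:
                shifted[lo:hi] = base[lo + off:hi + off]
            cols.append(shifted)
        return np.concatenate(cols, axis=1) if cols else np.zeros((L, 0), np.int64)

    def slice(self, start: int, stop: int) -> "FeatureSequence":
        return FeatureSequence(letters=self.letters[start:stop], window=self.window)


def featurize(
    shift_letters: Optional[Sequence[str]],
    profile_letters: Optional[Sequence[str]],
    window: int = 3,
) -> FeatureSequence:
    """Concatenate per-residue shift letters (6) and profile letters (8).

    Either family may be omitted (``None``) for ablation runs; at least one
    must be present and lengths must agree.
    """
    if shift_letters is None and profile_letters is None:
        raise FeatureError("at least one feature family required")
    if (
        shift_letters is not None
        and profile_letters is not None
        and len(shift_letters) != len(profile_letters)
    ):
        raise FeatureError("shift/profile feature length mismatch")
    n = len(shift_letters) if shift_letters is not None else len(profile_letters)
    rows = []
    for t in range(n):
        row = ""
        if shift_letters is not None:
            row += shift_letters[t]
        if profile_letters is not None:
            row += profile_letters[t]
        rows.append(row)
    return FeatureSequence(letters=tuple(rows), window=window)


def split_at_undefined(
    feats: FeatureSequence, labels: str
) -> list[tuple[FeatureSequence, str]]:
    """Split a labeled sequence at runs of ``X`` (no-shape positions).

    X is missing supervision, not a learnable class, so training sequences
    are cut at X runs and the fragments trained independently.
    """
    if len(feats) != len(labels):
        raise FeatureError("feature/label length mismatch")
    out = []
    start = None
    for i, c in enumerate(labels + UNDEFINED):
        if c == UNDEFINED:
            if start is not None:
                out.append((feats.slice(start, i), labels[start:i]))
                start = None
        elif start is None:
            start = i
    return out


def write_feature_columns(feats: FeatureSequence, labels: Optional[str], path) -> None:
    """Dump base features as column text (one residue per row, label last).

    The layout matches the classic CRF-toolkit convention — one column per
    base feature plus an optional final label column — for interoperability
    with external CRF engines.
    """
    if labels is not None and len(labels) != len(feats):
        raise FeatureError("feature/label length mismatch")
    with open(path, "w") as fh:
        for t, row in enumerate(feats.letters):
            cols = list(row)
            if labels is not None:
                cols.append(labels[t])
            fh.write("\t".join(cols) + "\n")


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)


class ShapeCRF:
    """Linear-chain CRF labeling residues with the 8 shape letters.

    Parameters
    ----------
    window : half-width of the observation window (offsets -window..+window).
    l2 : L2 penalty coefficient on all weights (0.5 * l2 * ||w||^2).
    max_iter : L-BFGS iteration budget.
    seed : stored for provenance; training is deterministic regardless
        (convex objective, zero initialization).
    """

    def __init__(
        self,
        window: int = 3,
        l2: float = 1.0,
        max_iter: int = 200,
        seed: int = 0,
    ):
        if l2 < 0:
            raise ValueError("l2 must be >= 0")
        self.window = window
        self.l2 = float(l2)
        self.max_iter = int(max_iter)
        self.seed = int(seed)
        self.n_base: Optional[int] = None
        self.w_obs: Optional[np.ndarray] = None  # (n_slots * 12, 8)
        self.w_trans: Optional[np.ndarray] = None  # (8, 8)
        self.final_objective_: Optional[float] = None
        self.objective_trace_: list[float] = []
        self.n_iter_: Optional[int] = None

    # -- geometry -----------------------------------------------------------

    @property
    def n_slots(self) -> int:
        assert self.n_base is not None
        return self.n_base * (2 * self.window + 1)

    @property
    def n_flat(self) -> int:
        return self.n_slots * N_LETTER_VALUES

    def _check_compatible(self, feats: FeatureSequence) -> None:
        if self.n_base is None:
            raise FeatureError("model is untrained")
        if feats.window != self.window or feats.n_base != self.n_base:
            raise FeatureError(
                f"feature template mismatch: model (window={self.window}, "
                f"n_base={self.n_base}) vs input (window={feats.window}, "
                f"n_base={feats.n_base})"
            )

    def _flat_indices(self, feats: FeatureSequence) -> np.ndarray:
        obs = feats.observation_indices()  # (L, n_slots)
        return obs + np.arange(self.n_slots, dtype=np.int64)[None, :] * N_LETTER_VALUES

    def _emissions(self, feats: FeatureSequence) -> np.ndarray:
        self._check_compatible(feats)
        flat = self._flat_indices(feats)
        return self.w_obs[flat].sum(axis=1)  # (L, 8)

    # -- training -----------------------------------------------------------

    def fit(self, corpus: Sequence[tuple[FeatureSequence, str]]) -> "ShapeCRF":
        """Train on (features, shape-string) pairs; X runs are split out."""
        pieces: list[tuple[FeatureSequence, str]] = []
        import logging

        log = logging.getLogger(__name__)
        for feats, labels in corpus:
            subs = split_at_undefined(feats, labels)
            if not subs:
                log.warning("skipping all-undefined training sequence")
            pieces.extend(subs)
        if not pieces:
            raise ValueError("no trainable sequences after removing undefined runs")
        windows = {f.window for f, _ in pieces}
        bases = {f.n_base for f, _ in pieces}
        if len(windows) != 1 or len(bases) != 1:
            raise FeatureError("inconsistent feature templates in corpus")
        if windows != {self.window}:
            raise FeatureError("corpus window differs from model window")
        self.n_base = bases.pop()

        lens = np.array([len(f) for f, _ in pieces], dtype=np.int64)
        P = int(lens.sum())
        Lmax = int(lens.max())
        N = len(pieces)

        flat_rows = np.concatenate([self._flat_indices(f) for f, _ in pieces], axis=0)
        y = np.concatenate(
            [[SHAPE_LETTERS.index(c) for c in lab] for _, lab in pieces]
        ).astype(np.int64)

        # sparse one-hot design matrix: (P, n_flat), n_slots ones per row
        rows = np.repeat(np.arange(P, dtype=np.int64), self.n_slots)
        X = sparse.csr_matrix(
            (np.ones(P * self.n_slots), (rows, flat_rows.ravel())),
            shape=(P, self.n_flat),
        )

        # padded-batch bookkeeping
        starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
        pad_idx = np.zeros((N, Lmax), dtype=np.int64)
        mask = np.zeros((N, Lmax), dtype=bool)
        for i, (s, l) in enumerate(zip(starts, lens)):
            pad_idx[i, :l] = np.arange(s, s + l)
            mask[i, :l] = True

        # empirical statistics
        onehot = np.zeros((P, N_LABELS))
        onehot[np.arange(P), y] = 1.0
        emp_obs = X.T @ onehot  # (n_flat, 8)
        emp_trans = np.zeros((N_LABELS, N_LABELS))
        for s, l in zip(starts, lens):
            labs = y[s:s + l]
            np.add.at(emp_trans, (labs[:-1], labs[1:]), 1.0)

        n_obs_params = self.n_flat * N_LABELS
        trace: list[float] = []

        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            w_obs = theta[:n_obs_params].reshape(self.n_flat, N_LABELS)
            w_trans = theta[n_obs_params:].reshape(N_LABELS, N_LABELS)
            E = X @ w_obs  # (P, 8)
            E_pad = E[pad_idx]  # (N, Lmax, 8); garbage where mask False
            logZ, node_marg, pair_sum = _batched_forward_backward(
                E_pad, w_trans, mask, lens
            )
            gold_score = float(E[np.arange(P), y].sum() + (emp_trans * w_trans).sum())
            nll = float(logZ.sum()) - gold_score
            nll += 0.5 * self.l2 * float(theta @ theta)

            grad_obs = X.T @ (_scatter_to_positions(node_marg, mask, pad_idx, P) - onehot)
            grad_trans = pair_sum - emp_trans
            grad = np.concatenate([grad_obs.ravel(), grad_trans.ravel()])
            grad += self.l2 * theta
            trace.append(nll)
            return nll, grad

        theta0 = np.zeros(n_obs_params + N_LABELS * N_LABELS)
        res = optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": 1e-9, "gtol": 1e-6},
        )
        theta = res.x
        self.w_obs = theta[:n_obs_params].reshape(self.n_flat, N_LABELS)
        self.w_trans = theta[n_obs_params:].reshape(N_LABELS, N_LABELS)
        self.final_objective_ = float(res.fun)
        self.objective_trace_ = trace
        self.n_iter_ = int(res.nit)
        return self

    # -- inference ----------------------------------------------------------

    def log_partition(self, feats: FeatureSequence) -> float:
        """log Z: log-sum over all 8^L label paths of exp(score)."""
        E = self._emissions(feats)
        alpha = E[0].copy()
        for t in range(1, len(feats)):
            alpha = E[t] + _logsumexp(alpha[:, None] + self.w_trans, axis=0)
        return float(_logsumexp(alpha[None, :], axis=1)[0])

    def sequence_score(self, feats: FeatureSequence, labels: str) -> float:
        """Unnormalized path score of a label sequence."""
        E = self._emissions(feats)
        idx = [SHAPE_LETTERS.index(c) for c in labels]
        s = float(sum(E[t, i] for t, i in enumerate(idx)))
        s += float(sum(self.w_trans[a, b] for a, b in zip(idx, idx[1:])))
        return s

    def best_path(self, feats: FeatureSequence) -> tuple[str, float]:
        """Viterbi decoding: (label string, max path score)."""
        E = self._emissions(feats)
        L = len(feats)
        delta = E[0].copy()
        back = np.zeros((L, N_LABELS), dtype=np.int64)
        for t in range(1, L):
            scores = delta[:, None] + self.w_trans  # (prev, cur)
            back[t] = np.argmax(scores, axis=0)
            delta = E[t] + np.max(scores, axis=0)
        best = int(np.argmax(delta))
        path = [best]
        for t in range(L - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return "".join(SHAPE_LETTERS[i] for i in path), float(np.max(delta))

    def marginals(self, feats: FeatureSequence) -> np.ndarray:
        """(L, 8) forward-backward posterior marginals; rows sum to 1."""
        E = self._emissions(feats)
        L = len(feats)
        log_alpha = np.zeros((L, N_LABELS))
        log_alpha[0] = E[0]
        for t in range(1, L):
            log_alpha[t] = E[t] + _logsumexp(log_alpha[t - 1][:, None] + self.w_trans, axis=0)
        log_beta = np.zeros((L, N_LABELS))
        for t in range(L - 2, -1, -1):
            log_beta[t] = _logsumexp(
                self.w_trans + (E[t + 1] + log_beta[t + 1])[None, :], axis=1
            )
        logZ = _logsumexp(log_alpha[-1][None, :], axis=1)[0]
        return np.exp(log_alpha + log_beta - logZ)

    def decode(self, feats: FeatureSequence) -> tuple[str, np.ndarray]:
        """Viterbi shape string plus forward-backward marginals."""
        if len(feats) == 0:
            return "", np.zeros((0, N_LABELS))
        path, _ = self.best_path(feats)
        return path, self.marginals(feats)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        if self.w_obs is None:
            raise ValueError("untrained model cannot be serialized")
        return {
            "format": "shapestring-crf",
            "version": 1,
            "labels": SHAPE_LETTERS,
            "letters": _LETTERS,
            "window": self.window,
            "n_base": self.n_base,
            "l2": self.l2,
            "max_iter": self.max_iter,
            "seed": self.seed,
            "final_objective": self.final_objective_,
            "n_iter": self.n_iter_,
            "w_obs": self.w_obs.tolist(),
            "w_trans": self.w_trans.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShapeCRF":
        if d.get("format") != "shapestring-crf":
            raise ValueError("not a CRF model dictionary")
        model = cls(window=d["window"], l2=d["l2"], max_iter=d["max_iter"], seed=d["seed"])
        model.n_base = d["n_base"]
        model.w_obs = np.array(d["w_obs"], dtype=float)
        model.w_trans = np.array(d["w_trans"], dtype=float)
        model.final_objective_ = d.get("final_objective")
        model.n_iter_ = d.get("n_iter")
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ShapeCRF":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _scatter_to_positions(
    node_marg: np.ndarray, mask: np.ndarray, pad_idx: np.ndarray, P: int
) -> np.ndarray:
    """Collect padded (N, Lmax, 8) marginals back into flat (P, 8) order."""
    out = np.zeros((P, N_LABELS))
    out[pad_idx[mask]] = node_marg[mask]
    return out


def _batched_forward_backward(
    E_pad: np.ndarray, w_trans: np.ndarray, mask: np.ndarray, lens: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-backward over a padded batch.

    Returns per-sequence log partition values, padded node marginals
    (N, Lmax, 8), and the batch-summed pairwise transition expectations
    (8, 8).
    """
    N, Lmax, K = E_pad.shape
    A = np.zeros((N, Lmax, K))
    A[:, 0] = E_pad[:, 0]
    for t in range(1, Lmax):
        new = E_pad[:, t] + _logsumexp(A[:, t - 1][:, :, None] + w_trans[None], axis=1)
        upd = mask[:, t]
        A[:, t] = np.where(upd[:, None], new, A[:, t - 1])
    logZ = _logsumexp(A[np.arange(N), lens - 1], axis=1)

    B = np.zeros((N, Lmax, K))
    for t in range(Lmax - 2, -1, -1):
        nxt = E_pad[:, t + 1] + B[:, t + 1]
        new = _logsumexp(w_trans[None] + nxt[:, None, :], axis=2)
        B[:, t] = np.where(mask[:, t + 1][:, None], new, 0.0)

    node = np.exp(A + B - logZ[:, None, None])
    node[~mask] = 0.0

    pair_sum = np.zeros((K, K))
    for t in range(1, Lmax):
        valid = mask[:, t]
        if not valid.any():
            continue
        lp = (
            A[valid, t - 1][:, :, None]
            + w_trans[None]
            + (E_pad[valid, t] + B[valid, t])[:, None, :]
            - logZ[valid][:, None, None]
        )
        pair_sum += np.exp(lp).sum(axis=0)
    return logZ, node, pair_sum
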