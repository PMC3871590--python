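"""End-to-end predictor: preprocessing + profiles + CRF, plus experiment harness.

:class:`ShapePredictor` bundles everything a prediction needs — the scale
table learned from the training shifts, the hallmark-pattern library and
annotated reference corpus used for profiles, and the trained CRF — into
one serializable artifact.  The ablation harness runs leave-one-shift-out
and feature-family-combination experiments under chain-level k-fold
cross-validation, mirroring the feature-selection protocol of this kind of
predictor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabets import ATOMS
from .crf import FeatureSequence, ShapeCRF, featurize
from .metrics import evaluate_corpus, EvalReport
from .preprocess import ScaleTable, alphabetize_record, fit_scale_table
from .profiles import (
    HallmarkPattern,
    HitSource,
    KmerHitSource,
    alphabetize_profile,
    build_profile,
    mine_patterns,
    read_pattern_library,
    write_pattern_library,
)
from .shifty import ShiftRecordSeq

TrainingPair = tuple[ShiftRecordSeq, str]  # (shift record, shape string)


@dataclass
class PredictorConfig:
    """Resolved parameters of a training run (written to the manifest)."""

    atoms: tuple[str, ...] = ATOMS
    use_profile: bool = True
    k: int = 6
    top_n: int = 10
    flank: int = 5
    min_support: int = 100
    max_p: float = 0.01
    window: int = 3
    l2: float = 1.0
    max_iter: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["atoms"] = list(self.atoms)
        return d


class ShapePredictor:
    """Trainable shape-string predictor over shift and/or profile features."""

    def __init__(self, config: Optional[PredictorConfig] = None):
        self.config = config or PredictorConfig()
        self.scale_table: Optional[ScaleTable] = None
        self.patterns: list[HallmarkPattern] = []
        self.reference_corpus: list[tuple[str, str]] = []
        self.crf: Optional[ShapeCRF] = None

    # -- feature construction ----------------------------------------------

    def _shift_letters(self, rec: ShiftRecordSeq) -> Optional[list[str]]:
        if not self.config.atoms:
            return None
        letters = alphabetize_record(rec, self.scale_table)
        keep = [ATOMS.index(a) for a in self.config.atoms]
        return ["".join(row[i] for i in keep) for row in letters]

    def _profile_letters(
        self, sequence: str, hit_source: Optional[HitSource]
    ) -> Optional[list[str]]:
        if not self.config.use_profile:
            return None
        source = hit_source
        if source is None:
            source = KmerHitSource(self.reference_corpus, k=self.config.k)
        boxes = build_profile(
            sequence,
            source.hits(sequence),
            self.patterns,
            top_n=self.config.top_n,
            flank=self.config.flank,
        )
        return alphabetize_profile(boxes)

    def featurize_record(
        self, rec: ShiftRecordSeq, hit_source: Optional[HitSource] = None
    ) -> FeatureSequence:
        if self.scale_table is None:
            raise ValueError("predictor is untrained")
        return featurize(
            self._shift_letters(rec),
            self._profile_letters(rec.sequence, hit_source),
            window=self.config.window,
        )

    # -- training -----------------------------------------------------------

    def fit(
        self,
        corpus: Sequence[TrainingPair],
        profile_corpus: Optional[Sequence[tuple[str, str]]] = None,
    ) -> "ShapePredictor":
        """Fit scale table, hallmark library and CRF on an annotated corpus.

        ``profile_corpus`` (sequence, shape) pairs default to the training
        pairs themselves.  During training each chain's own entry is
        excluded from its k-mer hit source so profile features do not leak
        the answer.
        """
        if not corpus:
            raise ValueError("empty training corpus")
        cfg = self.config
        self.scale_table = fit_scale_table([rec for rec, _ in corpus])
        self.reference_corpus = (
            list(profile_corpus)
            if profile_corpus is not None
            else [(rec.sequence, shape) for rec, shape in corpus]
        )
        if cfg.use_profile:
            self.patterns = mine_patterns(
                self.reference_corpus, min_support=cfg.min_support, max_p=cfg.max_p
            )
        training = []
        own_profiles = profile_corpus is None and cfg.use_profile
        for i, (rec, shape) in enumerate(corpus):
            source = (
                KmerHitSource(self.reference_corpus, k=cfg.k, exclude=i)
                if own_profiles
                else None
            )
            training.append((self.featurize_record(rec, hit_source=source), shape))
        self.crf = ShapeCRF(
            window=cfg.window, l2=cfg.l2, max_iter=cfg.max_iter, seed=cfg.seed
        ).fit(training)
        return self

    def predict(
        self, rec: ShiftRecordSeq, hit_source: Optional[HitSource] = None
    ) -> tuple[str, np.ndarray]:
        """Viterbi shape string and per-residue marginals for one record."""
        if self.crf is None:
            raise ValueError("predictor is untrained")
        return self.crf.decode(self.featurize_record(rec, hit_source))

    # -- persistence --------------------------------------------------------

    def save(self, model_path, scale_path=None, patterns_path=None) -> list[Path]:
        """Write the model archive; optionally the portable TSV side files.

        Returns the list of files written.
        """
        if self.crf is None:
            raise ValueError("predictor is untrained")
        model_path = Path(model_path)
        payload = {
            "format": "shapestring-predictor",
            "version": 1,
            "config": self.config.to_dict(),
            "scale_table": {
                f"{aa}:{atom}": list(v)
                for (aa, atom), v in self.scale_table.entries.items()
            },
            "patterns": [
                {
                    "pattern": p.pattern,
                    "letters": list(p.letters),
                    "p_values": list(p.p_values),
                    "conserved": list(p.conserved),
                    "support": p.support,
                }
                for p in self.patterns
            ],
            "reference_corpus": self.reference_corpus,
            "crf": self.crf.to_dict(),
        }
        with open(model_path, "w") as fh:
            json.dump(payload, fh)
        written = [model_path]
        if scale_path is not None:
            self.scale_table.to_tsv(scale_path)
            written.append(Path(scale_path))
        if patterns_path is not None:
            write_pattern_library(self.patterns, patterns_path)
            written.append(Path(patterns_path))
        return written

    @classmethod
    def load(cls, model_path) -> "ShapePredictor":
        with open(model_path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "shapestring-predictor":
            raise ValueError(f"{model_path}: not a predictor archive")
        cfg_d = payload["config"]
        cfg = PredictorConfig(**{**cfg_d, "atoms": tuple(cfg_d["atoms"])})
        pred = cls(cfg)
        pred.scale_table = ScaleTable(
            entries={
                (k.split(":")[0], k.split(":")[1]): tuple(v)
                for k, v in payload["scale_table"].items()
            }
        )
        pred.patterns = [
            HallmarkPattern(
                pattern=p["pattern"],
                letters=tuple(p["letters"]),
                p_values=tuple(p["p_values"]),
                conserved=tuple(p["conserved"]),
                support=p["support"],
            )
            for p in payload["patterns"]
        ]
        pred.reference_corpus = [tuple(x) for x in payload["reference_corpus"]]
        pred.crf = ShapeCRF.from_dict(payload["crf"])
        return pred


# -- cross-validation and ablation -----------------------------------------


def kfold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic chain-level fold assignment."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if n < folds:
        raise ValueError("fewer chains than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(order[i::folds]) for i in range(folds)]


def cross_validate(
    corpus: Sequence[TrainingPair],
    config: PredictorConfig,
    folds: int = 5,
    seed: int = 0,
    bootstrap_reps: int = 200,
) -> EvalReport:
    """Chain-level k-fold CV; pooled predictions scored with bootstrap +/- SE."""
    fold_idx = kfold_indices(len(corpus), folds, seed)
    pairs = []
    for held_out in fold_idx:
        held = set(int(i) for i in held_out)
        train = [corpus[i] for i in range(len(corpus)) if i not in held]
        predictor = ShapePredictor(config).fit(train)
        for i in sorted(held):
            rec, ref = corpus[i]
            pred, _ = predictor.predict(rec)
            pairs.append((pred, ref))
    return evaluate_corpus(pairs, bootstrap_reps=bootstrap_reps, seed=seed)


def ablation_conditions(
    base: PredictorConfig,
) -> dict[str, tuple[str, PredictorConfig]]:
    """Leave-one-shift-out table plus feature-family combinations.

    The ``leave_one_out`` family has seven rows over shift features alone:
    six single-omission conditions (five atoms each) and the all-six-shifts
    row.  The ``combination`` family compares shifts only, profile only,
    and both together.  Values are ``(family, config)`` pairs.
    """
    def variant(**kw) -> PredictorConfig:
        d = base.to_dict()
        d.update(kw)
        return PredictorConfig(**{**d, "atoms": tuple(d["atoms"])})

    conditions: dict[str, tuple[str, PredictorConfig]] = {}
    for atom in ATOMS:
        kept = tuple(a for a in ATOMS if a != atom)
        conditions[f"minus_{atom}"] = (
            "leave_one_out",
            variant(atoms=kept, use_profile=False),
        )
    conditions["all_six_shifts"] = (
        "leave_one_out",
        variant(atoms=ATOMS, use_profile=False),
    )
    conditions["shifts_only"] = (
        "combination",
        variant(atoms=ATOMS, use_profile=False),
    )
    conditions["profile_only"] = ("combination", variant(atoms=(), use_profile=True))
    conditions["combined"] = ("combination", variant(atoms=ATOMS, use_profile=True))
    return conditions


def ablate(
    corpus: Sequence[TrainingPair],
    config: Optional[PredictorConfig] = None,
    folds: int = 5,
    seed: int = 0,
    bootstrap_reps: int = 0,
) -> pd.DataFrame:
    """Run every ablation condition under the same CV folds.

    Returns a table with one row per condition and columns
    ``family S8 SOV8 S3 SOV3`` (percent).
    """
    config = config or PredictorConfig()
    rows = []
    for name, (family, cond) in ablation_conditions(config).items():
        report = cross_validate(
            corpus, cond, folds=folds, seed=seed, bootstrap_reps=bootstrap_reps
        )
        rows.append(
            {
                "condition": name,
                "family": family,
                "S8": report.s8,
                "SOV8": report.sov8,
                "S3": report.s3,
                "SOV3": report.sov3,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
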