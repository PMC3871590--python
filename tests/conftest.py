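import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from shapestring import (
    Residue,
    ShiftRecordSeq,
    SynthConfig,
    default_torsion_table,
    generate,
)


@pytest.fixture(scope="session")
def torsion_table():
    return default_torsion_table()


@pytest.fixture(scope="session")
def tiny_corpus():
    """Eight short chains with strong shift/shape coupling and no vacancies."""
    cfg = SynthConfig(
        n_chains=8, length_range=(20, 30), separation=3.0, missingness=0.0, seed=11
    )
    return generate(cfg)


def make_record(chain_id: str, rows) -> ShiftRecordSeq:
    """rows: list of (index, aa, shifts-dict) tuples."""
    return ShiftRecordSeq(
        chain_id=chain_id,
        residues=[Residue(index=i, aa=aa, shifts=dict(sh)) for i, aa, sh in rows],
    )


def random_shape_string(rng: np.random.Generator, length: int, with_x=False) -> str:
    letters = "SRUVKATG" + ("X" if with_x else "")
    return "".join(rng.choice(list(letters), size=length))
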