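import numpy as np
import pandas as pd
import pytest

from gxetools.expression import ExpressionTable


def random_table(seed: int, temps=("T1",), tissues=("e1", "e2", "e3"),
                 genes=("g1", "g2"), blocks=2, loc=2.0, scale=1.0) -> ExpressionTable:
    """Balanced random table: independent N(loc, scale) per observation."""
    rng = np.random.default_rng(seed)
    rows = [
        (tp, e, g, b, rng.normal(loc, scale))
        for tp in temps for e in tissues for g in genes
        for b in range(1, blocks + 1)
    ]
    return ExpressionTable(
        pd.DataFrame(rows, columns=["temperature", "tissue", "gene", "block", "value"])
    )


@pytest.fixture
def small_table():
    return random_table(seed=11)


@pytest.fixture
def study_like_table():
    """One temperature, study dimensions: 4 genes x 10 tissues x 3 blocks."""
    return random_table(
        seed=5, temps=("23",),
        tissues=tuple(f"e{j}" for j in range(10)),
        genes=tuple(f"g{i}" for i in range(4)),
        blocks=3,
    )
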