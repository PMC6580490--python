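from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from liftrr import ContingencyTable, TransactionMatrix, from_counts

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"

#: the bundled worked example: SGA births vs a three-chemical mixture
WORKED_COUNTS = (7828, 64021, 21851, 239550)


@pytest.fixture(scope="session")
def worked_table() -> ContingencyTable:
    return from_counts(*WORKED_COUNTS)


@pytest.fixture(scope="session")
def table2_csv() -> Path:
    return DATA_DIR / "table2_rules.csv"


@pytest.fixture()
def toy_matrix() -> TransactionMatrix:
    """8 subjects enumerating every (E1, E2) combination twice.

    The outcome fires exactly when both exposures are present, so the
    {E1, E2} conjunction cross-tabulates to (2, 0, 0, 6) by hand count.
    """
    combos = [(0, 0), (0, 1), (1, 0), (1, 1)] * 2
    exposures = np.array(combos)
    outcome = (exposures[:, 0] & exposures[:, 1]).astype(int)
    return TransactionMatrix(
        exposure_names=("E1", "E2"), exposures=exposures, outcome=outcome
    )


def positive_margin_tables(max_cell: int, min_cell: int = 0):
    """Yield every 2x2 table with cells in [min_cell, max_cell] and all four
    margins positive."""
    r = range(min_cell, max_cell + 1)
    for a in r:
        for b in r:
            if a + b == 0:
                continue
            for c in r:
                if a + c == 0:
                    continue
                for d in r:
                    if c + d == 0 or b + d == 0:
                        continue
                    yield ContingencyTable(a, b, c, d)
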