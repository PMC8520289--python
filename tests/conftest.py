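import numpy as np
import pytest

from rdci.intervals import ArmCount, TwoArmTable
from rdci.synthetic import generate_fixture


@pytest.fixture
def micro_table() -> TwoArmTable:
    """The worked 8/10 vs 6/10 example."""
    return TwoArmTable(ArmCount(8, 10), ArmCount(6, 10))


@pytest.fixture
def degenerate_table() -> TwoArmTable:
    return TwoArmTable(ArmCount(50, 50), ArmCount(50, 50))


@pytest.fixture
def fixture_dataset():
    return generate_fixture()


def random_tables(rng: np.random.Generator, count: int, max_n: int = 60):
    """Random small 2x2 tables (uniform totals and success counts)."""
    out = []
    for _ in range(count):
        n1 = int(rng.integers(1, max_n + 1))
        n2 = int(rng.integers(1, max_n + 1))
        x1 = int(rng.integers(0, n1 + 1))
        x2 = int(rng.integers(0, n2 + 1))
        out.append(TwoArmTable(ArmCount(x1, n1), ArmCount(x2, n2)))
    return out
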