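import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tirpscope import (
    STI,
    STIDatabase,
    Transaction,
    build_indices,
    fig1_fixture,
)

# short handles for the toy tree's symbols
F = "Fall.Event"
L = "Fluids.Low"
P = "Physical.Decreasing"
H = "Happiness.Decreasing"
A = "Appetite.Decreasing"


@pytest.fixture(scope="session")
def toy_tree():
    return fig1_fixture()


@pytest.fixture(scope="session")
def toy_indices(toy_tree):
    return build_indices(toy_tree)


@pytest.fixture()
def metric_example_db():
    """Two transactions whose <A before B> support is hand-enumerable:
    txn1 has 3 instances spanning {3, 12, 3}; txn2 has 1 spanning 4."""
    txn1 = Transaction(
        "t1",
        (STI("A", 0, 1), STI("B", 2, 3), STI("A", 9, 10), STI("B", 11, 12)),
        {"gender": "female"},
    )
    txn2 = Transaction("t2", (STI("A", 0, 1), STI("B", 3, 4)), {"gender": "male"})
    return STIDatabase([txn1, txn2])
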