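import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from larma import datasets
from larma.io_transactions import Transaction, TransactionSet


@pytest.fixture(scope="session")
def discovery_ts() -> TransactionSet:
    """The six discovery comparisons encoded as transactions."""
    return datasets.discovery_transactions()


@pytest.fixture(scope="session")
def discovery_lfc():
    return datasets.load_discovery_lfc()


@pytest.fixture(scope="session")
def validation_microarray():
    return datasets.load_validation_microarray()


@pytest.fixture(scope="session")
def validation_rnaseq():
    return datasets.load_validation_rnaseq()


def make_ts(baskets, signs=None) -> TransactionSet:
    """Build a TransactionSet from plain item collections (all signs +1
    unless given)."""
    txs = []
    for i, basket in enumerate(baskets):
        sign_of = {g: 1 for g in basket}
        if signs is not None:
            sign_of.update(signs[i])
        txs.append(
            Transaction(
                comparison_id=f"T{i:03d}",
                items=frozenset(basket),
                sign_of=sign_of,
                lfc_of={g: float(s) for g, s in sign_of.items()},
            )
        )
    return TransactionSet(txs)
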