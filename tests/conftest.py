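"""Shared fixtures: class pools and small brute-force oracles."""

import numpy as np
import pytest

from chainlogic.bfcore import BooleanFunction, truth_table_from_expression
from chainlogic.chainclass import Label, classify
from chainlogic.chaincount import enumerate_class


def bf(expr: str, k: int) -> BooleanFunction:
    """Parse an expression over the variables x1..xk."""
    return truth_table_from_expression(expr, [f"x{i}" for i in range(1, k + 1)])


def from_rowlast_int(k: int, tt: int) -> BooleanFunction:
    return BooleanFunction.from_int(k, tt, msb_row0=False)


@pytest.fixture(scope="session")
def class_sets():
    """Deduplicated truth-table integer sets per (k, class), k <= 6.

    Integers use the row-last-most-significant dialect (bit r = row r).
    """
    pools = {}

    def get(k, cls):
        key = (k, cls)
        if key not in pools:
            pools[key] = frozenset(enumerate_class(k, cls, encoding="msb-rowlast"))
        return pools[key]

    return get


@pytest.fixture(scope="session")
def brute_labels_k3():
    """Classification of every 3-input function, from the greedy classifier
    (cross-checked against the peel-order oracle elsewhere)."""
    return {
        tt: classify(from_rowlast_int(3, tt)).label for tt in range(2**8)
    }
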