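import logging

import numpy as np
import pytest

from microcausal import DataTable, PartiallyDirectedGraph

logging.getLogger("microcausal").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_graph():
    """A -> B -> C."""
    return PartiallyDirectedGraph(["A", "B", "C"], [("A", "B"), ("B", "C")])


def make_chain_data(n=2000, a=1.0, b=1.0, seed=1):
    """Linear chain X -> Y -> Z with unit noise."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = a * x + rng.standard_normal(n)
    z = b * y + rng.standard_normal(n)
    return DataTable(np.column_stack([x, y, z]), ["X", "Y", "Z"])


def make_collider_data(n=2000, a=1.0, b=1.0, seed=2):
    """X and Y independent causes of Z = aX + bY + noise."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    z = a * x + b * y + rng.standard_normal(n)
    return DataTable(np.column_stack([x, y, z]), ["X", "Y", "Z"])
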