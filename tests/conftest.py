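import numpy as np
import pandas as pd
import pytest

from lne.expression import ExpressionStudy
from lne.network import GeneNetwork


def make_random_toy(rng, max_genes=10, max_samples=8):
    """Random small study + connected-ish network for oracle comparisons.

    Returns (case_series, ref_frame, network).
    """
    n_genes = int(rng.integers(3, max_genes + 1))
    genes = [f"g{i}" for i in range(n_genes)]
    edges = []
    for i in range(1, n_genes):
        j = int(rng.integers(0, i))
        edges.append((genes[i], genes[j]))
    for _ in range(int(rng.integers(0, n_genes))):
        i, j = rng.choice(n_genes, size=2, replace=False)
        edges.append((genes[int(i)], genes[int(j)]))
    net = GeneNetwork(edges)

    n_ref = int(rng.integers(3, max_samples))  # leaves room for the case sample
    ref = pd.DataFrame(
        rng.normal(size=(n_genes, n_ref)) * rng.uniform(0.5, 3.0),
        index=genes,
        columns=[f"r{i}" for i in range(n_ref)],
    )
    case = pd.Series(rng.normal(size=n_genes), index=genes)
    return case, ref, net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_network():
    """a - b - c path."""
    return GeneNetwork([("a", "b"), ("b", "c")])


@pytest.fixture
def tiny_study(rng):
    """3-gene path network study with 4 reference and 2 case samples."""
    genes = ["a", "b", "c"]
    cols = {f"r{i}": rng.normal(size=3) for i in range(4)}
    cols["s1"] = rng.normal(size=3)
    cols["s2"] = rng.normal(size=3)
    expr = pd.DataFrame(cols, index=genes)
    groups = {f"r{i}": "reference" for i in range(4)} | {"s1": "case", "s2": "case"}
    stages = {"s1": "early", "s2": "late"}
    return ExpressionStudy(expression=expr, groups=groups, stages=stages)
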