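"""Shared fixtures: tiny OTU tables, small graphs, study-scale simulation."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from seasonet.core import OtuTable
from seasonet.simulate import CommunityParams, simulate_study


@pytest.fixture
def tiny_table() -> OtuTable:
    """3 OTUs x 2 samples with taxonomy."""
    counts = pd.DataFrame(
        {"S1": [5, 3, 2], "S2": [0, 7, 3]},
        index=["OTU1", "OTU2", "OTU3"],
    )
    tax = pd.Series(
        ["Bacteria;Proteobacteria", "Bacteria;Acidobacteria", "unclassified"],
        index=counts.index, name="taxonomy",
    )
    return OtuTable(counts, tax)


def make_table(counts: np.ndarray) -> OtuTable:
    counts = np.asarray(counts)
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"OTU{i+1}" for i in range(counts.shape[0])],
            columns=[f"S{j+1}" for j in range(counts.shape[1])],
        )
    )


@pytest.fixture
def barbell() -> nx.Graph:
    """Two triangles joined by one edge."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


@pytest.fixture(scope="session")
def small_study():
    """Reduced study simulation shared across tests (2 blocks, 12 months)."""
    return simulate_study(
        1,
        community_params=CommunityParams(
            n_otus=150, n_modules=3, module_size=10, depth=2000
        ),
        n_blocks=2,
        n_months=12,
    )


def set_partitions(nodes):
    """All partitions of a node list (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1:]
        yield [[first]] + part


def signed_random_network(n_nodes: int, seed: int, p: float = 0.4):
    """Random connected-ish signed network plus positive abundances."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31 - 1)))
    g.remove_nodes_from(list(nx.isolates(g)))
    for u, v in g.edges:
        r = float(rng.uniform(0.5, 1.0)) * (1 if rng.random() < 0.7 else -1)
        g[u][v]["r"] = r
        g[u][v]["weight"] = abs(r)
    abund = pd.Series(
        rng.uniform(0.01, 1.0, g.number_of_nodes()), index=sorted(g.nodes)
    )
    return g, abund
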