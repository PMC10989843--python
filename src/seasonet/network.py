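"""Co-occurrence network construction.

The construction follows the hard-threshold correlation recipe used for
molecular ecological networks: keep OTUs present in at least 75% of the
samples in scope, transform abundances, compute pairwise Pearson r across
samples, and keep edges with similarity |r| >= S_t.  Strong negative
associations survive thresholding because similarity is |r|; the sign is
retained as an edge attribute.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import OtuTable, relative_abundance

logger = logging.getLogger("seasonet")

__all__ = [
    "CoNetwork",
    "prevalence_filter",
    "transform_abundance",
    "similarity_matrix",
    "threshold_network",
]

TRANSFORMS = ("log10_pseudocount", "none", "clr")


@dataclass
class CoNetwork:
    """Undirected signed weighted co-occurrence network.

    Nodes are OTU ids (with taxonomy attributes when known); each edge
    stores the signed Pearson ``r`` and similarity ``weight`` = |r|.  The
    construction record (sample set, prevalence rule, transform, S_t) is
    kept for provenance.
    """

    graph: nx.Graph
    s_t: float
    sample_ids: list[str] = field(default_factory=list)
    prevalence_fraction: float | None = None
    transform: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def positive_link_fraction(self) -> float:
        L = self.n_links
        if L == 0:
            return math.nan
        pos = sum(1 for _, _, d in self.graph.edges(data=True) if d["r"] > 0)
        return pos / L

    @property
    def negative_link_fraction(self) -> float:
        L = self.n_links
        if L == 0:
            return math.nan
        return 1.0 - self.positive_link_fraction

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-edge at {u}")
            if abs(d["r"]) < self.s_t - 1e-12:
                raise ValueError(f"edge ({u},{v}) below threshold")
        if any(deg == 0 for _, deg in self.graph.degree()):
            raise ValueError("isolated node after pruning")


def prevalence_filter(
    table: OtuTable, sample_subset=None, min_fraction: float = 0.75
) -> OtuTable:
    """Keep OTUs with nonzero counts in >= ceil(min_fraction * n) samples.

    With 48 samples and the default 75% rule the cutoff is 36 samples; with
    a 12-sample seasonal scope it is 9.
    """
    sub = table if sample_subset is None else table.subset_samples(sample_subset)
    n = len(sub.sample_ids)
    if n == 0:
        raise ValueError("empty sample subset")
    cutoff = math.ceil(min_fraction * n)
    occ = (sub.counts > 0).sum(axis=1)
    keep = occ[occ >= cutoff].index
    if len(keep) == 0:
        raise ValueError(
            f"no OTU passes the prevalence filter (cutoff {cutoff}/{n} samples); "
            "lower min_fraction"
        )
    logger.info(
        "prevalence_filter: %d/%d OTUs retained (cutoff %d of %d samples)",
        len(keep), len(sub.otu_ids), cutoff, n,
    )
    return sub.subset_otus(list(keep))


def transform_abundance(
    table: OtuTable, transform: str = "log10_pseudocount"
) -> pd.DataFrame:
    """Abundance transform applied before correlation (OTU x sample).

    ``log10_pseudocount``: log10 of relative abundance with zeros replaced
    per OTU by 0.01 x that OTU's smallest nonzero proportion.  ``clr``:
    centred log-ratio with the same pseudocount rule.  ``none``: raw
    proportions.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    prop = relative_abundance(table)
    if transform == "none":
        return prop
    x = prop.to_numpy(copy=True)
    for i in range(x.shape[0]):
        row = x[i]
        nz = row[row > 0]
        if nz.size == 0:
            continue  # all-zero row: left as zeros, dropped later
        row[row == 0] = 0.01 * nz.min()
    logx = np.log10(x, where=x > 0, out=np.zeros_like(x))
    if transform == "clr":
        logx = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(logx, index=prop.index, columns=prop.columns)


def similarity_matrix(
    table: OtuTable, transform: str = "log10_pseudocount"
) -> pd.DataFrame:
    """Signed Pearson correlation between OTUs across samples.

    Zero-variance OTUs are dropped with a warning before correlating.
    Returns a symmetric DataFrame of signed r with unit diagonal; the
    similarity used for thresholding is |r|.
    """
    if len(table.sample_ids) < 3:
        raise ValueError("need at least 3 samples to correlate")
    x = transform_abundance(table, transform)
    sd = x.std(axis=1, ddof=1)
    flat = sd[sd == 0].index
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance OTU(s)")
        x = x.drop(index=flat)
    r = np.corrcoef(x.to_numpy())
    return pd.DataFrame(r, index=x.index, columns=x.index)


def threshold_network(
    sim: pd.DataFrame,
    s_t: float,
    table: OtuTable | None = None,
    sample_ids=None,
    prevalence_fraction: float | None = None,
    transform: str | None = None,
) -> CoNetwork:
    """Build the network with edges where |r| >= s_t; prune isolated nodes.

    An s_t above the largest |r| yields an empty network with a warning,
    not an error.
    """
    if not (0 < s_t <= 1):
        raise ValueError(f"s_t must be in (0, 1], got {s_t}")
    ids = list(sim.index)
    r = sim.to_numpy()
    g = nx.Graph()
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.abs(r[iu, ju]) >= s_t
    for i, j in zip(iu[mask], ju[mask]):
        rij = float(r[i, j])
        g.add_edge(ids[i], ids[j], r=rij, weight=abs(rij))
    if g.number_of_edges() == 0:
        warnings.warn(f"threshold s_t={s_t} yields an empty network")
    if table is not None and table.taxonomy is not None:
        for node in g.nodes:
            g.nodes[node]["taxonomy"] = str(table.taxonomy.get(node, ""))
    net = CoNetwork(
        graph=g,
        s_t=s_t,
        sample_ids=list(sample_ids) if sample_ids is not None else
        (table.sample_ids if table is not None else []),
        prevalence_fraction=prevalence_fraction,
        transform=transform,
    )
    logger.info("threshold_network: s_t=%.3f n=%d L=%d", s_t, net.n_nodes, net.n_links)
    return net
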