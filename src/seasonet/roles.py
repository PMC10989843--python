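"""Zi-Pi node roles and module eigengene analysis.

Node roles follow the Guimera-Amaral scheme: the within-module degree
z-score Zi and the among-module participation coefficient
Pi = 1 - sum_s (k_is / k_i)^2 classify nodes with the conventional cutoffs
Zi > 2.5 and Pi > 0.62 into module hubs, connectors, network hubs and
peripherals.  A module eigengene is the first singular direction of the
module members' standardized abundance profiles, summarizing the module as
one profile over samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core import OtuTable, relative_abundance
from .topology import ModuleSet

logger = logging.getLogger("seasonet")

__all__ = [
    "NodeRole",
    "Eigengene",
    "zi_pi",
    "module_eigengene",
    "eigengene_clustering",
    "eigengene_env_correlation",
    "ZI_THRESHOLD",
    "PI_THRESHOLD",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class NodeRole:
    otu_id: str
    module_id: str
    zi: float
    pi: float
    category: str  # peripheral | module_hub | connector | network_hub


def _classify(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return "network_hub"
    if zi > ZI_THRESHOLD:
        return "module_hub"
    if pi > PI_THRESHOLD:
        return "connector"
    return "peripheral"


def zi_pi(net, modules: ModuleSet) -> list[NodeRole]:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes the node's within-module degree against the nodes of
    its own module (Zi = 0 when the module sd is 0 or the module has a
    single member).  Pi = 1 - sum_s (k_is/k_i)^2 over the modules s the
    node links to.
    """
    g = net if isinstance(net, nx.Graph) else net.graph
    assign = modules.assignment
    missing = [v for v in g.nodes if v not in assign]
    if missing:
        raise ValueError(f"modules do not cover nodes: {missing[:5]}")

    k_within: dict = {}
    k_by_module: dict = {}
    for node in g.nodes:
        counts: dict = {}
        for nb in g.neighbors(node):
            counts[assign[nb]] = counts.get(assign[nb], 0) + 1
        k_by_module[node] = counts
        k_within[node] = counts.get(assign[node], 0)

    # module-wise mean/sd of within-module degree
    module_stats: dict = {}
    for mod, mem in modules.modules.items():
        ks = np.array([k_within[v] for v in mem if v in k_within], float)
        module_stats[mod] = (ks.mean(), ks.std(ddof=0)) if len(ks) else (0.0, 0.0)

    roles = []
    for node in sorted(g.nodes, key=str):
        k_i = g.degree(node)
        mu, sd = module_stats[assign[node]]
        zi = (k_within[node] - mu) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((k / k_i) ** 2 for k in k_by_module[node].values()) if k_i else 0.0
        roles.append(
            NodeRole(
                otu_id=node,
                module_id=assign[node],
                zi=float(zi),
                pi=float(pi),
                category=_classify(zi, pi),
            )
        )
    return roles


# ---------------------------------------------------------------------------
# eigengenes
# ---------------------------------------------------------------------------

@dataclass
class Eigengene:
    module_id: str
    scores: pd.Series          # per-sample, zero mean unit variance
    variance_explained: float
    sign_flipped: bool


def module_eigengene(
    table: OtuTable, modules: ModuleSet, min_size: int = 5
) -> list[Eigengene]:
    """First singular direction of each large module's member profiles.

    Member relative abundances are standardized per OTU (zero mean, unit
    variance over samples); the eigengene is the first right singular
    vector over samples, scaled to unit variance, and oriented to correlate
    positively with the mean member profile.  Modules smaller than
    ``min_size`` are skipped.
    """
    prop = relative_abundance(table)
    eigs = []
    for mod, mem in sorted(modules.modules.items()):
        mem = [m for m in mem if m in prop.index]
        if len(mem) < min_size:
            logger.info("module %s: %d members < %d, eigengene skipped",
                        mod, len(mem), min_size)
            continue
        x = prop.loc[mem].to_numpy(float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        keep = sd[:, 0] > 0
        if keep.sum() < 2:
            logger.warning("module %s: too few variable members, skipped", mod)
            continue
        z = (x[keep] - mu[keep]) / sd[keep]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        scores = vt[0]
        var_explained = float(s[0] ** 2 / (s ** 2).sum())
        mean_profile = z.mean(axis=0)
        flipped = False
        r = np.corrcoef(scores, mean_profile)[0, 1]
        if r < 0:
            scores = -scores
            flipped = True
        scores = (scores - scores.mean()) / scores.std(ddof=0)
        eigs.append(
            Eigengene(
                module_id=mod,
                scores=pd.Series(scores, index=prop.columns, name=mod),
                variance_explained=var_explained,
                sign_flipped=flipped,
            )
        )
    return eigs


def eigengene_clustering(eigs: list[Eigengene]):
    """Average-linkage hierarchy on 1 - Pearson correlation between
    eigengenes.  Returns (scipy linkage matrix, ordered module ids)."""
    if len(eigs) < 2:
        raise ValueError("need at least 2 eigengenes to cluster")
    mat = np.vstack([e.scores.to_numpy() for e in eigs])
    corr = np.corrcoef(mat)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    z = linkage(squareform(d, checks=False), method="average")
    return z, [e.module_id for e in eigs]


def eigengene_env_correlation(
    eigs: list[Eigengene], env: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided p for every eigengene x environment pair.

    Missing environment values are dropped pairwise; constant variables are
    reported as missing.  Raw p-values carry significance stars; a
    Benjamini-Hochberg adjusted column is included alongside.
    """
    rows = []
    for e in eigs:
        shared = e.scores.index.intersection(env.index)
        for var in env.columns:
            y = env.loc[shared, var].astype(float)
            mask = y.notna()
            x = e.scores.loc[shared][mask].to_numpy()
            yv = y[mask].to_numpy()
            if len(x) < 3 or np.std(yv) == 0 or np.std(x) == 0:
                rows.append({"module": e.module_id, "variable": var,
                             "r": np.nan, "p": np.nan, "n": int(mask.sum())})
                continue
            r, p = stats.pearsonr(x, yv)
            rows.append({"module": e.module_id, "variable": var,
                         "r": float(r), "p": float(p), "n": int(len(x))})
    out = pd.DataFrame(rows)
    # Benjamini-Hochberg over the finite p-values
    p = out["p"].to_numpy()
    finite = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if finite.sum():
        ps = p[finite]
        order = np.argsort(ps)
        m = len(ps)
        ranked = ps[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.minimum(ranked, 1.0)
        adj[finite] = vals
    out["p_adj_bh"] = adj
    out["stars"] = [
        "***" if q <= 0.001 else "**" if q <= 0.01 else "*" if q <= 0.05 else ""
        for q in out["p"].fillna(1.0)
    ]
    return out
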