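"""Network topology: summary indices, power-law fit, greedy modularity,
degree-preserving null ensembles and relative modularity.

Modularity uses the Newman-Girvan quality
M = sum_c (l_c/L - (d_c/2L)^2) on the unweighted simple graph, maximized
by CNM-style agglomerative merging with deterministic tie-breaking.
M > 0.4 is the conventional threshold for declaring modular structure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import CoNetwork

__all__ = [
    "TopologySummary",
    "ModuleSet",
    "topology_summary",
    "powerlaw_fit",
    "modularity",
    "greedy_modules",
    "random_null_ensemble",
    "relative_modularity",
]

MODULARITY_THRESHOLD = 0.4


def _as_graph(net) -> nx.Graph:
    return net if isinstance(net, nx.Graph) else net.graph


@dataclass
class ModuleSet:
    """Node -> module partition with its Newman-Girvan modularity."""

    assignment: dict            # node id -> module id (e.g. "M1")
    modularity: float

    @property
    def modules(self) -> dict:
        out: dict[str, list] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, []).append(node)
        return out

    @property
    def is_modular(self) -> bool:
        return self.modularity > MODULARITY_THRESHOLD

    def module_of(self, node) -> str:
        return self.assignment[node]


@dataclass
class TopologySummary:
    n: int
    L: int
    avgK: float
    avgCC: float
    connectance: float
    GD: float
    unreachable_pairs: int
    powerlaw_exponent: float | None = None
    powerlaw_r2: float | None = None
    modularity: float | None = None
    relative_modularity: float | None = None
    null: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "n": self.n, "L": self.L, "avgK": self.avgK, "avgCC": self.avgCC,
            "connectance": self.connectance, "GD": self.GD,
            "unreachable_pairs": self.unreachable_pairs,
            "powerlaw_exponent": self.powerlaw_exponent,
            "powerlaw_r2": self.powerlaw_r2,
            "modularity": self.modularity,
            "relative_modularity": self.relative_modularity,
        }
        if self.null:
            d["null"] = self.null
        return d


def topology_summary(net) -> TopologySummary:
    """Size, connectivity, clustering, connectance and geodesic distance.

    avgK = 2L/n; connectance = 2L/(n(n-1)); avgCC is the mean local
    clustering coefficient (degree < 2 contributes 0); GD averages
    shortest-path lengths over connected pairs only, reporting the number
    of unreachable pairs alongside.
    """
    g = _as_graph(net)
    n, L = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        raise ValueError("network must have at least 2 nodes")
    avg_k = 2 * L / n
    connectance = 2 * L / (n * (n - 1))
    avg_cc = float(np.mean(list(nx.clustering(g).values())))
    total_pairs = n * (n - 1) // 2
    path_sum = 0.0
    connected_pairs = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        m = len(comp)
        if m < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(lengths.values())
        connected_pairs += m * (m - 1) // 2
    gd = path_sum / (2 * connected_pairs) if connected_pairs else math.nan
    return TopologySummary(
        n=n, L=L, avgK=avg_k, avgCC=avg_cc, connectance=connectance,
        GD=gd, unreachable_pairs=total_pairs - connected_pairs,
    )


def powerlaw_fit(degrees) -> tuple[float | None, float | None]:
    """Least-squares fit of log(frequency) on log(degree).

    Returns (exponent, R^2) where the fitted slope is -exponent.  Needs at
    least 3 distinct positive degrees; otherwise returns (None, None) with
    a warning.
    """
    degrees = np.asarray(list(degrees))
    degrees = degrees[degrees > 0]
    ks, freq = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        warnings.warn("power-law fit undefined: fewer than 3 distinct degrees")
        return None, None
    x = np.log(ks.astype(float))
    y = np.log(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # flat frequency spectrum: no power-law decay to explain
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 1e-12 else 0.0
    return float(-slope), float(r2)


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def modularity(g: nx.Graph, assignment: dict) -> float:
    """Newman-Girvan modularity of a partition on the unweighted graph."""
    L = g.number_of_edges()
    if L == 0:
        raise ValueError("modularity undefined for an empty graph")
    within: dict = {}
    deg: dict = {}
    for node in g.nodes:
        deg[assignment[node]] = deg.get(assignment[node], 0) + g.degree(node)
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            within[assignment[u]] = within.get(assignment[u], 0) + 1
    return float(
        sum(
            within.get(c, 0) / L - (d / (2 * L)) ** 2
            for c, d in deg.items()
        )
    )


def greedy_modules(net) -> ModuleSet:
    """CNM agglomerative modularity maximization.

    Starts from singleton communities and repeatedly merges the connected
    community pair with the largest modularity gain
    dQ = l_ij/L - 2 a_i a_j (l_ij = edges between the pair, a_i = degree
    fraction), continuing through negative gains and returning the
    partition with the highest M along the merge path.  Ties are broken
    deterministically by the lexicographically smallest pair of community
    representatives (lowest node id).  Modularity is computed on the
    unweighted simple graph.
    """
    g = _as_graph(net)
    L = g.number_of_edges()
    if L == 0:
        raise ValueError("greedy_modules requires at least one edge")
    nodes = sorted(g.nodes, key=str)
    comm_of = {v: v for v in nodes}          # node -> representative (smallest id)
    members = {v: [v] for v in nodes}
    a = {v: g.degree(v) / (2 * L) for v in nodes}
    links: dict = {v: {} for v in nodes}     # edge counts between communities
    for u, v in g.edges:
        if u == v:
            continue
        links[u][v] = links[u].get(v, 0) + 1
        links[v][u] = links[v].get(u, 0) + 1

    q = -sum(val ** 2 for val in a.values())  # all-singleton partition
    best_q = q
    best_partition = dict(comm_of)

    while len(members) > 1:
        best_gain = None
        best_pair = None
        for ci in members:
            for cj, lij in links[ci].items():
                if not (str(ci) < str(cj)):
                    continue
                gain = lij / L - 2.0 * a[ci] * a[cj]
                if (
                    best_gain is None
                    or gain > best_gain + 1e-15
                    or (abs(gain - best_gain) <= 1e-15 and (ci, cj) < best_pair)
                ):
                    best_gain = gain
                    best_pair = (ci, cj)
        if best_pair is None:
            break  # remaining communities are mutually disconnected
        ci, cj = best_pair
        q += best_gain
        # merge cj into ci (ci keeps the smaller representative id)
        members[ci].extend(members[cj])
        for v in members[cj]:
            comm_of[v] = ci
        del members[cj]
        for other, lij in links[cj].items():
            if other == ci:
                continue
            links[ci][other] = links[ci].get(other, 0) + lij
            links[other][ci] = links[ci][other]
            del links[other][cj]
        links[ci].pop(cj, None)
        del links[cj]
        a[ci] += a[cj]
        del a[cj]
        if q > best_q + 1e-12:
            best_q = q
            best_partition = dict(comm_of)

    best_partition = _refine_partition(g, best_partition)
    best_q = modularity(g, best_partition)

    # canonical module ids, ordered by size then representative
    groups: dict = {}
    for node, rep in best_partition.items():
        groups.setdefault(rep, []).append(node)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), str(kv[0])))
    assignment = {}
    for k, (_, mem) in enumerate(ordered, start=1):
        for node in mem:
            assignment[node] = f"M{k}"
    return ModuleSet(assignment=assignment, modularity=float(best_q))


def _refine_partition(g: nx.Graph, assignment: dict) -> dict:
    """Deterministic single-node moves that increase modularity.

    After agglomeration, each node (in sorted order) is tentatively moved
    to the neighboring community with the largest positive gain; sweeps
    repeat until no move improves.  Gains are evaluated incrementally from
    community degree sums and the node's links into each community.
    """
    L = g.number_of_edges()
    assign = dict(assignment)
    deg_sum: dict = {}
    for v in g.nodes:
        deg_sum[assign[v]] = deg_sum.get(assign[v], 0) + g.degree(v)
    nodes = sorted(g.nodes, key=str)
    for _ in range(len(nodes)):
        improved = False
        for v in nodes:
            cv = assign[v]
            k_v = g.degree(v)
            links_to: dict = {}
            for nb in g.neighbors(v):
                links_to[assign[nb]] = links_to.get(assign[nb], 0) + 1
            base_links = links_to.get(cv, 0)
            best_gain, best_c = 0.0, cv
            for c, l_c in sorted(links_to.items(), key=lambda kv: str(kv[0])):
                if c == cv:
                    continue
                # dQ of moving v from cv to c
                gain = (l_c - base_links) / L - k_v * (
                    deg_sum.get(c, 0) - (deg_sum[cv] - k_v)
                ) / (2 * L * L)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            if best_c != cv:
                assign[v] = best_c
                deg_sum[cv] -= k_v
                deg_sum[best_c] = deg_sum.get(best_c, 0) + k_v
                improved = True
        if not improved:
            break
    return assign


# ---------------------------------------------------------------------------
# null ensembles
# ---------------------------------------------------------------------------

def random_null_ensemble(
    net,
    n_reps: int = 100,
    method: str = "degree_preserving_rewire",
    seed: int | None = None,
    swaps_per_edge: int = 10,
) -> dict:
    """Degree-preserving rewired null graphs and their summaries.

    Every replicate keeps the exact degree sequence (double edge swaps,
    10 x L attempted swaps by default).  Returns per-replicate avgCC, M and
    GD with their means and standard deviations.
    """
    if method != "degree_preserving_rewire":
        raise ValueError(f"unknown null method {method!r}")
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    g = _as_graph(net)
    L = g.number_of_edges()
    if L < 2:
        raise ValueError("graph too small to rewire (L < 2)")
    rng = np.random.default_rng(seed)
    deg_ref = sorted(d for _, d in g.degree())
    cc, mod, gd = [], [], []
    for _ in range(n_reps):
        h = g.copy()
        try:
            nx.double_edge_swap(
                h,
                nswap=swaps_per_edge * L,
                max_tries=100 * swaps_per_edge * L,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXAlgorithmError:
            pass  # max_tries exhausted: keep partially rewired graph
        assert sorted(d for _, d in h.degree()) == deg_ref
        assert h.number_of_edges() == L
        summ = topology_summary(h)
        cc.append(summ.avgCC)
        gd.append(summ.GD)
        mod.append(greedy_modules(h).modularity)
    out = {}
    for name, vals in (("avgCC", cc), ("modularity", mod), ("GD", gd)):
        arr = np.asarray(vals, float)
        out[name] = {
            "mean": float(np.nanmean(arr)),
            "sd": float(np.nanstd(arr, ddof=1)),
            "values": [float(v) for v in arr],
        }
    out["n_reps"] = n_reps
    out["method"] = method
    return out


def relative_modularity(m_observed: float, m_null_mean: float) -> float:
    """RM = (M - M_null) / M_null; undefined for non-positive null mean."""
    if m_null_mean <= 0:
        raise ValueError("relative modularity undefined: null mean <= 0")
    return (m_observed - m_null_mean) / m_null_mean
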