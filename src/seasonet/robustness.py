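"""Network robustness under node removal with extinction cascades.

After an initial removal (a random fraction of taxa, or the top module
hubs), surviving nodes are re-evaluated by their abundance-weighted mean
interaction strength wMIS_i = sum_j b_j s_ij / sum_j b_j over remaining
neighbors j (b_j = neighbor relative abundance, s_ij = signed Pearson r of
the edge).  Nodes with wMIS <= 0 or no remaining neighbors go extinct and
the evaluation repeats to a fixed point.  Robustness is the fraction of
the original nodes that survive.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .roles import NodeRole

logger = logging.getLogger("seasonet")

__all__ = [
    "RobustnessResult",
    "wmis",
    "extinction_cascade",
    "robustness_random",
    "robustness_targeted",
    "robustness_compare",
]


@dataclass
class RobustnessResult:
    scenario: str               # random_fraction | targeted_hubs
    parameter: float            # fraction removed or hub count
    values: np.ndarray          # per-repetition robustness in [0, 1]
    removed_counts: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    @property
    def n_reps(self) -> int:
        return len(self.values)


def _graph_arrays(net, abundances: pd.Series):
    g = net if isinstance(net, nx.Graph) else net.graph
    nodes = sorted(g.nodes, key=str)
    missing = [v for v in nodes if v not in abundances.index or not abundances[v] > 0]
    if missing:
        raise ValueError(f"missing/non-positive abundance for node(s): {missing[:5]}")
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w[idx[u], idx[v]] = d["r"]
        w[idx[v], idx[u]] = d["r"]
    b = abundances.loc[nodes].to_numpy(float)
    return nodes, w, b


def wmis(net, abundances: pd.Series) -> pd.Series:
    """Abundance-weighted mean interaction strength per node.

    wMIS_i = sum_j b_j s_ij / sum_j b_j over the node's neighbors; NaN for
    a node without neighbors (which a pruned network cannot contain).
    """
    nodes, w, b = _graph_arrays(net, abundances)
    adj = w != 0
    denom = adj @ b
    num = w @ b
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(vals, index=nodes, name="wMIS")


def extinction_cascade(
    w: np.ndarray,
    b: np.ndarray,
    alive: np.ndarray,
    threshold: float = 0.0,
    iterative: bool = True,
) -> np.ndarray:
    """Iterate the extinction rule to a fixed point; returns the survivor mask.

    A node dies when it has no remaining neighbor or its wMIS over the
    remaining neighbors is <= ``threshold``.  The surviving set shrinks
    monotonically and the loop ends in at most n iterations.
    """
    alive = alive.copy()
    adj = w != 0
    n = len(b)
    for _ in range(n + 1):
        if not alive.any():
            break
        mask = np.outer(alive, alive) & adj
        denom = (mask * b[None, :]).sum(axis=1)
        num = (mask * w * b[None, :]).sum(axis=1)
        with np.errstate(invalid="ignore"):
            wm = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), -np.inf)
        dead = alive & ((denom <= 0) | (wm <= threshold))
        if not dead.any():
            return alive
        alive = alive & ~dead
        if not iterative:
            return alive
    return alive


def robustness_random(
    net,
    abundances: pd.Series,
    fraction: float = 0.5,
    n_reps: int = 100,
    seed: int | None = None,
    threshold: float = 0.0,
    iterative: bool = True,
) -> RobustnessResult:
    """Robustness after removing a random fraction of taxa plus cascade.

    Per repetition: remove floor(fraction * n) uniformly chosen nodes, run
    the extinction cascade, and report survivors / n.  The study convention
    is fraction 0.5 with 100 repetitions.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    nodes, w, b = _graph_arrays(net, abundances)
    n = len(nodes)
    if n < 4:
        raise ValueError("network too small for removal simulation")
    n_remove = int(math.floor(fraction * n))
    rng = np.random.default_rng(seed)
    vals = np.empty(n_reps)
    for k in range(n_reps):
        alive = np.ones(n, bool)
        alive[rng.choice(n, size=n_remove, replace=False)] = False
        surv = extinction_cascade(w, b, alive, threshold, iterative)
        vals[k] = surv.sum() / n
    return RobustnessResult(
        scenario="random_fraction",
        parameter=fraction,
        values=vals,
        removed_counts=[n_remove] * n_reps,
    )


def robustness_targeted(
    net,
    abundances: pd.Series,
    roles: list[NodeRole],
    n_hubs: int = 5,
    n_reps: int = 100,
    seed: int | None = None,
    threshold: float = 0.0,
    iterative: bool = True,
) -> RobustnessResult:
    """Robustness after removing the top module hubs plus cascade.

    Module hubs (Zi > 2.5, including network hubs) are ranked by Zi, ties
    by Pi then node id; when equal-standing hubs straddle the cut the
    repetitions sample among the tied ones, so the sd is nondegenerate.
    Fewer hubs than requested removes all of them with a logged shortfall.
    """
    nodes, w, b = _graph_arrays(net, abundances)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    hubs = [r for r in roles if r.category in ("module_hub", "network_hub")]
    if n_hubs == 0:
        return RobustnessResult("targeted_hubs", 0, np.ones(max(n_reps, 1)), [0])
    if not hubs:
        warnings.warn("no module hubs present; robustness = 1 (nothing removed)")
        return RobustnessResult("targeted_hubs", n_hubs, np.ones(max(n_reps, 1)), [0])
    if len(hubs) < n_hubs:
        logger.warning("only %d module hub(s) available, requested %d",
                       len(hubs), n_hubs)
    ranked = sorted(hubs, key=lambda r: (-r.zi, -r.pi, str(r.otu_id)))
    take = min(n_hubs, len(ranked))
    rng = np.random.default_rng(seed)
    # fixed head: strictly above the cut; tied tail sampled per repetition
    if take < len(ranked):
        cut_key = (ranked[take - 1].zi, ranked[take - 1].pi)
        head = [r for r in ranked if (r.zi, r.pi) > cut_key]
        tied = [r for r in ranked if (r.zi, r.pi) == cut_key]
    else:
        head, tied = ranked[:take], []
    vals = np.empty(n_reps)
    removed_counts = []
    for k in range(n_reps):
        chosen = list(head)
        need = take - len(head)
        if need > 0:
            pick = rng.choice(len(tied), size=need, replace=False)
            chosen += [tied[i] for i in pick]
        alive = np.ones(n, bool)
        for r in chosen:
            alive[idx[r.otu_id]] = False
        surv = extinction_cascade(w, b, alive, threshold, iterative)
        vals[k] = surv.sum() / n
        removed_counts.append(len(chosen))
    return RobustnessResult("targeted_hubs", take, vals, removed_counts)


def robustness_compare(a: RobustnessResult, b: RobustnessResult):
    """Welch two-sided t-test on per-repetition robustness values.

    Returns (t, df, p).  Two zero-variance samples with equal means give
    p = 1 by convention.
    """
    x, y = np.asarray(a.values), np.asarray(b.values)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 repetitions per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return math.inf, float(len(x) + len(y) - 2), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return float(t), float(df), float(p)
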