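"""Normalized stochasticity ratio (NST) from taxonomic null models.

For each group of samples, observed pairwise dissimilarities D_ij are
compared with their expectation E_ij under a null assembly model that
fixes every sample's richness and draws taxa with probability proportional
to their occurrence frequency in the group.  The per-pair stochasticity
ratio is D/E when D < E (deterministic convergence), (1-D)/(1-E) when
D > E (deterministic divergence) and 1 at equality; the group NST is the
mean over pairs, in [0, 1] (reported as a percentage downstream).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OtuTable

__all__ = [
    "NstResult",
    "nst_null_communities",
    "nst",
    "nst_compare",
]

NULL_MODELS = ("proportional_occurrence_fixed_richness", "equiprobable_fixed_richness")


@dataclass
class NstResult:
    group: str
    sample_ids: list[str]
    pairs: pd.DataFrame         # columns: i, j, D, E, stochasticity
    nst: float                  # mean per-pair stochasticity in [0, 1]
    metric: str
    model: str
    n_rand: int

    @property
    def nst_percent(self) -> float:
        return 100.0 * self.nst


def _pair_stochasticity(d: float, e: float) -> float:
    if math.isclose(d, e, abs_tol=1e-12):
        return 1.0
    if d < e:
        return d / e if e > 0 else math.nan
    return (1.0 - d) / (1.0 - e) if e < 1 else math.nan


def nst_null_communities(
    table: OtuTable,
    sample_ids,
    model: str = "proportional_occurrence_fixed_richness",
    n_rand: int = 1000,
    seed: int | None = None,
    abundances: bool = False,
):
    """Null community tables for one group of samples.

    Every randomization preserves each sample's observed richness exactly;
    taxa are drawn (without replacement) with probability proportional to
    their occurrence frequency across the group (or equiprobably).  With
    ``abundances=True`` each sample's reads are redistributed among its
    null taxa multinomially with probabilities proportional to regional
    relative abundance.

    Returns a boolean array (n_rand, taxa, samples) restricted to the
    group's regional taxon pool, or (presence, counts) when abundances are
    requested, plus the list of pool taxa.
    """
    if model not in NULL_MODELS:
        raise ValueError(f"unknown null model {model!r}; choose from {NULL_MODELS}")
    sample_ids = list(sample_ids)
    if len(sample_ids) < 3:
        raise ValueError("group must have >= 3 samples")
    sub = table.subset_samples(sample_ids)
    present = sub.counts.to_numpy() > 0
    pool = present.any(axis=1)
    taxa = [t for t, keep in zip(sub.otu_ids, pool) if keep]
    present = present[pool]
    counts = sub.counts.to_numpy()[pool]
    n_taxa, n_samples = present.shape
    richness = present.sum(axis=0)
    assert (richness <= n_taxa).all()  # guaranteed: pool spans the group

    freq = present.sum(axis=1).astype(float)
    if model == "proportional_occurrence_fixed_richness":
        prob = freq / freq.sum()
    else:
        prob = np.full(n_taxa, 1.0 / n_taxa)
    regional = counts.sum(axis=1).astype(float)
    totals = counts.sum(axis=0)

    rng = np.random.default_rng(seed)
    null_presence = np.zeros((n_rand, n_taxa, n_samples), bool)
    null_counts = (
        np.zeros((n_rand, n_taxa, n_samples), np.int64) if abundances else None
    )
    for r in range(n_rand):
        # weighted sampling without replacement via exponential keys
        # (equivalent to successive draws with renormalized probabilities)
        keys = rng.exponential(size=(n_taxa, n_samples)) / prob[:, None]
        order = np.argsort(keys, axis=0)
        for s in range(n_samples):
            chosen = order[: int(richness[s]), s]
            null_presence[r, chosen, s] = True
            if abundances:
                p = regional[chosen]
                p = p / p.sum()
                null_counts[r, chosen, s] = rng.multinomial(int(totals[s]), p)
    if abundances:
        return null_presence, null_counts, taxa
    return null_presence, taxa


def _pairwise_jaccard(presence: np.ndarray) -> np.ndarray:
    """Jaccard distance matrix between columns of a boolean taxa x sample array."""
    x = presence.astype(float)
    inter = x.T @ x
    sums = x.sum(axis=0)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _pairwise_bray(counts: np.ndarray) -> np.ndarray:
    x = counts.astype(float)
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i][:, None] - x[:, i + 1:])
        tot = x[:, i][:, None] + x[:, i + 1:]
        with np.errstate(invalid="ignore"):
            dij = diff.sum(axis=0) / np.maximum(tot.sum(axis=0), 1e-300)
        d[i, i + 1:] = dij
        d[i + 1:, i] = dij
    return d


def nst(
    table: OtuTable,
    meta: pd.DataFrame,
    grouping: str = "treatment_season",
    metric: str = "jaccard",
    model: str = "proportional_occurrence_fixed_richness",
    n_rand: int = 1000,
    seed: int | None = None,
) -> dict[str, NstResult]:
    """Group-wise normalized stochasticity ratio.

    ``grouping`` is a metadata column name or "treatment_season" for the
    treatment x season cross.  Pairs whose null expectation is exactly 0
    or 1 are flagged and excluded from the group mean.
    """
    if metric not in ("jaccard", "bray_curtis"):
        raise ValueError("metric must be jaccard or bray_curtis")
    meta = meta.loc[[s for s in table.sample_ids if s in meta.index]]
    if grouping == "treatment_season":
        labels = meta["treatment"].astype(str) + ":" + meta["season"].astype(str)
    elif grouping in meta.columns:
        labels = meta[grouping].astype(str)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rng = np.random.default_rng(seed)
    results: dict[str, NstResult] = {}
    for group in sorted(labels.unique()):
        samples = list(labels.index[labels == group])
        if len(samples) < 3:
            warnings.warn(f"group {group}: fewer than 3 samples, skipped")
            continue
        results[group] = _nst_one_group(
            table, samples, group, metric, model, n_rand,
            seed=int(rng.integers(2**31 - 1)),
        )
    return results


def _nst_one_group(
    table, samples, group, metric, model, n_rand, seed
) -> NstResult:
    sub = table.subset_samples(samples)
    obs = sub.counts.to_numpy()
    obs = obs[(obs > 0).any(axis=1)]
    if metric == "jaccard":
        d_obs = _pairwise_jaccard(obs > 0)
        nulls, _ = nst_null_communities(
            table, samples, model=model, n_rand=n_rand, seed=seed
        )
        e = np.mean([_pairwise_jaccard(nulls[r]) for r in range(n_rand)], axis=0)
    else:
        d_obs = _pairwise_bray(obs)
        _, null_counts, _ = nst_null_communities(
            table, samples, model=model, n_rand=n_rand, seed=seed, abundances=True
        )
        e = np.mean([_pairwise_bray(null_counts[r]) for r in range(n_rand)], axis=0)

    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        dij, eij = float(d_obs[i, j]), float(e[i, j])
        if eij <= 0.0 or eij >= 1.0:
            st = math.nan
            warnings.warn(f"pair ({samples[i]},{samples[j]}): E={eij}, excluded")
        else:
            st = _pair_stochasticity(dij, eij)
        rows.append({"i": samples[i], "j": samples[j], "D": dij, "E": eij,
                     "stochasticity": st})
    pairs = pd.DataFrame(rows)
    finite = pairs["stochasticity"].dropna()
    return NstResult(
        group=group,
        sample_ids=list(samples),
        pairs=pairs,
        nst=float(finite.mean()) if len(finite) else math.nan,
        metric=metric,
        model=model,
        n_rand=n_rand,
    )


def nst_compare(
    a: NstResult,
    b: NstResult,
    pooled: NstResult | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Permutation test on the difference in group NST.

    ``pooled`` must be the NstResult of the union of both groups treated as
    one group (it carries per-pair stochasticity for every sample pair
    under a common null model).  Group labels are permuted over the union
    and the group NST recomputed from within-group pairs; when the number
    of distinct label splits is small, the full split space is enumerated
    and the p-value is exact.  Identical sample sets give p = 1.
    """
    set_a, set_b = set(a.sample_ids), set(b.sample_ids)
    if set_a == set_b:
        return {"observed_diff": 0.0, "p_value": 1.0, "n_perm": 0, "exact": True}
    if pooled is None:
        raise ValueError(
            "nst_compare needs the pooled NstResult over the union of both groups"
        )
    union = sorted(set_a | set_b)
    if set(pooled.sample_ids) != set(union):
        raise ValueError("pooled result does not cover the union of both groups")
    st = {
        frozenset((row.i, row.j)): row.stochasticity
        for row in pooled.pairs.itertuples()
    }

    def group_nst(sample_set) -> float:
        vals = [
            st[frozenset(p)]
            for p in itertools.combinations(sorted(sample_set), 2)
        ]
        return float(np.nanmean(vals))

    obs = abs(group_nst(set_a) - group_nst(set_b))
    n_a = len(set_a)
    n_splits = math.comb(len(union), n_a)
    if n_splits < 20:
        warnings.warn(
            f"only {n_splits} distinct label splits; exact enumeration used"
        )
    if n_splits <= max(n_perm, 20):
        diffs = []
        for combo in itertools.combinations(union, n_a):
            ga = set(combo)
            gb = set(union) - ga
            diffs.append(abs(group_nst(ga) - group_nst(gb)))
        diffs = np.asarray(diffs)
        p = float(np.mean(diffs >= obs - 1e-12))
        return {"observed_diff": obs, "p_value": p, "n_perm": n_splits, "exact": True}
    rng = np.random.default_rng(seed)
    arr = np.array(union, dtype=object)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(arr))
        ga = set(arr[perm[:n_a]])
        gb = set(arr[perm[n_a:]])
        if abs(group_nst(ga) - group_nst(gb)) >= obs - 1e-12:
            count += 1
    return {
        "observed_diff": obs,
        "p_value": (1 + count) / (1 + n_perm),
        "n_perm": n_perm,
        "exact": False,
    }
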