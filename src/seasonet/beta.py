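"""Beta-diversity analyses: PCoA, PERMANOVA, beta-dispersion, paired
warming-control divergence regression, and Mantel tests.

All permutation machinery is implemented here.  Permutation p-values use
the +1 convention p = (1 + #{perm >= obs}) / (1 + n_perm), so p is never 0.
PERMANOVA partitions the Gower-centred distance matrix with sequential
(type-I) sums of squares, adonis-style.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import orth

from .core import CommunityDistance

__all__ = [
    "PermTestResult",
    "PCoAResult",
    "pcoa",
    "permanova",
    "beta_dispersion",
    "paired_divergence_curve",
    "mantel",
]


@dataclass
class PermTestResult:
    """Result of one permutation test (or one PERMANOVA term)."""

    statistic_name: str
    observed: float
    n_perm: int
    p_value: float
    r_squared: float | None = None
    df: int | None = None
    extra: dict = field(default_factory=dict)


def _perm_p(observed: float, perms: np.ndarray) -> float:
    return (1 + int(np.sum(perms >= observed - 1e-12))) / (1 + len(perms))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray       # positive-eigenvalue axes, scaled by sqrt(lambda)
    neg_coordinates: np.ndarray   # axes for negative eigenvalues (sqrt(|lambda|))
    eigenvalues: np.ndarray       # all eigenvalues, descending

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PCo{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()

def pcoa(dist: CommunityDistance | np.ndarray, sample_ids=None) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Negative eigenvalues are reported as-is (no Lingoes/Cailliez
    correction); their axes are kept separately for the beta-dispersion
    construction.
    """
    if isinstance(dist, CommunityDistance):
        d = dist.values
        ids = dist.sample_ids
    else:
        d = np.asarray(dist, float)
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        ids = list(sample_ids) if sample_ids is not None else list(range(len(d)))
    g = _gower_center(d)
    lam, vec = np.linalg.eigh(g)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = 1e-9 * max(1.0, abs(lam).max())
    pos = lam > tol
    neg = lam < -tol
    coords = vec[:, pos] * np.sqrt(lam[pos])
    neg_coords = vec[:, neg] * np.sqrt(-lam[neg])
    return PCoAResult(list(ids), coords, neg_coords, lam)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _term_design(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Full-rank-agnostic indicator matrix for a factor or interaction."""
    parts = [p.strip() for p in term.replace("*", ":").split(":")]
    for p in parts:
        if p not in meta.columns:
            raise ValueError(f"term {term!r} references unknown column {p!r}")
        if meta[p].nunique() < 2:
            raise ValueError(f"term {p!r} has a single level")
    combo = meta[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + "\x1f" + meta[p].astype(str)
    return pd.get_dummies(combo).to_numpy(float)


def permanova(
    dist: CommunityDistance,
    meta: pd.DataFrame,
    terms=("treatment", "month", "treatment:month", "block"),
    n_perm: int = 999,
    seed: int | None = None,
    permute_within: str | None = None,
) -> list[PermTestResult]:
    """Distance-based multivariate ANOVA with sequential sums of squares.

    Terms are factor names from ``meta`` or interactions joined with ":".
    Pseudo-F per term; p-values by permutation of sample identities (free
    by default, or restricted within the levels of ``permute_within`` for a
    repeated-measures design).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    meta = meta.loc[dist.sample_ids]
    n = len(dist.sample_ids)
    g = _gower_center(dist.values)
    total_ss = float(np.trace(g))

    # sequential orthonormal bases: intercept, then each term appended
    ones = np.ones((n, 1))
    design = ones
    hats, dfs = [], []
    prev_rank = 1
    for term in terms:
        design = np.hstack([design, _term_design(meta, term)])
        basis = orth(design)
        rank = basis.shape[1]
        dfs.append(rank - prev_rank)
        hats.append(basis @ basis.T)
        prev_rank = rank
    df_res = n - prev_rank
    if df_res <= 0:
        raise ValueError("model is saturated: no residual degrees of freedom")

    hat0 = ones @ ones.T / n

    def partition(gmat: np.ndarray):
        traces = [float(np.sum(h * gmat)) for h in hats]  # tr(H G), H symmetric
        ss = np.empty(len(hats))
        prev = float(np.sum(hat0 * gmat))
        for k, t in enumerate(traces):
            ss[k] = t - prev
            prev = t
        ss_res = float(np.trace(gmat)) - traces[-1]
        return ss, ss_res

    ss_obs, ss_res_obs = partition(g)
    f_obs = (ss_obs / np.array(dfs)) / (ss_res_obs / df_res)

    rng = np.random.default_rng(seed)
    perm_f = np.empty((n_perm, len(terms)))
    groups = None
    if permute_within is not None:
        groups = [np.where(meta[permute_within] == lv)[0]
                  for lv in meta[permute_within].unique()]
    for b in range(n_perm):
        if groups is None:
            idx = rng.permutation(n)
        else:
            idx = np.arange(n)
            for gidx in groups:
                idx[gidx] = gidx[rng.permutation(len(gidx))]
        gp = g[np.ix_(idx, idx)]
        ss_p, ss_res_p = partition(gp)
        perm_f[b] = (ss_p / np.array(dfs)) / (ss_res_p / df_res)

    results = []
    for k, term in enumerate(terms):
        results.append(
            PermTestResult(
                statistic_name=f"pseudo-F[{term}]",
                observed=float(f_obs[k]),
                n_perm=n_perm,
                p_value=_perm_p(f_obs[k], perm_f[:, k]),
                r_squared=float(ss_obs[k] / total_ss),
                df=int(dfs[k]),
                extra={"ss": float(ss_obs[k])},
            )
        )
    results.append(
        PermTestResult(
            statistic_name="residual",
            observed=math.nan,
            n_perm=n_perm,
            p_value=math.nan,
            r_squared=float(ss_res_obs / total_ss),
            df=int(df_res),
            extra={"ss": float(ss_res_obs)},
        )
    )
    return results


# ---------------------------------------------------------------------------
# beta-dispersion (multivariate homogeneity of group variances)
# ---------------------------------------------------------------------------

def _dist_to_centroids(ord_res: PCoAResult, labels: np.ndarray) -> np.ndarray:
    """betadisper squared distances: positive-axis part minus negative-axis
    part, floored at 0 before the square root."""
    z = np.empty(len(labels))
    for lv in np.unique(labels):
        m = labels == lv
        c_pos = ord_res.coordinates[m].mean(axis=0)
        c_neg = ord_res.neg_coordinates[m].mean(axis=0)
        d2 = ((ord_res.coordinates[m] - c_pos) ** 2).sum(axis=1) - (
            (ord_res.neg_coordinates[m] - c_neg) ** 2
        ).sum(axis=1)
        z[m] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_b = ss_w = 0.0
    k = 0
    for lv in np.unique(labels):
        grp = values[labels == lv]
        ss_b += len(grp) * (grp.mean() - grand) ** 2
        ss_w += ((grp - grp.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, len(values) - k
    if ss_w <= 0:
        return math.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


def beta_dispersion(
    dist: CommunityDistance,
    grouping: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[PermTestResult, pd.Series]:
    """Homogeneity of multivariate dispersions around group centroids.

    Samples are embedded by PCoA; each sample's distance to its group
    centroid handles negative eigenvalue axes by subtraction (standard
    betadisper construction).  F is a one-way ANOVA on those distances;
    p by permutation of group labels.  Returns the test result and the
    per-sample distance-to-centroid series.
    """
    grouping = grouping.loc[dist.sample_ids]
    sizes = grouping.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding size-1 group(s): {small}")
        keep = grouping[~grouping.isin(small)].index.tolist()
        dist = dist.submatrix(keep)
        grouping = grouping.loc[keep]
    if grouping.nunique() < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    labels = grouping.to_numpy()
    ord_res = pcoa(dist)
    z = _dist_to_centroids(ord_res, labels)
    f_obs = _anova_f(z, labels)

    rng = np.random.default_rng(seed)
    perm_f = np.empty(n_perm)
    for b in range(n_perm):
        lab_p = labels[rng.permutation(len(labels))]
        perm_f[b] = _anova_f(_dist_to_centroids(ord_res, lab_p), lab_p)
    res = PermTestResult(
        statistic_name="betadisper-F",
        observed=float(f_obs),
        n_perm=n_perm,
        p_value=_perm_p(f_obs, perm_f),
        df=int(grouping.nunique() - 1),
    )
    return res, pd.Series(z, index=dist.sample_ids, name="dist_to_centroid")


# ---------------------------------------------------------------------------
# paired warming-control divergence over the year
# ---------------------------------------------------------------------------

def paired_divergence_curve(
    dist: CommunityDistance, meta: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Warming-control dissimilarity per (block, month), with quadratic fit.

    For each block and month the dissimilarity between the warmed and the
    control sample is extracted; the points are fitted by OLS to
    d ~ month + month^2.  Returns the table and a fit dict with
    coefficients, R^2 and the overall-F p-value.
    """
    meta = meta.loc[dist.sample_ids]
    dmat = dist.to_dataframe()
    rows = []
    for (block, month), grp in meta.groupby(["block", "month"]):
        w = grp.index[grp["treatment"] == "warming"]
        c = grp.index[grp["treatment"] == "control"]
        if len(w) != 1 or len(c) != 1:
            warnings.warn(f"block {block} month {month}: missing W/C pair, skipped")
            continue
        rows.append(
            {"block": block, "month": month,
             "dissimilarity": float(dmat.loc[w[0], c[0]])}
        )
    pairs = pd.DataFrame(rows)
    if len(pairs) < 4:
        raise ValueError("too few W-C pairs for a quadratic fit")
    x = pairs["month"].to_numpy(float)
    y = pairs["dissimilarity"].to_numpy(float)
    design = np.column_stack([np.ones_like(x), x, x ** 2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    tol = 1e-12 * max(1.0, float(np.abs(y).max()) ** 2)
    df_model, df_res = 2, len(y) - 3
    if ss_tot <= tol:
        r2, f, p = 0.0, 0.0, 1.0  # constant response: nothing to explain
    else:
        r2 = 1.0 - ss_res / ss_tot
        if df_res > 0 and ss_res > tol:
            f = (ss_tot - ss_res) / df_model / (ss_res / df_res)
            p = float(stats.f.sf(f, df_model, df_res))
        else:
            f, p = math.inf, 0.0
    fit = {
        "intercept": float(coef[0]),
        "linear": float(coef[1]),
        "quadratic": float(coef[2]),
        "r_squared": float(r2),
        "f_statistic": float(f),
        "p_value": p,
        "n_points": int(len(y)),
    }
    return pairs, fit


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    dist_a: CommunityDistance,
    dist_b,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Mantel correlation between two distance matrices on the same samples.

    Pearson r of the off-diagonal vectors; p by row/column permutation of
    the second matrix.  When n! <= n_perm the full permutation space is
    enumerated and the p-value is exact.
    """
    ids = dist_a.sample_ids
    if isinstance(dist_b, CommunityDistance):
        if set(dist_b.sample_ids) != set(ids):
            raise ValueError("sample sets differ between matrices")
        b = dist_b.submatrix(ids).values
    else:
        b = np.asarray(dist_b, float)
        if b.shape != dist_a.values.shape:
            raise ValueError("matrix shapes differ")
        if not np.allclose(b, b.T, atol=1e-10):
            raise ValueError("second matrix not symmetric")
    a = dist_a.values
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    va = a[iu]

    def corr(mat):
        return float(np.corrcoef(va, mat[iu])[0, 1])

    r_obs = corr(b)
    if math.factorial(n) <= n_perm:
        perms = [
            corr(b[np.ix_(p, p)]) for p in itertools.permutations(range(n))
        ]
        perms = np.asarray(perms)
        p_val = float(np.mean(perms >= r_obs - 1e-12))
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty(n_perm)
        for k in range(n_perm):
            idx = rng.permutation(n)
            perms[k] = corr(b[np.ix_(idx, idx)])
        p_val = _perm_p(r_obs, perms)
        n_used = n_perm
    return PermTestResult(
        statistic_name="mantel-r", observed=r_obs, n_perm=n_used, p_value=p_val
    )
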