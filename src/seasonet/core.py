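"""Core data containers and basic community operations.

The pipeline's root object is an :class:`OtuTable` — an integer read-count
matrix (OTU x sample) with optional taxonomy strings per OTU.  Sample
metadata and environmental tables are plain :class:`pandas.DataFrame`
objects validated by :func:`validate_metadata` / :func:`validate_env`.
Pairwise community dissimilarities live in :class:`CommunityDistance`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("seasonet")

__all__ = [
    "FormatError",
    "OtuTable",
    "CommunityDistance",
    "season_of_month",
    "validate_metadata",
    "validate_env",
    "rarefy",
    "relative_abundance",
    "community_distance",
    "DISTANCE_METRICS",
]


class FormatError(ValueError):
    """Raised when an input table violates the format contract."""


#: months 3-5 spring, 6-8 summer, 9-11 fall, 12/1/2 winter
_SEASONS = {
    **{m: "spring" for m in (3, 4, 5)},
    **{m: "summer" for m in (6, 7, 8)},
    **{m: "fall" for m in (9, 10, 11)},
    **{m: "winter" for m in (12, 1, 2)},
}

TREATMENTS = ("warming", "control")
SEASONS = ("spring", "summer", "fall", "winter")


def season_of_month(month: int) -> str:
    """Deterministic month -> season mapping used by the whole design."""
    try:
        return _SEASONS[int(month)]
    except KeyError:
        raise ValueError(f"month must be in 1..12, got {month!r}") from None


@dataclass
class OtuTable:
    """Integer OTU x sample count matrix with optional taxonomy.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id, columns are sample ids, values are
        non-negative integer read counts.
    taxonomy
        Optional Series (index = OTU ids) of semicolon-delimited lineage
        strings; "unclassified" ranks are permitted.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(vals < 0):
            raise FormatError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise FormatError("counts must be integral")
        if vals.dtype.kind != "i":
            self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(c.index)

    # -- convenience accessors -------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[:, list(sample_ids)].copy(), self.taxonomy)

    def subset_otus(self, otu_ids) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.counts.index]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        tax = self.taxonomy.loc[list(otu_ids)] if self.taxonomy is not None else None
        return OtuTable(self.counts.loc[list(otu_ids)].copy(), tax)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        same_tax = (
            (self.taxonomy is None and other.taxonomy is None)
            or (
                self.taxonomy is not None
                and other.taxonomy is not None
                and self.taxonomy.equals(other.taxonomy)
            )
        )
        return self.counts.equals(other.counts) and same_tax


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table.

    Required columns: ``treatment`` (warming/control), ``block`` (int >= 1),
    ``month`` (1..12).  A ``season`` column is derived from month if absent
    and checked against the month grouping if present.  Each
    (treatment, block, month) combination may occur at most once.
    """
    meta = meta.copy()
    for col in ("treatment", "block", "month"):
        if col not in meta.columns:
            raise FormatError(f"metadata missing column {col!r}")
    bad = set(meta["treatment"]) - set(TREATMENTS)
    if bad:
        raise FormatError(f"unknown treatments: {sorted(bad)}")
    meta["block"] = meta["block"].astype(int)
    meta["month"] = meta["month"].astype(int)
    if not meta["month"].between(1, 12).all():
        raise FormatError("month must be in 1..12")
    derived = meta["month"].map(season_of_month)
    if "season" in meta.columns:
        if not (meta["season"] == derived).all():
            raise FormatError("season column inconsistent with month")
    meta["season"] = derived
    key = meta[["treatment", "block", "month"]]
    if key.duplicated().any():
        raise FormatError("duplicate (treatment, block, month) combinations")
    return meta


def validate_env(env: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Range checks for an environmental table (rows = samples)."""
    env = env.copy()
    if sample_ids is not None:
        unknown = [s for s in env.index if s not in set(sample_ids)]
        if unknown:
            raise FormatError(f"env samples not in OTU table: {unknown}")
    if "pH" in env.columns:
        ph = env["pH"].dropna()
        if not ((ph > 0) & (ph < 14)).all():
            raise FormatError("pH outside (0, 14)")
    if "moisture" in env.columns:
        m = env["moisture"].dropna()
        if not ((m >= 0) & (m <= 1)).all():
            raise FormatError("moisture outside [0, 1]")
    return env


# ---------------------------------------------------------------------------
# rarefaction & abundance transforms
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int | None = None) -> OtuTable:
    """Subsample every sample to a fixed read depth without replacement.

    Sampling within a sample is multivariate hypergeometric, so no OTU can
    exceed its observed count and each retained column sums exactly to
    ``depth``.  Samples whose total is below ``depth`` are dropped with a
    warning.  All-zero OTU rows are retained — prevalence filtering is a
    downstream decision.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.depths
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        )
        logger.warning("rarefy: dropped samples %s", dropped)
    if not keep:
        raise ValueError("no sample reaches the requested depth")
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    counts = pd.DataFrame(out, index=table.counts.index)
    return OtuTable(counts, table.taxonomy)


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Proportion matrix: every column sums to 1, order preserved."""
    totals = table.depths
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return table.counts / totals


# ---------------------------------------------------------------------------
# community dissimilarity
# ---------------------------------------------------------------------------

#: supported metric -> (scipy pdist metric, use presence/absence)
DISTANCE_METRICS = {
    "bray_curtis": ("braycurtis", False),
    "sorensen": ("dice", True),
    "jaccard": ("jaccard", True),
}


@dataclass
class CommunityDistance:
    """Symmetric sample x sample dissimilarity matrix in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-10):
            raise ValueError("distance matrix diagonal not zero")
        if v.min() < -1e-10 or v.max() > 1 + 1e-10:
            raise ValueError("distances outside [0, 1]")
        self.values = np.clip((v + v.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def submatrix(self, sample_ids) -> "CommunityDistance":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityDistance(
            list(sample_ids), self.values[np.ix_(idx, idx)], self.metric
        )

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def community_distance(table: OtuTable, metric: str = "bray_curtis") -> CommunityDistance:
    """Pairwise dissimilarity between samples.

    ``bray_curtis`` uses counts; ``sorensen`` (Dice) and ``jaccard`` are
    computed on presence/absence.
    """
    if metric not in DISTANCE_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; supported: {sorted(DISTANCE_METRICS)}"
        )
    if len(table.sample_ids) < 2:
        raise ValueError("need at least two samples")
    scipy_name, binarize = DISTANCE_METRICS[metric]
    x = table.counts.to_numpy().T.astype(float)
    if binarize:
        x = (x > 0).astype(float)
    d = squareform(pdist(x, metric=scipy_name))
    return CommunityDistance(table.sample_ids, d, metric)
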