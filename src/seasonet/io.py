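"""File readers and writers: OTU tables, metadata, environment, networks.

All tabular formats are TSV.  OTU tables have OTU ids in the first column,
one column per sample, and an optional trailing ``taxonomy`` column with
semicolon-delimited ranks.  Networks are exported as GraphML or as a flat
edge list (source, target, signed_r, abs_r).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .core import FormatError, OtuTable, validate_env, validate_metadata

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_env_table",
    "write_env_table",
    "write_network",
    "read_network",
]

TAXONOMY_COLUMN = "taxonomy"


def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU count table from TSV.

    First column = OTU id; remaining numeric columns = samples; an optional
    last column named ``taxonomy`` carries lineage strings.  Ids are kept in
    file order.
    """
    if format != "tsv":
        raise ValueError(f"unsupported format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate OTU ids in {path}: {dups}")
    taxonomy = None
    if len(df.columns) and df.columns[-1] == TAXONOMY_COLUMN:
        taxonomy = df[TAXONOMY_COLUMN].copy()
        df = df.drop(columns=[TAXONOMY_COLUMN])
    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from None
    if counts.isna().to_numpy().any():
        raise FormatError(f"missing count values in {path}")
    return OtuTable(counts, taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    out = table.counts.copy()
    if table.taxonomy is not None:
        out[TAXONOMY_COLUMN] = table.taxonomy
    out.to_csv(path, sep="\t", index_label="otu_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_env_table(path, sample_ids=None) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_env(env, sample_ids)


def write_env_table(env: pd.DataFrame, path) -> None:
    env.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(net, path, format: str = "graphml") -> None:
    """Write a co-occurrence network to GraphML or an edge-list TSV.

    Edge attributes carry the signed Pearson r and |r|; node attributes
    carry taxonomy, module id, role category, Zi and Pi when available.
    """
    graph = net if isinstance(net, nx.Graph) else net.graph
    if format == "graphml":
        # GraphML cannot store None attribute values
        g = graph.copy()
        for _, data in g.nodes(data=True):
            for k in [k for k, v in data.items() if v is None]:
                del data[k]
        nx.write_graphml(g, path)
    elif format == "edge_list_tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "signed_r": data.get("r", np.nan),
                "abs_r": data.get("weight", np.nan),
            }
            for u, v, data in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "signed_r", "abs_r"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unsupported network format {format!r}")


def read_network(path) -> nx.Graph:
    """Read back a GraphML network written by :func:`write_network`."""
    return nx.read_graphml(path)
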