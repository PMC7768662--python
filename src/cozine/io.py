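"""Readers and writers: OTU tables, taxonomy tables, network outputs.

TSV is the primary format; networks are additionally written as GraphML
for interchange with graph tools, and run metadata as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .estimation import Edge, NetworkEstimate
from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_otu_table",
    "read_taxonomy",
    "write_network",
    "read_network",
    "write_adjacency",
    "read_adjacency",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_otu_table(path: str | Path, transpose: bool = False) -> CountTable:
    """Read a samples-by-taxa abundance table.

    Expected layout: first column sample identifiers, header row of taxon
    identifiers.  ``transpose=True`` reads the taxa-as-rows dialect.
    Duplicate identifiers, non-numeric cells and ragged rows are rejected
    with context.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    # pandas silently renames duplicate columns, so check the raw header
    seen: set[str] = set()
    for name in header:
        if name in seen:
            kind = "sample" if transpose else "taxon"
            raise ValueError(f"duplicate {kind} id in {path}: {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    for axis, name in ((df.index, "sample"), (df.columns, "taxon")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {name} id in {path}: {dup[0]!r}")
    bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(bad):
        raise ValueError(f"non-numeric values in column {bad[0]!r} of {path}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"missing value in column {col!r} of {path}")
    table = CountTable.from_dataframe(df)
    row_sums = table.values.sum(axis=1)
    counts_like = np.allclose(table.values, np.round(table.values))
    proportions_like = np.allclose(row_sums, 1.0, atol=1e-6)
    if not counts_like and not proportions_like:
        logger.warning(
            "%s: rows are neither integer counts nor unit-sum proportions; "
            "proceeding (the method only uses ratios)",
            path,
        )
    return table


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy table with columns taxon_id, kingdom, phylum, class,
    order, family (extra columns ignored), indexed by taxon_id."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if "taxon_id" not in df.columns:
        raise ValueError(f"{path} lacks a 'taxon_id' column")
    ranks = [r for r in TAXONOMY_RANKS if r in df.columns]
    if not ranks:
        raise ValueError(f"{path} has none of the rank columns {TAXONOMY_RANKS}")
    return df.set_index("taxon_id")[ranks]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def _to_graph(net: NetworkEstimate, taxonomy: pd.DataFrame | None = None) -> nx.Graph:
    g = nx.Graph()
    degrees = net.degrees()
    for idx, t in enumerate(net.taxon_ids):
        attrs = {"taxon": t, "degree": int(degrees[idx])}
        if taxonomy is not None and t in taxonomy.index:
            attrs.update({r: str(v) for r, v in taxonomy.loc[t].items()})
        g.add_node(t, **attrs)
    for e in net.edges:
        attrs = {
            "weight": e.weight,
            **{f"{k}_flag": int(v) for k, v in e.components.items()},
        }
        if e.stability is not None:
            attrs["stability"] = e.stability
        g.add_edge(net.taxon_ids[e.i], net.taxon_ids[e.j], **attrs)
    return g


def write_network(
    net: NetworkEstimate,
    prefix: str | Path,
    taxonomy: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write a network as edge-list TSV, adjacency TSV and GraphML.

    Returns the mapping of format name to written path.  The edge list
    has columns node1, node2, weight, g_flag, h_ij_flag, h_ji_flag,
    k_flag and, when stability has been computed, stability.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    has_stab = any(e.stability is not None for e in net.edges)
    for e in net.edges:
        row = {
            "node1": net.taxon_ids[e.i],
            "node2": net.taxon_ids[e.j],
            "weight": e.weight,
            **{f"{k}_flag": int(v) for k, v in e.components.items()},
        }
        if has_stab:
            row["stability"] = e.stability if e.stability is not None else 0.0
        rows.append(row)
    cols = ["node1", "node2", "weight", "g_flag", "h_ij_flag", "h_ji_flag", "k_flag"]
    if has_stab:
        cols.append("stability")
    edge_path = prefix.with_name(prefix.name + ".edges.tsv")
    pd.DataFrame(rows, columns=cols).to_csv(edge_path, sep="\t", index=False)

    adj_path = prefix.with_name(prefix.name + ".adjacency.tsv")
    write_adjacency(net.adjacency(), net.taxon_ids, adj_path)

    gml_path = prefix.with_name(prefix.name + ".graphml")
    nx.write_graphml(_to_graph(net, taxonomy), gml_path)
    return {"edges": edge_path, "adjacency": adj_path, "graphml": gml_path}


def read_network(edge_path: str | Path, taxon_ids: list[str] | None = None) -> NetworkEstimate:
    """Read an edge-list TSV written by :func:`write_network`.

    ``taxon_ids`` fixes the node universe (needed to represent isolated
    nodes); if omitted, the nodes appearing in edges are used, sorted.
    """
    df = pd.read_csv(edge_path, sep="\t")
    if taxon_ids is None:
        taxon_ids = sorted(set(df["node1"]) | set(df["node2"]))
    index = {t: i for i, t in enumerate(taxon_ids)}
    edges = []
    for _, row in df.iterrows():
        i, j = sorted((index[row["node1"]], index[row["node2"]]))
        comps = {
            k: bool(row.get(f"{k}_flag", 0)) for k in ("g", "h_ij", "h_ji", "k")
        }
        stab = float(row["stability"]) if "stability" in df.columns else None
        edges.append(Edge(i=i, j=j, weight=float(row["weight"]), components=comps, stability=stab))
    return NetworkEstimate(taxon_ids=tuple(taxon_ids), edges=edges)


def write_adjacency(adjacency: np.ndarray, taxon_ids, path: str | Path) -> None:
    pd.DataFrame(
        np.asarray(adjacency), index=list(taxon_ids), columns=list(taxon_ids)
    ).to_csv(path, sep="\t")


def read_adjacency(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: adjacency row and column labels differ")
    return df.to_numpy(), list(df.columns)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
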