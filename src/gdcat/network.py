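"""Signed, undirected correlation network around a query gene.

Nodes are gene-tissue combinations: the query source, its strongest
within-tissue correlates and its strongest peripheral correlates.  Edges
carry the bicor coefficient recomputed from the raw panel over
pairwise-complete subjects (so peripheral-peripheral edges exist, not
just source-spoke ones) and are kept when ``min_abs <= |r| <= max_abs``
— the 0.6 floor keeps only strong relations, the 0.99 ceiling guards
against near-duplicate transcripts.  Edge sign records correlation
direction; width is proportional to |r|.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import numpy as np

from .data_io import ExpressionPanel
from .gene_query import QueryResult, top_correlates
from .robust_corr import bicor_cross


def _node_id(gene: str, tissue: str) -> str:
    return f"{gene}@{tissue}"


def build_network(
    query: QueryResult,
    panel: ExpressionPanel,
    n_within: int = 30,
    n_peripheral: int = 30,
    min_abs: float = 0.6,
    max_abs: float = 0.99,
    q_filter: float | None = 0.1,
    min_n: int = 3,
) -> nx.Graph:
    """Build the correlation network around the query source.

    Candidate nodes are the top ``n_within`` within-tissue and top
    ``n_peripheral`` peripheral correlates ranked by |bicor|; by default
    only records at q < ``q_filter`` are eligible (set ``q_filter=None``
    to rank on |r| alone).  All pairwise bicor values among the chosen
    nodes are recomputed from the panel; zero-dispersion nodes are
    dropped with a warning.
    """
    if n_within < 0 or n_peripheral < 0:
        raise ValueError("node counts must be >= 0")
    if not (0.0 < min_abs < max_abs <= 1.0):
        raise ValueError(f"need 0 < min_abs < max_abs <= 1, got {min_abs}, {max_abs}")

    filtered = query
    if q_filter is not None:
        rec = query.records
        filtered = QueryResult(
            query.source_gene,
            query.source_tissue,
            rec.loc[rec["q"] < q_filter].reset_index(drop=True),
            query.thresholds,
        )

    nodes: list[tuple[str, str, str]] = [
        (query.source_gene, query.source_tissue, "source")
    ]
    for scope, role, count in (
        ("within", "within", n_within),
        ("peripheral", "peripheral", n_peripheral),
    ):
        if count == 0 or filtered.records.empty:
            continue
        top = top_correlates(filtered, count, scope=scope, direction="absolute")
        for _, row in top.iterrows():
            nodes.append((row["gene"], row["tissue"], role))

    vectors, kept = [], []
    for gene, tissue, role in nodes:
        v = panel.gene_vector(gene, tissue).to_numpy()
        finite = v[np.isfinite(v)]
        if finite.size == 0 or finite.std() == 0:
            warnings.warn(
                f"node {gene}@{tissue} has zero dispersion; excluded", stacklevel=2
            )
            continue
        vectors.append(v)
        kept.append((gene, tissue, role))

    G = nx.Graph()
    for gene, tissue, role in kept:
        G.add_node(_node_id(gene, tissue), gene=gene, tissue=tissue, role=role)
    if len(kept) > 1:
        X = np.vstack(vectors)
        R, _N = bicor_cross(X, X, min_n=min_n)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                r = R[i, j]
                if np.isfinite(r) and min_abs <= abs(r) <= max_abs:
                    G.add_edge(
                        _node_id(*kept[i][:2]),
                        _node_id(*kept[j][:2]),
                        r=float(r),
                        sign=int(np.sign(r)),
                        width=float(abs(r)),
                    )
    return G


EDGE_COLUMNS = ("gene_a", "tissue_a", "gene_b", "tissue_b", "bicor", "sign")


def export_graph(G: nx.Graph, path: str | Path, fmt: str = "edge-list") -> None:
    """Write the network as an edge-list TSV or as GraphML.

    The edge list carries (gene, tissue) endpoint labels, bicor and sign;
    GraphML additionally preserves node roles.
    """
    path = Path(path)
    if fmt == "edge-list":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(EDGE_COLUMNS)
            for a, b, data in sorted(G.edges(data=True)):
                na, nb = G.nodes[a], G.nodes[b]
                writer.writerow(
                    [
                        na["gene"], na["tissue"], nb["gene"], nb["tissue"],
                        f"{data['r']:.10g}", data["sign"],
                    ]
                )
    elif fmt == "graphml":
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'edge-list' or 'graphml'")


def read_edge_list(path: str | Path) -> list[tuple]:
    """Read back an exported edge list as a list of row tuples."""
    rows = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if tuple(header) != EDGE_COLUMNS:
            raise ValueError(f"unexpected edge-list header {header}")
        for row in reader:
            rows.append(
                (row[0], row[1], row[2], row[3], float(row[4]), int(row[5]))
            )
    return rows
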