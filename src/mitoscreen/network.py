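"""Interaction-network summary statistics.

Undirected protein-protein interaction graphs (e.g. a STRING export for
a gene signature) are summarized by node/edge counts, average node
degree, average local clustering coefficient, and the split between
interacting and isolated proteins.  Isolated (declared but edge-less)
nodes are part of the graph: the average degree denominator is the full
node set, and by default degree-<2 nodes contribute a local clustering
coefficient of 0 to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import pandas as pd

__all__ = ["GraphSummary", "build_graph", "load_edge_list", "graph_summary"]

DEFAULT_MIN_CONFIDENCE = 0.400


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_edges: int
    average_node_degree: float
    average_local_clustering: float
    n_interacting: int
    n_isolated: int

    def as_dict(self) -> dict:
        return asdict(self)


def build_graph(
    edges: list[tuple[str, str]],
    nodes: list[str] | None = None,
) -> nx.Graph:
    """Undirected graph from an edge list plus optional declared nodes.

    Self-loops and edge endpoints outside the declared node list are
    structural errors; duplicate pairs (either orientation) collapse to
    one edge.  Declared nodes without edges stay as isolated nodes.
    """
    offenders = [e for e in edges if e[0] == e[1]]
    if offenders:
        raise ValueError(f"self-loop edge(s) not allowed: {offenders[:5]}")
    g = nx.Graph()
    if nodes is not None:
        declared = list(dict.fromkeys(nodes))
        g.add_nodes_from(declared)
        known = set(declared)
        offenders = [e for e in edges if e[0] not in known or e[1] not in known]
        if offenders:
            raise ValueError(
                f"edge endpoint(s) not in the declared node list: {offenders[:5]}"
            )
    g.add_edges_from(edges)
    return g


def load_edge_list(
    path,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[tuple[str, str]]:
    """Read a 2- or 3-column tab-separated edge list.

    A third column is a confidence score in [0,1]; edges below
    ``min_confidence`` are dropped at load time and the score is then
    ignored.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    if df.shape[1] >= 3:
        conf = pd.to_numeric(df.iloc[:, 2], errors="coerce")
        df = df[conf >= min_confidence]
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False, name=None)]


def graph_summary(g: nx.Graph, include_low_degree: bool = True) -> GraphSummary:
    """Node/edge counts, mean degree (2|E|/|V|, 2 dp) and mean clustering.

    ``include_low_degree`` keeps degree-<2 nodes (clustering 0) in the
    clustering mean so the denominator matches the degree convention;
    switch it off to average over degree>=2 nodes only, since either
    convention appears in published network statistics.
    """
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        raise ValueError("graph has no nodes")
    degrees = dict(g.degree())
    clustering = nx.clustering(g)
    if include_low_degree:
        avg_clust = sum(clustering.values()) / n
    else:
        eligible = [v for v, d in degrees.items() if d >= 2]
        avg_clust = (
            sum(clustering[v] for v in eligible) / len(eligible) if eligible else 0.0
        )
    n_interacting = sum(1 for d in degrees.values() if d >= 1)
    return GraphSummary(
        n_nodes=n,
        n_edges=e,
        average_node_degree=round(2.0 * e / n, 2),
        average_local_clustering=avg_clust,
        n_interacting=n_interacting,
        n_isolated=n - n_interacting,
    )
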