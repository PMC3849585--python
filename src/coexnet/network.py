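"""Graph construction, components, export, and the collapsed cluster diagram.

Graphs are :class:`networkx.Graph` objects whose nodes are probeset (or
sample) ids and whose edges carry the Pearson correlation as weight ``r``.
Only endpoints of surviving edges become nodes: probesets with no
correlation at the graph threshold are absent from the graph entirely, which
is why a coexpression graph typically covers a fraction of the array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from coexnet.correlation import CorrelationEdgeList


def build_graph(edges: CorrelationEdgeList, graph_threshold: float) -> nx.Graph:
    """Build the undirected coexpression graph at ``graph_threshold``.

    The threshold must be at least the edge list's save threshold (pairs
    below the save threshold were never stored, so a lower graph threshold
    cannot be honored).  Nodes are exactly the endpoints of surviving edges.
    """
    if graph_threshold < edges.save_threshold:
        raise ValueError(
            f"graph threshold {graph_threshold} is below the save threshold "
            f"{edges.save_threshold}; pairs below the save threshold were not stored"
        )
    g = nx.Graph()
    g.add_weighted_edges_from(
        (a, b, r) for a, b, r in edges.edges if r >= graph_threshold
    )
    return g


def connected_components(graph: nx.Graph) -> list[set]:
    """Connected components, largest first; ties broken by smallest member id."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


@dataclass
class CollapsedGraph:
    """Meta-graph of clusters: one node per cluster, sized by membership.

    ``cluster_edges`` maps an unordered cluster-number pair to the exact
    count of underlying inter-cluster edges.
    """

    cluster_sizes: dict[int, int] = field(default_factory=dict)
    cluster_edges: dict[tuple[int, int], int] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for c, size in self.cluster_sizes.items():
            g.add_node(c, size=size)
        for (a, b), count in self.cluster_edges.items():
            g.add_edge(a, b, cross_edge_count=count)
        return g


def collapse_clusters(graph: nx.Graph, clusters, min_cluster_size: int = 10) -> CollapsedGraph:
    """Collapse each cluster to a single node; edges count cross-cluster links.

    Only clusters with strictly more than ``min_cluster_size`` members (of
    the graph's nodes) appear.  Two cluster nodes are joined iff at least one
    underlying edge connects a node of one to a node of the other, and the
    edge carries the exact count of such edges.  Unassigned nodes and nodes
    of excluded (small) clusters contribute no collapsed edges.
    """
    cluster_of = clusters.cluster_of if hasattr(clusters, "cluster_of") else dict(clusters)
    sizes: dict[int, int] = {}
    for node in graph.nodes:
        c = cluster_of.get(node)
        if c is not None:
            sizes[c] = sizes.get(c, 0) + 1
    kept = {c for c, s in sizes.items() if s > min_cluster_size}
    edge_counts: dict[tuple[int, int], int] = {}
    for u, v in graph.edges:
        cu, cv = cluster_of.get(u), cluster_of.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        if cu in kept and cv in kept:
            key = (cu, cv) if cu < cv else (cv, cu)
            edge_counts[key] = edge_counts.get(key, 0) + 1
    return CollapsedGraph(
        cluster_sizes={c: sizes[c] for c in sorted(kept)},
        cluster_edges=edge_counts,
    )


def export_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Export a graph as GraphML (attributes preserved, ids XML-escaped) or
    as an edge TSV readable by the ``.pearson`` reader."""
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge_tsv":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("node_a\tnode_b\tr\n")
            for u, v, data in sorted(graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
                if v < u:
                    u, v = v, u
                fh.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6f}\n")
    else:
        raise ValueError(f"unknown format {format!r}")
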