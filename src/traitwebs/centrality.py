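"""Node centrality on the two-mode interaction graph.

Degree is normalized against the opposite node set; closeness and
betweenness are computed on the full bipartite vertex set with unweighted
shortest paths.  Closeness uses the Wasserman-Faust component scaling
``((c - 1) / sum d) * ((c - 1) / (N - 1))`` so disconnected graphs stay in
[0, 1]; betweenness is normalized by ``(N - 1)(N - 2) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "CentralityReport",
    "to_graph",
    "normalized_degree",
    "closeness",
    "betweenness",
    "centrality_report",
    "most_central",
]


@dataclass
class CentralityReport:
    """Per-node centralities; ``nodes`` maps node id -> metric dict."""

    nodes: dict[str, dict]

    def values(self, metric: str) -> dict[str, float]:
        return {n: d[metric] for n, d in self.nodes.items()}


def to_graph(net, weighted: bool = False) -> nx.Graph:
    """Undirected bipartite graph with an edge per nonzero cell.

    Vertices are the node labels of both sides (``bipartite`` attribute 0
    for plants, 1 for bees); weights are attached when requested but the
    default metrics ignore them.
    """
    G = nx.Graph()
    G.add_nodes_from(net.row_labels, bipartite=0, side="plant")
    G.add_nodes_from(net.col_labels, bipartite=1, side="bee")
    for i, rlab in enumerate(net.row_labels):
        for j, clab in enumerate(net.col_labels):
            w = int(net.matrix[i, j])
            if w:
                if weighted:
                    G.add_edge(rlab, clab, weight=w)
                else:
                    G.add_edge(rlab, clab)
    return G


def normalized_degree(net) -> dict[str, float]:
    """Binary degree divided by the size of the opposite node set."""
    M = np.asarray(net.matrix)
    P, A = M.shape
    out: dict[str, float] = {}
    for i, rlab in enumerate(net.row_labels):
        out[rlab] = float(np.count_nonzero(M[i]) / A)
    for j, clab in enumerate(net.col_labels):
        out[clab] = float(np.count_nonzero(M[:, j]) / P)
    return out


def closeness(graph: nx.Graph) -> dict[str, float]:
    """Component-scaled closeness centrality in [0, 1] (0 for singletons)."""
    return {n: float(v) for n, v in nx.closeness_centrality(graph, wf_improved=True).items()}


def betweenness(graph: nx.Graph) -> dict[str, float]:
    """Shortest-path betweenness normalized by (N-1)(N-2)/2."""
    return {n: float(v) for n, v in nx.betweenness_centrality(graph, normalized=True).items()}


def centrality_report(net) -> CentralityReport:
    """All three centralities plus component membership for every node."""
    G = to_graph(net)
    nd = normalized_degree(net)
    cl = closeness(G)
    bt = betweenness(G)
    comp_of: dict[str, int] = {}
    for cid, comp in enumerate(sorted(nx.connected_components(G), key=lambda c: sorted(c)[0])):
        for node in comp:
            comp_of[node] = cid
    sides = dict.fromkeys(net.row_labels, "plant") | dict.fromkeys(net.col_labels, "bee")
    nodes = {
        n: {
            "side": sides[n],
            "normalized_degree": nd[n],
            "closeness": cl[n],
            "betweenness": bt[n],
            "component": comp_of[n],
        }
        for n in list(net.row_labels) + list(net.col_labels)
    }
    return CentralityReport(nodes=nodes)


def most_central(
    report: CentralityReport,
    metric: str,
    side: str | None = None,
) -> list[tuple[str, float, int]]:
    """Nodes ranked by a metric, descending; ties share a (competition) rank."""
    items = [
        (n, d[metric])
        for n, d in report.nodes.items()
        if side is None or d["side"] == side
    ]
    items.sort(key=lambda t: (-t[1], t[0]))
    ranked: list[tuple[str, float, int]] = []
    for node, value in items:
        rank = 1 + sum(1 for _, v in items if v > value)
        ranked.append((node, value, rank))
    return ranked
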