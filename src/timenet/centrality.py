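"""Shortest-path centralities on collapsed structure networks.

Betweenness centrality (BC) and characteristic-path-length centrality
(CPLC) are classic single-structure scores: multi-edges and timelines are
collapsed to an unweighted simple graph -- an edge exists wherever any
interaction type connects two nodes in at least one frame -- and
interaction magnitude is deliberately ignored.

The characteristic path length L is the mean shortest-path length over
*connected* unordered node pairs; disconnected pairs are excluded rather
than assigned infinite distance, which keeps CPLC = L - L_i finite when a
deletion splits the graph.  The alternative convention of skipping
disconnecting deletions entirely is available via ``on_disconnect``.
Both scores are min-max normalized across nodes, an all-equal vector
mapping to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import StructureNetwork
from .scores import ScoreTable, min_max_normalize

__all__ = [
    "collapse",
    "PathStatistics",
    "path_statistics",
    "betweenness",
    "cplc",
]


def collapse(network: StructureNetwork | nx.Graph) -> nx.Graph:
    """Collapse a timeline network to an unweighted simple graph.

    All nodes are kept (isolated nodes included); an edge is present when
    any interaction type connects the pair in at least one frame.
    """
    if isinstance(network, nx.Graph):
        return network
    graph = nx.Graph()
    graph.add_nodes_from(sorted(network.nodes))
    for (u, v, _kind) in network.sorted_edge_keys():
        if network.edges[(u, v, _kind)].timeline.values.any():
            graph.add_edge(u, v)
    return graph


def _mean_path_length(graph: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path length and count over connected unordered pairs."""
    total = 0
    n_pairs = 0
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        k = len(component)
        n_pairs += k * (k - 1) // 2
    if n_pairs == 0:
        return float("nan"), 0
    # each unordered pair counted twice in the double loop
    return total / (2 * n_pairs), n_pairs


@dataclass
class PathStatistics:
    """All-pairs shortest-path summary of a collapsed network."""

    distances: dict[tuple[str, str], int]  # connected unordered pairs, u < v
    path_counts: dict[tuple[str, str], int]  # sigma_jk for those pairs
    characteristic_path_length: float
    n_connected_pairs: int


def _count_shortest_paths(graph: nx.Graph, source) -> tuple[dict, dict]:
    """BFS distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for w in graph.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        queue = nxt
    return dist, sigma


def path_statistics(network: StructureNetwork | nx.Graph) -> PathStatistics:
    """Distances, shortest-path counts and characteristic path length."""
    graph = collapse(network)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    distances: dict[tuple[str, str], int] = {}
    counts: dict[tuple[str, str], int] = {}
    for source in graph.nodes:
        dist, sigma = _count_shortest_paths(graph, source)
        for target, d in dist.items():
            if source < target:
                distances[(source, target)] = d
                counts[(source, target)] = sigma[target]
    L, n_pairs = _mean_path_length(graph)
    return PathStatistics(distances, counts, L, n_pairs)


def betweenness(network: StructureNetwork | nx.Graph) -> ScoreTable:
    """Min-max normalized betweenness centrality.

    Raw scores sum, over unordered pairs (j, k) with i not an endpoint, the
    fraction of shortest j-k paths passing through i.
    """
    graph = collapse(network)
    raw = nx.betweenness_centrality(graph, normalized=False)
    return ScoreTable(
        min_max_normalize(raw), method="BC", params={"normalized": "min-max"}
    )


def cplc(
    network: StructureNetwork | nx.Graph, on_disconnect: str = "exclude-pairs"
) -> ScoreTable:
    """Min-max normalized characteristic path length centrality.

    CPLC_i = L - L_i with L_i recomputed after deleting node i.  With
    ``on_disconnect="exclude-pairs"`` (default) pairs disconnected by the
    deletion are simply excluded from L_i; with ``"skip-node"`` a deletion
    that increases the number of connected components scores 0.
    """
    if on_disconnect not in ("exclude-pairs", "skip-node"):
        raise ValueError(f"unknown on_disconnect mode {on_disconnect!r}")
    graph = collapse(network)
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    L, _ = _mean_path_length(graph)
    n_components = nx.number_connected_components(graph)
    raw: dict[str, float] = {}
    for node in graph.nodes:
        rest = graph.subgraph(n for n in graph.nodes if n != node)
        if rest.number_of_nodes() == 0:
            raw[node] = 0.0
            continue
        if (
            on_disconnect == "skip-node"
            and nx.number_connected_components(rest) > n_components
        ):
            raw[node] = 0.0
            continue
        L_i, n_pairs = _mean_path_length(rest)
        raw[node] = 0.0 if n_pairs == 0 or np.isnan(L) else L - L_i
    return ScoreTable(
        min_max_normalize(raw),
        method="CPLC",
        params={"normalized": "min-max", "on_disconnect": on_disconnect},
    )
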