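"""Independent brute-force oracles for the scoring algorithms.

Everything here is written from the defining formulas, literally and
inefficiently, and deliberately shares no code path with the package:
mutual information is summed state-by-state from dict histograms, the
edge-neighborhood indicator is evaluated over ordered node pairs against
the per-type adjacency matrices, and centralities come from exhaustive
shortest-path enumeration and node-deletion recomputation.
"""

from __future__ import annotations

import itertools
import math


def hist(values) -> dict:
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return {k: c / len(values) for k, c in counts.items()}


def joint_hist(x, y) -> dict:
    counts: dict = {}
    for a, b in zip(x, y):
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return {k: c / len(x) for k, c in counts.items()}


def brute_mi(x, y) -> float:
    """Literal plug-in mutual information in bits."""
    x, y = list(x), list(y)
    px, py, pxy = hist(x), hist(y), joint_hist(x, y)
    total = 0.0
    for (a, b), p in pxy.items():
        total += p * math.log2(p / (px[a] * py[b]))
    return total


def brute_diff_mi(x, y, x_ref=None, y_ref=None) -> float:
    """Pointwise MI difference summed over the union state alphabets."""
    x, y = list(x), list(y)
    x_ref = list(x_ref) if x_ref is not None else []
    y_ref = list(y_ref) if y_ref is not None else []
    px, py, pxy = hist(x), hist(y), joint_hist(x, y)
    pxr = hist(x_ref) if x_ref else {}
    pyr = hist(y_ref) if y_ref else {}
    pxyr = joint_hist(x_ref, y_ref) if x_ref else {}
    total = 0.0
    for a in set(px) | set(pxr):
        for b in set(py) | set(pyr):
            p = pxy.get((a, b), 0.0)
            if p > 0:
                total += p * math.log2(p / (px[a] * py[b]))
            pr = pxyr.get((a, b), 0.0)
            if pr > 0:
                total -= pr * math.log2(pr / (pxr[a] * pyr[b]))
    return total


def _adjacency(network):
    """Per-type dense adjacency dicts A[l][(n, m)] with symmetric entries."""
    A: dict = {}
    for (u, v, l) in network.edges:
        A.setdefault(l, {})[(u, v)] = 1
        A[l][(v, u)] = 1
    return A


def chi(i, j, k, n, m, l) -> int:
    """Literal neighbor-selection indicator over one ordered pair."""
    d_in = int(i == n)
    d_jm = int(j == m)
    d_kl = int(k == l)
    return d_in + d_jm - d_in * d_jm * (d_kl + 1)


def brute_ecf(network, focal, reference=None) -> float:
    """ECF by full ordered-pair enumeration of the indicator function."""
    i, j, k = focal
    A = _adjacency(network)
    x_focal = network.edges[focal].timeline.values.tolist()
    nodes = sorted(network.nodes)
    total = 0.0
    for l in sorted(A):
        for n, m in itertools.product(nodes, nodes):
            if A[l].get((n, m), 0) == 0:
                continue
            weight = chi(i, j, k, n, m, l)
            if weight == 0:
                continue
            u, v = (n, m) if n <= m else (m, n)
            y = network.edges[(u, v, l)].timeline.values.tolist()
            if reference is None:
                total += weight * brute_mi(x_focal, y)
            else:
                rf = focal if focal in reference.edges else None
                rn = (u, v, l) if (u, v, l) in reference.edges else None
                if rf is None or rn is None:
                    total += weight * brute_diff_mi(x_focal, y)
                else:
                    total += weight * brute_diff_mi(
                        x_focal,
                        y,
                        reference.edges[rf].timeline.values.tolist(),
                        reference.edges[rn].timeline.values.tolist(),
                    )
    return total


def brute_ncf(network, reference=None) -> dict:
    """Per-node sum of adjacent-edge brute-force ECF scores."""
    scores = {node: 0.0 for node in network.nodes}
    for key in network.edges:
        value = brute_ecf(network, key, reference)
        scores[key[0]] += value
        scores[key[1]] += value
    return scores


# -- shortest-path oracles ---------------------------------------------------


def _neighbors(graph) -> dict:
    adj = {n: set() for n in graph.nodes}
    for u, v in graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _bfs_distances(adj, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def enumerate_shortest_paths(adj, source, target, max_len) -> list:
    """All simple shortest paths, by depth-pruned exhaustive DFS."""
    paths = []

    def walk(path):
        head = path[-1]
        if head == target:
            paths.append(list(path))
            return
        if len(path) - 1 >= max_len:
            return
        for w in sorted(adj[head]):
            if w not in path:
                path.append(w)
                walk(path)
                path.pop()

    walk([source])
    return paths


def brute_betweenness_raw(graph) -> dict:
    """Raw betweenness by explicit shortest-path enumeration."""
    adj = _neighbors(graph)
    nodes = sorted(graph.nodes)
    scores = {n: 0.0 for n in nodes}
    for j, k in itertools.combinations(nodes, 2):
        dist = _bfs_distances(adj, j)
        if k not in dist:
            continue
        paths = enumerate_shortest_paths(adj, j, k, dist[k])
        sigma = len(paths)
        for i in nodes:
            if i in (j, k):
                continue
            through = sum(1 for p in paths if i in p[1:-1])
            scores[i] += through / sigma
    return scores


def brute_mean_path_length(graph, exclude=None):
    """(L, n_connected_pairs) over connected unordered pairs."""
    adj = _neighbors(graph)
    if exclude is not None:
        adj = {
            n: {w for w in ws if w != exclude}
            for n, ws in adj.items()
            if n != exclude
        }
    nodes = sorted(adj)
    total, pairs = 0, 0
    for j, k in itertools.combinations(nodes, 2):
        dist = _bfs_distances(adj, j)
        if k in dist:
            total += dist[k]
            pairs += 1
    if pairs == 0:
        return float("nan"), 0
    return total / pairs, pairs


def brute_cplc_raw(graph) -> dict:
    L, _ = brute_mean_path_length(graph)
    scores = {}
    for node in sorted(graph.nodes):
        L_i, pairs = brute_mean_path_length(graph, exclude=node)
        scores[node] = 0.0 if pairs == 0 or math.isnan(L) else L - L_i
    return scores


def minmax(scores: dict) -> dict:
    vals = list(scores.values())
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return {k: 0.0 for k in scores}
    return {k: (v - lo) / (hi - lo) for k, v in scores.items()}
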