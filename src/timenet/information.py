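"""Mutual-information scoring of interaction timelines.

The conformational coupling of a residue to its environment is estimated
from the information shared between the timeline of each of its
interactions and the timelines of the neighboring interactions (edges
separated by at most a single node):

* ``ECF`` (edge neighbor correlation factor) of an edge is the sum of the
  mutual information, in bits, between that edge's timeline and each
  neighboring edge's timeline.  The edge's self-information is excluded;
  a parallel edge (same endpoints, different interaction type) counts
  exactly once, as does an edge sharing a single endpoint.
* ``NCF`` (node correlation factor) of a node is the sum of the ECF scores
  of its adjacent edges.
* ``DNCF`` (difference NCF) replaces each mutual-information term by the
  difference between the target network's term and the term of the
  matching edge pair in a reference network (e.g. ligand-free vs bound),
  so it highlights residues whose interaction coupling changes between the
  two simulations.  Edges present only in the reference do not contribute,
  which makes the score asymmetric under swapping target and reference.

All probabilities are plug-in (maximum-likelihood) estimates over the raw
integer states of the timelines -- no binning, no bias correction.  The
finite-sample bias of the plug-in estimator is characterised in the test
suite rather than corrected for.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .network import EdgeKey, StructureNetwork, Timeline
from .scores import ScoreTable

__all__ = [
    "entropy",
    "mutual_information",
    "difference_mutual_information",
    "edge_neighborhood",
    "ecf",
    "ecf_table",
    "ncf",
    "dncf",
    "match_edges",
]


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, Timeline) else np.asarray(x)


def entropy(x) -> float:
    """Plug-in Shannon entropy, in bits, of a timeline's state histogram."""
    vals = _values(x)
    _, counts = np.unique(vals, return_counts=True)
    p = counts / vals.size
    return float(-np.sum(p * np.log2(p)))


def _joint_probs(x: np.ndarray, y: np.ndarray):
    """Joint and marginal plug-in probabilities of paired per-frame states."""
    if x.size != y.size:
        raise ValueError(f"timeline lengths differ: {x.size} != {y.size}")
    pairs = np.stack([x, y], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    pxy = counts / x.size
    # marginals for each observed joint state
    xs, xc = np.unique(x, return_counts=True)
    ys, yc = np.unique(y, return_counts=True)
    px = dict(zip(xs.tolist(), (xc / x.size).tolist()))
    py = dict(zip(ys.tolist(), (yc / y.size).tolist()))
    return uniq, pxy, px, py


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) in bits between two timelines.

    Summation runs over the observed joint states; zero-probability terms
    contribute nothing.  The estimate is symmetric, nonnegative and bounded
    by min(H(X), H(Y)) up to floating-point round-off.
    """
    xv, yv = _values(x), _values(y)
    uniq, pxy, px, py = _joint_probs(xv, yv)
    total = 0.0
    for (xs, ys), p in zip(uniq.tolist(), pxy.tolist()):
        total += p * np.log2(p / (px[xs] * py[ys]))
    return max(0.0, float(total))


def difference_mutual_information(x, y, x_ref=None, y_ref=None) -> float:
    """Difference of plug-in MI between a target and a reference edge pair.

    The sum over the union of target and reference state alphabets splits
    into the two networks' own MI sums (states unobserved in a network have
    zero probability there), so the result is I(X;Y) - I(X_ref;Y_ref), each
    estimated within its own network.  Target and reference frame counts
    may differ.  With the reference pair absent (None) or constant the
    reference term is zero and the result reduces to I(X;Y).  Unlike plain
    MI the difference may be negative.
    """
    target = mutual_information(x, y)
    if x_ref is None or y_ref is None:
        return target
    return target - mutual_information(x_ref, y_ref)


def edge_neighborhood(network: StructureNetwork, edge_key: EdgeKey) -> list[EdgeKey]:
    """Neighboring edges of a focal edge, in canonical order.

    An edge neighbors the focal edge when the two share at least one
    endpoint: parallel edges (both endpoints shared, different type) and
    single-endpoint neighbors each appear exactly once; the focal edge
    itself never does.
    """
    if edge_key not in network.edges:
        raise KeyError(f"edge {edge_key} not in network")
    u, v, _ = edge_key
    return [
        k
        for k in network.sorted_edge_keys()
        if k != edge_key and (k[0] in (u, v) or k[1] in (u, v))
    ]


def match_edges(
    target: StructureNetwork, reference: StructureNetwork
) -> tuple[dict[EdgeKey, EdgeKey | None], list[EdgeKey]]:
    """Match-location edge mapping between two same-grain networks.

    Edges are equivalent when they connect the same node identifiers with
    the same interaction type.  Returns the target->reference mapping (None
    where the reference lacks the edge) and the list of reference-only
    edges, which never contribute to difference scores.
    """
    if target.grain != reference.grain:
        raise ValueError(
            f"grain mismatch: target is {target.grain}-grain, "
            f"reference is {reference.grain}-grain"
        )
    mapping: dict[EdgeKey, EdgeKey | None] = {
        k: (k if k in reference.edges else None) for k in target.sorted_edge_keys()
    }
    reference_only = [k for k in reference.sorted_edge_keys() if k not in target.edges]
    return mapping, reference_only


def _edge_pair_term(
    network: StructureNetwork,
    focal: EdgeKey,
    neighbor: EdgeKey,
    reference: StructureNetwork | None,
    mapping: Mapping[EdgeKey, EdgeKey | None] | None,
) -> float:
    x = network.edges[focal].timeline
    y = network.edges[neighbor].timeline
    if reference is None:
        return mutual_information(x, y)
    rf = mapping.get(focal)
    rn = mapping.get(neighbor)
    if rf is None or rn is None:
        # an unmatched target edge behaves as a constant reference timeline
        return difference_mutual_information(x, y)
    return difference_mutual_information(
        x, y, reference.edges[rf].timeline, reference.edges[rn].timeline
    )


def ecf(
    network: StructureNetwork,
    edge_key: EdgeKey,
    reference: StructureNetwork | None = None,
) -> float:
    """Edge neighbor correlation factor of one edge, in bits.

    With a reference network, each term is the difference MI of the matched
    edge pairs ("Match Location" semantics); an isolated edge scores 0.
    """
    mapping = None
    if reference is not None:
        mapping, _ = match_edges(network, reference)
    return sum(
        _edge_pair_term(network, edge_key, nb, reference, mapping)
        for nb in edge_neighborhood(network, edge_key)
    )


def ecf_table(
    network: StructureNetwork, reference: StructureNetwork | None = None
) -> dict[EdgeKey, float]:
    """ECF (or difference-ECF) for every edge, in canonical order."""
    mapping = None
    if reference is not None:
        mapping, _ = match_edges(network, reference)
    out: dict[EdgeKey, float] = {}
    for key in network.sorted_edge_keys():
        out[key] = sum(
            _edge_pair_term(network, key, nb, reference, mapping)
            for nb in edge_neighborhood(network, key)
        )
    return out


def ncf(
    network: StructureNetwork, reference: StructureNetwork | None = None
) -> ScoreTable:
    """Node correlation factor: per-node sum of adjacent-edge ECF scores.

    With a reference network supplied this is the DNCF score table.
    Isolated nodes score 0.  Scores are reported in raw bits.
    """
    per_edge = ecf_table(network, reference)
    scores = {node_id: 0.0 for node_id in sorted(network.nodes)}
    for (u, v, _kind), value in per_edge.items():
        scores[u] += value
        scores[v] += value
    method = "NCF" if reference is None else "DNCF"
    return ScoreTable(scores, method=method)


def dncf(network: StructureNetwork, reference: StructureNetwork) -> ScoreTable:
    """Difference node correlation factor against a reference network."""
    return ncf(network, reference=reference)
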