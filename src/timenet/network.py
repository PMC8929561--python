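"""Timeline-carrying protein structure networks.

A structure network maps atoms (or groups of atoms, typically residues) to
nodes and physical interactions -- carbon contacts, hydrogen bonds -- to
edges.  Each edge carries a *timeline*: one nonnegative interaction count
per frame of the underlying structure ensemble.  A network built from a
single structure is the degenerate case where every timeline has length
one.

Nodes at atom grain hold exactly one atom; group-grain nodes (residues by
default) hold a disjoint set of member atoms.  A node pair may be connected
by several edges of different interaction types, so the edge set is keyed
by ``(node_u, node_v, type)`` with endpoints in canonical (lexicographic)
order.  The per-type adjacency matrix is symmetric with zero diagonal and
has a 1 exactly where an edge of that type exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Timeline",
    "TimelineRecord",
    "NetworkNode",
    "InteractionEdge",
    "StructureNetwork",
    "build_network",
    "aggregate_to_groups",
    "residue_grouping",
    "split_node",
    "filter_network",
    "residue_network",
    "atom_name_of",
    "residue_id_of",
    "residue_name_of",
    "is_sidechain_atom",
]

#: Backbone atom names of standard amino acids.  Everything else, including
#: CB, counts as sidechain; glycine therefore has no sidechain atoms.
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)


def atom_name_of(atom_id: str) -> str:
    """Atom name field of a ``chain:resnum:resname:atom`` identifier."""
    parts = atom_id.split(":")
    if len(parts) != 4:
        raise ValueError(f"not an atom identifier: {atom_id!r}")
    return parts[3]


def residue_id_of(atom_id: str) -> str:
    """Residue identifier (``chain:resnum:resname``) of an atom identifier."""
    parts = atom_id.split(":")
    if len(parts) != 4:
        raise ValueError(f"not an atom identifier: {atom_id!r}")
    return ":".join(parts[:3])


def residue_name_of(node_id: str) -> str:
    """Residue name field of an atom or residue identifier."""
    parts = node_id.split(":")
    if len(parts) not in (3, 4):
        raise ValueError(f"not a residue or atom identifier: {node_id!r}")
    return parts[2]


def is_sidechain_atom(atom_id: str) -> bool:
    return atom_name_of(atom_id) not in BACKBONE_ATOMS


class Timeline:
    """Per-frame interaction counts for one edge.

    Atomistic timelines are binary (the interaction exists in a frame or it
    does not); group-grain timelines are frame-wise sums over the member
    atom pairs and may exceed 1.

    Parameters
    ----------
    values
        Sequence of nonnegative integers, one per frame.  Length >= 1.
    """

    __slots__ = ("values",)

    def __init__(self, values: Sequence[int] | np.ndarray):
        arr = np.asarray(values)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("timeline must be a non-empty 1-d sequence")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded):
                raise ValueError("timeline values must be integers")
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise ValueError("timeline values must be nonnegative")
        arr.setflags(write=False)
        self.values = arr

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Timeline):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    def __repr__(self) -> str:
        vals = ",".join(str(v) for v in self.values[:8])
        more = ",..." if len(self) > 8 else ""
        return f"Timeline([{vals}{more}], T={len(self)})"

    @property
    def is_binary(self) -> bool:
        return bool((self.values <= 1).all())

    def occupancy(self) -> float:
        """Fraction of frames in which the interaction is present (> 0)."""
        return float(np.mean(self.values > 0))


@dataclass(frozen=True)
class TimelineRecord:
    """One atom-atom interaction timeline, the unit of network input.

    ``flags`` carries provenance markers such as ``"distance-only"`` for
    hydrogen bonds detected without explicit hydrogens.
    """

    source: str
    target: str
    kind: str
    timeline: Timeline
    flags: tuple[str, ...] = ()

    def canonical_pair(self) -> tuple[str, str]:
        a, b = self.source, self.target
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class NetworkNode:
    """Atom- or group-grain network node.

    ``member_atoms`` is a singleton for atom-grain nodes and the (disjoint
    across nodes) set of constituent atoms for group-grain nodes.
    """

    id: str
    grain: str  # "atom" | "group"
    member_atoms: frozenset[str]

    def __post_init__(self):
        if self.grain not in ("atom", "group"):
            raise ValueError(f"unknown grain {self.grain!r}")
        if self.grain == "atom" and len(self.member_atoms) != 1:
            raise ValueError("atom-grain node must have exactly one member atom")


@dataclass(frozen=True)
class InteractionEdge:
    """Typed edge with a timeline; endpoints stored in canonical order.

    ``members`` retains the atomistic records a group-grain edge was
    aggregated from, enabling node splitting and sidechain filtering.
    """

    u: str
    v: str
    kind: str
    timeline: Timeline
    members: tuple[TimelineRecord, ...] | None = None

    def __post_init__(self):
        if self.u == self.v:
            raise ValueError(f"self-edge on node {self.u!r}")
        if self.u > self.v:
            raise ValueError("edge endpoints not in canonical order")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.u, self.v, self.kind)


EdgeKey = tuple[str, str, str]


class StructureNetwork:
    """Set of nodes plus typed timeline edges over ``n_frames`` frames."""

    def __init__(
        self,
        nodes: Iterable[NetworkNode],
        edges: Iterable[InteractionEdge],
        n_frames: int,
    ):
        if n_frames < 1:
            raise ValueError("frame count must be >= 1")
        self.n_frames = int(n_frames)
        self.nodes: dict[str, NetworkNode] = {}
        seen_atoms: set[str] = set()
        for node in nodes:
            if node.id in self.nodes:
                raise ValueError(f"duplicate node {node.id!r}")
            overlap = seen_atoms.intersection(node.member_atoms)
            if overlap:
                raise ValueError(
                    f"member atoms {sorted(overlap)} shared between nodes"
                )
            seen_atoms.update(node.member_atoms)
            self.nodes[node.id] = node
        self.edges: dict[EdgeKey, InteractionEdge] = {}
        for edge in edges:
            if edge.u not in self.nodes or edge.v not in self.nodes:
                raise ValueError(f"edge {edge.key} references unknown node")
            if len(edge.timeline) != self.n_frames:
                raise ValueError(
                    f"edge {edge.key}: timeline length {len(edge.timeline)} "
                    f"!= frame count {self.n_frames}"
                )
            if edge.key in self.edges:
                raise ValueError(f"duplicate edge {edge.key}")
            self.edges[edge.key] = edge

    # -- basic introspection -------------------------------------------------

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(sorted({e.kind for e in self.edges.values()}))

    @property
    def grain(self) -> str:
        grains = {n.grain for n in self.nodes.values()}
        if grains == {"atom"}:
            return "atom"
        if grains == {"group"}:
            return "group"
        return "mixed"

    def sorted_edge_keys(self) -> list[EdgeKey]:
        """Deterministic (canonical lexicographic) edge iteration order."""
        return sorted(self.edges)

    def edges_of(self, node_id: str) -> list[InteractionEdge]:
        if node_id not in self.nodes:
            raise KeyError(node_id)
        return [
            self.edges[k]
            for k in self.sorted_edge_keys()
            if node_id in (k[0], k[1])
        ]

    def atom_to_node(self) -> dict[str, str]:
        return {
            atom: node.id
            for node in self.nodes.values()
            for atom in node.member_atoms
        }

    def adjacency_matrix(self, kind: str) -> tuple[list[str], np.ndarray]:
        """Symmetric 0/1 adjacency for one interaction type.

        Returns the sorted node identifiers and the matrix indexed by them.
        """
        ids = sorted(self.nodes)
        index = {n: i for i, n in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)), dtype=np.int8)
        for (u, v, k) in self.edges:
            if k == kind:
                mat[index[u], index[v]] = 1
                mat[index[v], index[u]] = 1
        return ids, mat

    def __repr__(self) -> str:
        return (
            f"StructureNetwork({len(self.nodes)} nodes, "
            f"{len(self.edges)} edges, T={self.n_frames})"
        )


def build_network(
    records: Iterable[TimelineRecord], n_frames: int
) -> StructureNetwork:
    """Assemble an atom-grain network from atom-atom timeline records.

    Every record must carry a timeline of exactly ``n_frames`` frames and
    distinct endpoint atoms; a second record for the same (pair, type) is an
    error rather than silently merged.
    """
    nodes: dict[str, NetworkNode] = {}
    edges: dict[EdgeKey, InteractionEdge] = {}
    for rec in records:
        if rec.source == rec.target:
            raise ValueError(f"record {rec.source!r}: endpoints identical")
        if len(rec.timeline) != n_frames:
            raise ValueError(
                f"record {rec.source}--{rec.target} ({rec.kind}): timeline "
                f"length {len(rec.timeline)} != frame count {n_frames}"
            )
        u, v = rec.canonical_pair()
        key = (u, v, rec.kind)
        if key in edges:
            raise ValueError(f"duplicate record for edge {key}")
        for atom in (u, v):
            if atom not in nodes:
                nodes[atom] = NetworkNode(atom, "atom", frozenset({atom}))
        edges[key] = InteractionEdge(u, v, rec.kind, rec.timeline, members=(rec,))
    return StructureNetwork(nodes.values(), edges.values(), n_frames)


def residue_grouping(network: StructureNetwork) -> dict[str, str]:
    """Default atom -> residue grouping derived from atom identifiers."""
    return {
        atom: residue_id_of(atom)
        for node in network.nodes.values()
        for atom in node.member_atoms
    }


def aggregate_to_groups(
    network: StructureNetwork, grouping: Mapping[str, str]
) -> StructureNetwork:
    """Coarsen an atom-grain network to groups (typically residues).

    The timeline of a group-pair edge is the frame-wise sum of the member
    atomistic timelines, so per-frame interaction counts between any two
    groups are conserved.  Interactions internal to one group are dropped
    (no self-edges).  The atomistic records are retained on each edge so the
    aggregation can be inverted by :func:`split_node`.
    """
    if network.grain != "atom":
        raise ValueError("aggregation requires an atom-grain network")
    missing = [a for a in network.nodes if a not in grouping]
    if missing:
        raise ValueError(f"atoms missing from grouping: {sorted(missing)[:5]}")

    members: dict[str, set[str]] = {}
    for atom in network.nodes:
        members.setdefault(grouping[atom], set()).add(atom)
    nodes = [
        NetworkNode(gid, "group", frozenset(atoms))
        for gid, atoms in members.items()
    ]

    grouped: dict[EdgeKey, list[TimelineRecord]] = {}
    for key in network.sorted_edge_keys():
        edge = network.edges[key]
        gu, gv = grouping[edge.u], grouping[edge.v]
        if gu == gv:
            continue
        if gu > gv:
            gu, gv = gv, gu
        rec = edge.members[0] if edge.members else TimelineRecord(
            edge.u, edge.v, edge.kind, edge.timeline
        )
        grouped.setdefault((gu, gv, edge.kind), []).append(rec)

    edges = []
    for (gu, gv, kind), recs in grouped.items():
        summed = Timeline(np.sum([r.timeline.values for r in recs], axis=0))
        edges.append(InteractionEdge(gu, gv, kind, summed, members=tuple(recs)))
    return StructureNetwork(nodes, edges, network.n_frames)


def split_node(
    network: StructureNetwork,
    node_id: str,
    records: Iterable[TimelineRecord] | None = None,
) -> StructureNetwork:
    """Replace one group node by its member atoms (mixed-grain result).

    Atomistic records are taken from the edges' stored provenance unless
    supplied explicitly.  Each record connecting a member atom to another
    node's atoms becomes an edge between that atom and the other node, with
    timelines re-summed over the other node's members; records internal to
    the split node become atom-atom edges.  Re-aggregating the split atoms
    reproduces the original group edges.
    """
    if node_id not in network.nodes:
        raise KeyError(node_id)
    node = network.nodes[node_id]
    if node.grain != "group":
        raise ValueError(f"node {node_id!r} is not group-grain")

    if records is None:
        recs: list[TimelineRecord] = []
        for edge in network.edges_of(node_id):
            if edge.members is None:
                raise ValueError(
                    f"no atomistic records stored for edge {edge.key}; "
                    "pass them explicitly"
                )
            recs.extend(edge.members)
    else:
        recs = list(records)
        touched = {
            a
            for r in recs
            for a in (r.source, r.target)
            if a in node.member_atoms
        }
        if network.edges_of(node_id) and not touched:
            raise ValueError(f"records do not cover atoms of {node_id!r}")

    atom_owner = network.atom_to_node()
    new_nodes = [n for n in network.nodes.values() if n.id != node_id]
    new_nodes.extend(
        NetworkNode(a, "atom", frozenset({a})) for a in sorted(node.member_atoms)
    )

    # Edges not touching the split node survive unchanged.
    edges: dict[EdgeKey, InteractionEdge] = {
        k: e for k, e in network.edges.items() if node_id not in (k[0], k[1])
    }

    grouped: dict[EdgeKey, list[TimelineRecord]] = {}
    for rec in recs:
        endpoints = []
        for atom in (rec.source, rec.target):
            if atom in node.member_atoms:
                endpoints.append(atom)
            else:
                owner = atom_owner.get(atom)
                if owner is None:
                    raise ValueError(f"record atom {atom!r} not in network")
                endpoints.append(owner)
        a, b = endpoints
        if a == b:
            continue
        if a > b:
            a, b = b, a
        grouped.setdefault((a, b, rec.kind), []).append(rec)
    for (a, b, kind), rlist in grouped.items():
        summed = Timeline(np.sum([r.timeline.values for r in rlist], axis=0))
        edges[(a, b, kind)] = InteractionEdge(
            a, b, kind, summed, members=tuple(rlist)
        )
    return StructureNetwork(new_nodes, edges.values(), network.n_frames)


def _contributing_atoms(edge: InteractionEdge, grain: str) -> set[str]:
    if edge.members is not None:
        return {a for r in edge.members for a in (r.source, r.target)}
    if grain == "atom":
        return {edge.u, edge.v}
    raise ValueError(
        f"edge {edge.key} has no atomistic provenance; cannot apply the "
        "sidechain filter to a group-grain edge without member records"
    )


def residue_network(
    records: Iterable[TimelineRecord],
    n_frames: int,
    min_occupancy: float = 0.0,
    types: Iterable[str] | None = None,
    sidechain_only: bool = False,
) -> StructureNetwork:
    """Standard pipeline: atomistic records -> filtered residue network.

    Filtering (occupancy, type subset, sidechain exclusivity) is applied at
    atom grain *before* aggregation, so a sidechain-exclusive residue
    network only sums sidechain-sidechain atomistic timelines.
    """
    atomistic = build_network(records, n_frames)
    atomistic = filter_network(atomistic, min_occupancy, types, sidechain_only)
    return aggregate_to_groups(atomistic, residue_grouping(atomistic))


def filter_network(
    network: StructureNetwork,
    min_occupancy: float = 0.0,
    types: Iterable[str] | None = None,
    sidechain_only: bool = False,
) -> StructureNetwork:
    """Drop edges by occupancy, interaction type, or backbone involvement.

    Occupancy is the fraction of frames with a positive count; an edge is
    kept when it is >= ``min_occupancy``, its type is in ``types`` (all
    types when None), and -- with ``sidechain_only`` -- every contributing
    atom is a sidechain atom.  Nodes are retained even if left isolated, and
    the operation is idempotent at fixed parameters.
    """
    if not 0.0 <= min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be within [0, 1]")
    allowed = None if types is None else set(types)
    kept = []
    for key in network.sorted_edge_keys():
        edge = network.edges[key]
        if allowed is not None and edge.kind not in allowed:
            continue
        if edge.timeline.occupancy() < min_occupancy:
            continue
        if sidechain_only:
            atoms = _contributing_atoms(edge, network.nodes[edge.u].grain)
            if not all(is_sidechain_atom(a) for a in atoms):
                continue
        kept.append(edge)
    return StructureNetwork(network.nodes.values(), kept, network.n_frames)
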