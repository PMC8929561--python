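"""Seeded synthetic fixtures with known ground truth.

Three generators make the whole pipeline testable without any external
data: coupled binary timeline pairs (for the information machinery),
networks with a planted coupled hub (for score-recovery experiments), and
toy coordinate ensembles whose contacts and hydrogen bonds switch on a
known schedule (for the geometric extractors).

All generators draw from a single explicitly seeded
``numpy.random.Generator``; no global random state is touched, and equal
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    NetworkNode,
    StructureNetwork,
    Timeline,
    TimelineRecord,
    build_network,
)
from .io.ensemble import StructureEnsemble

__all__ = [
    "CouplingSpec",
    "generate_coupled_timelines",
    "generate_hub_network",
    "generate_random_network",
    "generate_toy_ensemble",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Parameters of the coupled-pair timeline generator.

    ``coupling`` is the per-frame probability that the partner copies the
    master's state (1 duplicates the master, 0 gives independent draws);
    ``occupancy`` is the Bernoulli rate of both series.
    """

    frames: int = 2000
    coupling: float = 0.8
    occupancy: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        if not 0.0 < self.occupancy < 1.0:
            raise ValueError("occupancy must be in (0, 1)")


def _coupled_pair(
    rng: np.random.Generator, frames: int, coupling: float, occupancy: float
) -> tuple[Timeline, Timeline]:
    master = (rng.random(frames) < occupancy).astype(int)
    copy_mask = rng.random(frames) < coupling
    independent = (rng.random(frames) < occupancy).astype(int)
    partner = np.where(copy_mask, master, independent)
    return Timeline(master), Timeline(partner)


def generate_coupled_timelines(
    spec: CouplingSpec, n_pairs: int = 1
) -> list[tuple[Timeline, Timeline]]:
    """Pairs of Bernoulli timelines with tunable per-frame coupling."""
    rng = np.random.default_rng(spec.seed)
    return [
        _coupled_pair(rng, spec.frames, spec.coupling, spec.occupancy)
        for _ in range(n_pairs)
    ]


def _node_id(i: int) -> str:
    return f"A:{i + 1}:GLY"


def generate_hub_network(
    spec: CouplingSpec,
    n_background: int = 8,
    hub_degree: int = 4,
) -> tuple[StructureNetwork, str]:
    """Residue-grain network with one planted conformationally coupled hub.

    Background nodes form a ring with independent Bernoulli contact
    timelines; a hub node connects to ``hub_degree`` ring nodes through
    edges whose timelines are noisy copies of a common master series.  The
    hub's edges therefore share information with each other while the ring
    edges do not (beyond finite-sample bias), so the hub should attain the
    top node-correlation-factor rank when the coupling is strong and the
    series long.  Returns the network and the hub's node id.
    """
    if n_background < 3 or not 1 <= hub_degree <= n_background:
        raise ValueError("need >= 3 background nodes and 1 <= degree <= n")
    rng = np.random.default_rng(spec.seed)
    T, q, c = spec.frames, spec.occupancy, spec.coupling

    nodes = [
        NetworkNode(_node_id(i), "group", frozenset({f"{_node_id(i)}:CA"}))
        for i in range(n_background + 1)
    ]
    hub = _node_id(n_background)

    records = []
    for i in range(n_background):  # independent ring edges
        j = (i + 1) % n_background
        tl = Timeline((rng.random(T) < q).astype(int))
        records.append(TimelineRecord(_node_id(i), _node_id(j), "contact", tl))
    master = (rng.random(T) < q).astype(int)
    for i in range(hub_degree):  # coupled hub edges
        copy_mask = rng.random(T) < c
        independent = (rng.random(T) < q).astype(int)
        tl = Timeline(np.where(copy_mask, master, independent))
        records.append(TimelineRecord(hub, _node_id(i), "contact", tl))

    edges = []
    from .network import InteractionEdge

    for rec in records:
        u, v = rec.canonical_pair()
        edges.append(InteractionEdge(u, v, rec.kind, rec.timeline, members=(rec,)))
    return StructureNetwork(nodes, edges, T), hub


def generate_random_network(
    rng: np.random.Generator,
    max_nodes: int = 8,
    max_types: int = 3,
    max_frames: int = 50,
    edge_prob: float = 0.45,
) -> StructureNetwork:
    """Random atom-grain timeline network for oracle-equivalence testing."""
    n = int(rng.integers(2, max_nodes + 1))
    n_types = int(rng.integers(1, max_types + 1))
    T = int(rng.integers(2, max_frames + 1))
    kinds = ["contact", "hbond", "salt"][:n_types]
    ids = [f"A:{i + 1}:GLY:CA" for i in range(n)]
    records = []
    for a in range(n):
        for b in range(a + 1, n):
            for kind in kinds:
                if rng.random() < edge_prob:
                    tl = Timeline(rng.integers(0, 3, size=T))
                    records.append(TimelineRecord(ids[a], ids[b], kind, tl))
    if not records:  # guarantee a nonempty network
        tl = Timeline(rng.integers(0, 2, size=T))
        records.append(TimelineRecord(ids[0], ids[1], kinds[0], tl))
    return build_network(records, T)


# -- toy coordinate ensembles ------------------------------------------------

_RES_SPACING = 12.0  # Angstrom between pseudo-residue anchors
_CONTACT_NEAR = 4.5
_CONTACT_FAR = 6.5


def generate_toy_ensemble(
    n_residues: int = 4,
    n_frames: int = 6,
    switch_period: int = 2,
    seed: int = 0,
) -> tuple[StructureEnsemble, dict[tuple[str, str, str], Timeline]]:
    """Chain of pseudo-residues with scheduled oscillating interactions.

    Residues (GLY backbone plus a CB carbon) are spaced far apart so that
    only two designed interactions exist:

    * a carbon contact between the CB atoms of residues 1 and 2 that is
      within 4.5 Angstrom on "on" frames and at 6.5 Angstrom otherwise --
      straddling the conventional 5 Angstrom cutoff;
    * a backbone hydrogen bond from the amide N-H of residue 3 to the
      carbonyl O of residue 2 at fixed 2.9 Angstrom N...O distance whose
      N-H vector swings so the donor-H-acceptor angle sits well above the
      135 degree cutoff on "on" frames (~157 degrees) and well below it
      otherwise (~100 degrees).

    A frame ``t`` is "on" when ``(t // switch_period) % 2 == 0`` with
    ``switch_period == 1`` meaning strictly alternating frames.  Returns
    the ensemble and the ground-truth timelines keyed by
    ``(source_atom, target_atom, kind)``.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)

    names = ["N", "H", "CA", "C", "O", "CB"]
    elements = ["N", "H", "C", "C", "O", "C"]
    offsets = {
        "N": np.array([0.0, 0.0, 0.0]),
        "H": np.array([0.0, -1.0, 0.0]),
        "CA": np.array([1.45, 0.0, 0.0]),
        "C": np.array([2.0, 1.3, 0.0]),
        "O": np.array([2.0, 2.53, 0.0]),
        "CB": np.array([1.45, 0.0, 1.5]),
    }
    rows = []
    base = np.zeros((n_residues * len(names), 3))
    for r in range(n_residues):
        anchor = np.array([0.0, r * _RES_SPACING, 0.0])
        for a, (name, elem) in enumerate(zip(names, elements)):
            rows.append(
                {
                    "chain": "A",
                    "res_id": r + 1,
                    "ins_code": "",
                    "res_name": "GLY",
                    "atom_name": name,
                    "element": elem,
                }
            )
            base[r * len(names) + a] = anchor + offsets[name]
    atoms = pd.DataFrame(rows)

    def index_of(res: int, name: str) -> int:
        return (res - 1) * len(names) + names.index(name)

    on = np.array(
        [((t // switch_period) % 2 == 0) for t in range(n_frames)], dtype=bool
    )

    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    # small jitter on CA atoms only; never crosses any interaction boundary
    jitter = rng.normal(scale=0.05, size=(n_frames, n_residues, 3))
    for r in range(n_residues):
        coords[:, index_of(r + 1, "CA")] += jitter[:, r]

    # contact pair: CB(res1) -- CB(res2); CB(res2) oscillates along z from
    # CB(res1), a direction clear of every other atom by > 6 Angstrom
    cb1, cb2 = index_of(1, "CB"), index_of(2, "CB")
    direction = np.array([0.0, 0.0, 1.0])
    dist = np.where(on, _CONTACT_NEAR, _CONTACT_FAR)
    coords[:, cb2] = base[cb1] + direction * dist[:, None]

    # hydrogen bond: N-H of res3 donates to O of res2 at 2.9 A N...O
    n3, h3, o2 = index_of(3, "N"), index_of(3, "H"), index_of(2, "O")
    n_pos = base[o2] + np.array([0.0, 2.9, 0.0])
    coords[:, n3] = n_pos
    to_acceptor = (base[o2] - n_pos) / np.linalg.norm(base[o2] - n_pos)
    perp = np.array([1.0, 0.0, 0.0])
    for t in range(n_frames):
        angle_dha = 165.0 if on[t] else 120.0
        # place H at 1.0 A from N such that angle(N-H, A-H) == angle_dha
        theta = np.radians(180.0 - angle_dha)
        h_dir = np.cos(theta) * to_acceptor + np.sin(theta) * perp
        coords[t, h3] = n_pos + h_dir

    ensemble = StructureEnsemble(atoms, coords, source="toy-ensemble")
    aid = lambda res, name: f"A:{res}:GLY:{name}"  # noqa: E731
    truth = {
        (aid(1, "CB"), aid(2, "CB"), "contact"): Timeline(on.astype(int)),
        (aid(3, "N"), aid(2, "O"), "hbond"): Timeline(on.astype(int)),
    }
    return ensemble, truth
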