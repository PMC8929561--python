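"""Network model: construction, aggregation, splitting, filtering."""

import numpy as np
import pytest

from timenet import (
    Timeline,
    TimelineRecord,
    aggregate_to_groups,
    build_network,
    filter_network,
    is_sidechain_atom,
    residue_grouping,
    residue_network,
    split_node,
)

from conftest import atom


class TestTimeline:
    def test_rejects_empty_negative_and_fractional(self):
        with pytest.raises(ValueError):
            Timeline([])
        with pytest.raises(ValueError):
            Timeline([1, -1])
        with pytest.raises(ValueError):
            Timeline([0.5, 1.0])

    def test_occupancy_counts_positive_frames(self):
        assert Timeline([2, 0, 1, 0]).occupancy() == 0.5

    def test_values_are_immutable(self):
        tl = Timeline([1, 0])
        with pytest.raises(ValueError):
            tl.values[0] = 5


class TestBuildNetwork:
    def test_single_record(self):
        net = build_network(
            [TimelineRecord(atom(1), atom(2), "contact", Timeline([1, 0, 1]))], 3
        )
        assert len(net.nodes) == 2
        assert len(net.edges) == 1
        assert net.n_frames == 3
        assert net.grain == "atom"

    def test_length_mismatch_names_record(self):
        rec = TimelineRecord(atom(1), atom(2), "contact", Timeline([1, 0]))
        with pytest.raises(ValueError, match="A:1:GLY:CA"):
            build_network([rec], 3)

    def test_duplicate_pair_type_rejected(self):
        recs = [
            TimelineRecord(atom(1), atom(2), "contact", Timeline([1])),
            TimelineRecord(atom(2), atom(1), "contact", Timeline([1])),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_network(recs, 1)

    def test_single_structure_reduces_to_length_one_timelines(self):
        net = build_network(
            [TimelineRecord(atom(1), atom(2), "contact", Timeline([1]))], 1
        )
        assert all(len(e.timeline) == 1 for e in net.edges.values())

    def test_adjacency_symmetric_zero_diagonal(self, triangle_network):
        ids, A = triangle_network.adjacency_matrix("contact")
        assert (A == A.T).all()
        assert np.diag(A).sum() == 0
        assert A.sum() == 6  # 3 undirected edges


class TestAggregation:
    def _atomistic(self):
        # a1,a2 in residue 1; b1 in residue 2
        a1, a2 = atom(1, "CB"), atom(1, "CG")
        b1 = atom(2, "CB")
        recs = [
            TimelineRecord(a1, b1, "contact", Timeline([1, 0])),
            TimelineRecord(a2, b1, "contact", Timeline([1, 1])),
        ]
        return build_network(recs, 2)

    def test_framewise_sum(self):
        residue = aggregate_to_groups(self._atomistic(), residue_grouping(self._atomistic()))
        (edge,) = residue.edges.values()
        assert edge.timeline == Timeline([2, 1])
        assert residue.grain == "group"

    def test_intra_group_interactions_dropped(self):
        recs = [
            TimelineRecord(atom(1, "CB"), atom(1, "CG"), "contact", Timeline([1, 1]))
        ]
        net = build_network(recs, 2)
        residue = aggregate_to_groups(net, residue_grouping(net))
        assert len(residue.edges) == 0
        assert len(residue.nodes) == 1

    def test_missing_atom_in_grouping_named(self):
        net = self._atomistic()
        grouping = residue_grouping(net)
        grouping.pop(atom(1, "CG"))
        with pytest.raises(ValueError, match="A:1:GLY:CG"):
            aggregate_to_groups(net, grouping)

    def test_per_frame_count_conservation(self, rng):
        # conservation: total inter-group counts equal total over
        # contributing atomistic edges, frame by frame
        recs = []
        for i in range(1, 5):
            for j in range(i + 1, 5):
                recs.append(
                    TimelineRecord(
                        atom(i, "CB"),
                        atom(j, "CB"),
                        "contact",
                        Timeline(rng.integers(0, 2, size=6)),
                    )
                )
        net = build_network(recs, 6)
        grouping = {a: f"G{(int(a.split(':')[1]) - 1) // 2}" for a in net.nodes}
        grouped = aggregate_to_groups(net, grouping)
        inter = [
            r
            for r in recs
            if grouping[r.source] != grouping[r.target]
        ]
        total_atomistic = np.sum([r.timeline.values for r in inter], axis=0)
        total_grouped = np.sum(
            [e.timeline.values for e in grouped.edges.values()], axis=0
        )
        assert (total_atomistic == total_grouped).all()


class TestSplitNode:
    def test_split_then_aggregate_round_trip(self):
        a1, a2, b1 = atom(1, "CB"), atom(1, "CG"), atom(2, "CB")
        recs = [
            TimelineRecord(a1, b1, "contact", Timeline([1, 0])),
            TimelineRecord(a2, b1, "contact", Timeline([1, 1])),
        ]
        net = build_network(recs, 2)
        residue = aggregate_to_groups(net, residue_grouping(net))
        mixed = split_node(residue, "A:1:GLY")
        # recovers the atomistic timelines
        assert mixed.edges[(a1, "A:2:GLY", "contact")].timeline == Timeline([1, 0])
        assert mixed.edges[(a2, "A:2:GLY", "contact")].timeline == Timeline([1, 1])
        back = aggregate_to_groups(
            build_network(recs, 2), residue_grouping(build_network(recs, 2))
        )
        again = {k: e.timeline for k, e in back.edges.items()}
        assert again == {k: e.timeline for k, e in residue.edges.items()}

    def test_split_isolated_node(self):
        from timenet import NetworkNode, StructureNetwork

        nodes = [
            NetworkNode(
                "A:3:GLY", "group", frozenset({atom(3, "CB"), atom(3, "CG")})
            )
        ]
        net = StructureNetwork(nodes, [], 1)
        mixed = split_node(net, "A:3:GLY")
        assert "A:3:GLY" not in mixed.nodes
        assert atom(3, "CB") in mixed.nodes and atom(3, "CG") in mixed.nodes
        assert len(mixed.edges) == 0

    def test_group_node_required(self, triangle_network):
        with pytest.raises(ValueError, match="not group-grain"):
            split_node(triangle_network, atom(1))


class TestFilterNetwork:
    def test_occupancy_threshold(self):
        recs = [TimelineRecord(atom(1), atom(2), "contact", Timeline([1, 0, 0, 0]))]
        net = build_network(recs, 4)
        out = filter_network(net, min_occupancy=0.5)
        assert len(out.edges) == 0
        assert len(out.nodes) == 2  # nodes retained even if isolated

    def test_identity_at_zero_occupancy(self, triangle_network):
        out = filter_network(triangle_network, min_occupancy=0.0)
        assert set(out.edges) == set(triangle_network.edges)

    def test_idempotent(self, triangle_network):
        once = filter_network(triangle_network, min_occupancy=0.4)
        twice = filter_network(once, min_occupancy=0.4)
        assert set(once.edges) == set(twice.edges)

    def test_backbone_hbond_removed_by_sidechain_filter(self):
        recs = [
            TimelineRecord(atom(1, "N"), atom(2, "O"), "hbond", Timeline([1, 1])),
            TimelineRecord(atom(1, "CB"), atom(2, "CB"), "contact", Timeline([1, 1])),
        ]
        net = build_network(recs, 2)
        out = filter_network(net, sidechain_only=True)
        assert [k[2] for k in out.edges] == ["contact"]

    def test_type_subset(self, triangle_network):
        out = filter_network(triangle_network, types=["hbond"])
        assert len(out.edges) == 0

    def test_sidechain_classification(self):
        assert not is_sidechain_atom(atom(1, "CA"))
        assert not is_sidechain_atom(atom(1, "OXT"))
        assert is_sidechain_atom(atom(1, "CB"))


def test_residue_network_filters_before_aggregation():
    # backbone-involving atomistic timelines are excluded from the
    # sidechain-exclusive residue sum, not just whole residue edges
    recs = [
        TimelineRecord(atom(1, "CB"), atom(2, "CB"), "contact", Timeline([1, 1])),
        TimelineRecord(atom(1, "CA"), atom(2, "CB"), "contact", Timeline([1, 1])),
    ]
    full = residue_network(recs, 2)
    side = residue_network(recs, 2, sidechain_only=True)
    assert full.edges[("A:1:GLY", "A:2:GLY", "contact")].timeline == Timeline([2, 2])
    assert side.edges[("A:1:GLY", "A:2:GLY", "contact")].timeline == Timeline([1, 1])
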