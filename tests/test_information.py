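"""Mutual-information machinery and ECF/NCF/DNCF scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timenet import (
    Timeline,
    TimelineRecord,
    build_network,
    difference_mutual_information,
    dncf,
    ecf,
    edge_neighborhood,
    entropy,
    match_edges,
    mutual_information,
    ncf,
)

from conftest import atom
from oracles import brute_diff_mi, brute_mi

timelines = st.lists(st.integers(0, 2), min_size=2, max_size=40)


class TestMutualInformation:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0, 1, 0, 1], [0, 1, 0, 1], 1.0),  # identical binary: I = H = 1
            ([0, 0, 1, 1], [0, 1, 0, 1], 0.0),  # empirically independent
            ([0, 0, 0, 1], [0, 0, 1, 1], 0.3112781244591328),  # direct summation
        ],
    )
    def test_plug_in_examples(self, x, y, expected):
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information([0, 1], [0, 1, 0])

    @given(x=timelines, y=timelines)
    @settings(derandomize=True, max_examples=150)
    def test_matches_literal_summation_and_identities(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        mi = mutual_information(x, y)
        assert mi == pytest.approx(brute_mi(x, y), abs=1e-12)
        assert mi == pytest.approx(mutual_information(y, x), abs=1e-12)
        assert -1e-12 <= mi <= min(entropy(x), entropy(y)) + 1e-12
        assert mutual_information(x, x) == pytest.approx(entropy(x), abs=1e-12)

    @given(x=timelines, y=timelines, seed=st.integers(0, 2**16))
    @settings(derandomize=True, max_examples=60)
    def test_joint_frame_permutation_invariance(self, x, y, seed):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        perm = np.random.default_rng(seed).permutation(n)
        assert mutual_information(x[perm], y[perm]) == pytest.approx(
            mutual_information(x, y), abs=1e-12
        )

    def test_single_permutation_drives_mi_to_bias_floor(self, rng):
        # shuffling one timeline alone destroys coupling; what remains is
        # finite-sample bias, about (|X|-1)(|Y|-1)/(2 T ln 2) bits
        T = 5000
        x = (rng.random(T) < 0.5).astype(int)
        y = x.copy()
        assert mutual_information(x, y) > 0.9
        shuffled = rng.permutation(y)
        bias = 1.0 / (2 * T * np.log(2))
        assert mutual_information(x, shuffled) < 20 * bias


class TestDifferenceMI:
    def test_identical_pairs_cancel(self):
        x = [0, 1, 0, 1]
        assert difference_mutual_information(x, x, x, x) == 0.0

    def test_reference_subtracted(self):
        # target pair perfectly coupled (1 bit), reference independent (0)
        val = difference_mutual_information(
            [0, 1, 0, 1], [0, 1, 0, 1], [0, 0, 1, 1], [0, 1, 0, 1]
        )
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_swap_flips_sign(self):
        val = difference_mutual_information(
            [0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 0, 1], [0, 1, 0, 1]
        )
        assert val == pytest.approx(-1.0, abs=1e-12)

    def test_absent_reference_reduces_to_mi(self):
        x, y = [0, 1, 0, 1], [0, 1, 1, 1]
        assert difference_mutual_information(x, y) == mutual_information(x, y)
        # constant reference pair carries no information either
        assert difference_mutual_information(
            x, y, [0, 0, 0], [1, 1, 1]
        ) == pytest.approx(mutual_information(x, y), abs=1e-12)

    @given(x=timelines, y=timelines, xr=timelines, yr=timelines)
    @settings(derandomize=True, max_examples=60)
    def test_matches_union_alphabet_oracle(self, x, y, xr, yr):
        n, m = min(len(x), len(y)), min(len(xr), len(yr))
        x, y, xr, yr = x[:n], y[:n], xr[:m], yr[:m]
        assert difference_mutual_information(x, y, xr, yr) == pytest.approx(
            brute_diff_mi(x, y, xr, yr), abs=1e-12
        )


class TestECF:
    def test_triangle(self, triangle_network):
        e1 = (atom(1), atom(2), "contact")
        assert ecf(triangle_network, e1) == pytest.approx(1.0, abs=1e-12)

    def test_single_edge_network_scores_zero(self):
        net = build_network(
            [TimelineRecord(atom(1), atom(2), "contact", Timeline([1, 0]))], 2
        )
        assert ecf(net, (atom(1), atom(2), "contact")) == 0.0

    def test_parallel_edge_counted_once_self_excluded(self):
        recs = [
            TimelineRecord(atom(1), atom(2), "contact", Timeline([0, 1, 0, 1])),
            TimelineRecord(atom(1), atom(2), "hbond", Timeline([0, 1, 0, 1])),
        ]
        net = build_network(recs, 4)
        focal = (atom(1), atom(2), "contact")
        assert edge_neighborhood(net, focal) == [(atom(1), atom(2), "hbond")]
        assert ecf(net, focal) == pytest.approx(1.0, abs=1e-12)

    def test_absent_edge_rejected(self, triangle_network):
        with pytest.raises(KeyError):
            ecf(triangle_network, (atom(1), atom(9), "contact"))


class TestNCF:
    def test_triangle_node_sums(self, triangle_network):
        table = ncf(triangle_network)
        assert table[atom(2)] == pytest.approx(2.0, abs=1e-12)
        assert table[atom(1)] == pytest.approx(1.0, abs=1e-12)
        assert table.method == "NCF"

    def test_constant_timelines_score_zero(self):
        recs = [
            TimelineRecord(atom(1), atom(2), "contact", Timeline([1, 1, 1])),
            TimelineRecord(atom(2), atom(3), "contact", Timeline([1, 1, 1])),
        ]
        table = ncf(build_network(recs, 3))
        assert all(v == 0.0 for v in table.scores.values())

    def test_identical_target_and_reference_gives_zero_dncf(self, triangle_network):
        table = dncf(triangle_network, triangle_network)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in table.scores.values())
        assert table.method == "DNCF"

    def test_dncf_sign_flips_under_swap_on_identical_topology(self, rng):
        def random_net(seed):
            r = np.random.default_rng(seed)
            recs = [
                TimelineRecord(
                    atom(i), atom(j), "contact", Timeline(r.integers(0, 2, 30))
                )
                for i, j in [(1, 2), (2, 3), (1, 3), (3, 4)]
            ]
            return build_network(recs, 30)

        a, b = random_net(1), random_net(2)
        fwd = dncf(a, reference=b)
        rev = dncf(b, reference=a)
        for node in fwd.scores:
            assert fwd[node] == pytest.approx(-rev[node], abs=1e-12)


class TestMatchEdges:
    def test_identical_topologies_bijective(self, triangle_network):
        mapping, ref_only = match_edges(triangle_network, triangle_network)
        assert all(v == k for k, v in mapping.items())
        assert ref_only == []

    def test_reference_only_edges_reported_and_excluded(self, triangle_network):
        recs = [
            TimelineRecord(atom(1), atom(2), "contact", Timeline([1, 1, 0, 0])),
            TimelineRecord(atom(2), atom(3), "contact", Timeline([1, 1, 0, 0])),
            TimelineRecord(atom(1), atom(3), "contact", Timeline([0, 1, 0, 1])),
            TimelineRecord(atom(3), atom(4), "contact", Timeline([0, 1, 1, 1])),
        ]
        reference = build_network(recs, 4)
        mapping, ref_only = match_edges(triangle_network, reference)
        assert ref_only == [(atom(3), atom(4), "contact")]
        assert None not in mapping.values()

    def test_target_only_edge_contributes_full_target_mi(self):
        # reference lacks the neighbor edge: its reference term is zero
        recs_t = [
            TimelineRecord(atom(1), atom(2), "contact", Timeline([0, 1, 0, 1])),
            TimelineRecord(atom(2), atom(3), "contact", Timeline([0, 1, 0, 1])),
        ]
        target = build_network(recs_t, 4)
        reference = build_network(recs_t[:1], 4)
        focal = (atom(1), atom(2), "contact")
        assert ecf(target, focal, reference=reference) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_grain_mismatch_rejected(self, triangle_network):
        from timenet import aggregate_to_groups, residue_grouping

        residue = aggregate_to_groups(
            triangle_network, residue_grouping(triangle_network)
        )
        with pytest.raises(ValueError, match="grain"):
            match_edges(triangle_network, residue)
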