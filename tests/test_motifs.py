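from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_census, color_isomorphic, connected_subsets, orbit_count
from statemotif.motifs import (
    canonical_colored,
    canonical_uncolored,
    count_possible_colored_motifs,
    enumerate_connected_subgraphs,
    motif_census,
    motif_types,
)
from statemotif.network_io import StateNetwork
from statemotif.synthetic import FixtureSpec, random_state_network

TRIANGLE = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
PATH3 = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]


class TestEnumeration:
    def test_triangle_yields_single_subset(self, triangle_net):
        assert list(enumerate_connected_subgraphs(triangle_net, 3)) == [
            frozenset("ABC")
        ]

    def test_path_skips_disconnected_subsets(self, path4_net):
        subsets = set(enumerate_connected_subgraphs(path4_net, 3))
        assert subsets == {frozenset("abc"), frozenset("bcd")}

    @pytest.mark.parametrize("k", [2, 5])
    def test_unsupported_size_rejected(self, triangle_net, k):
        with pytest.raises(ValueError):
            list(enumerate_connected_subgraphs(triangle_net, k))

    @pytest.mark.parametrize("k", [3, 4])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_subset_filter(self, k, seed):
        net = random_state_network(
            FixtureSpec(n_nodes=10, n_edges=20, state_alphabet=("a", "b"), seed=seed)
        )
        found = list(enumerate_connected_subgraphs(net, k))
        assert len(found) == len(set(found)), "duplicate subsets emitted"
        assert set(found) == connected_subsets(net, k)


class TestCanonicalUncolored:
    def test_motif_type_inventory(self):
        assert [t.label for t in motif_types(3)] == ["I", "II"]
        assert [t.label for t in motif_types(4)] == ["I", "II", "III", "IV", "V", "VI"]
        assert [t.n_edges for t in motif_types(4)] == [3, 3, 4, 4, 5, 6]

    def test_triangle_is_type_one(self):
        assert canonical_uncolored(TRIANGLE).label == "I"

    def test_path_is_type_two(self):
        assert canonical_uncolored(PATH3).label == "II"

    def test_four_cycle_invariant_under_relabeling(self):
        cycle = np.zeros((4, 4), dtype=int)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            cycle[i, j] = cycle[j, i] = 1
        ref = canonical_uncolored(cycle)
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.permutation(4)
            assert canonical_uncolored(cycle[np.ix_(p, p)]) == ref

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            canonical_uncolored([[0, 1, 0], [1, 0, 0], [0, 0, 0]])

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            canonical_uncolored(np.zeros((5, 5), dtype=int))


def _all_connected_labeled(k, states_alphabet):
    """Every connected labeled graph on k nodes with every state assignment."""
    pairs = list(combinations(range(k), 2))
    out = []
    for mask in range(2 ** len(pairs)):
        adj = [[0] * k for _ in range(k)]
        for b, (i, j) in enumerate(pairs):
            if mask >> b & 1:
                adj[i][j] = adj[j][i] = 1
        try:
            canonical_uncolored(adj)
        except ValueError:
            continue
        for states in product(states_alphabet, repeat=k):
            out.append((adj, states))
    return out


class TestCanonicalColored:
    def test_triangle_state_rotations_share_id(self):
        a = canonical_colored(TRIANGLE, ["active", "repressed", "active"])
        b = canonical_colored(TRIANGLE, ["repressed", "active", "active"])
        assert a.colored_motif_id == b.colored_motif_id

    def test_path_center_state_distinguishes(self):
        a = canonical_colored(PATH3, ["active", "repressed", "active"])
        b = canonical_colored(PATH3, ["active", "active", "repressed"])
        assert a.colored_motif_id != b.colored_motif_id

    def test_empty_state_rejected(self):
        with pytest.raises(ValueError, match="empty state"):
            canonical_colored(TRIANGLE, ["active", "", "active"])

    def test_equal_ids_iff_color_isomorphic_size3(self):
        """Exhaustive: canonical ids agree exactly when a brute-force
        permutation search finds a color-preserving isomorphism (k=3)."""
        graphs = _all_connected_labeled(3, ("x", "y", "z"))
        forms = [canonical_colored(a, s).colored_motif_id for a, s in graphs]
        for i in range(len(graphs)):
            for j in range(i, len(graphs)):
                iso = color_isomorphic(*graphs[i], *graphs[j])
                assert (forms[i] == forms[j]) == iso

    def test_equal_ids_iff_color_isomorphic_size4_sampled(self):
        graphs = _all_connected_labeled(4, ("x", "y"))
        forms = [canonical_colored(a, s).colored_motif_id for a, s in graphs]
        rng = np.random.default_rng(1)
        idx = rng.integers(0, len(graphs), size=(400, 2))
        for i, j in idx:
            iso = color_isomorphic(*graphs[i], *graphs[j])
            assert (forms[i] == forms[j]) == iso

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(data=st.data(), k=st.sampled_from([3, 4]))
    def test_id_invariant_under_node_permutation(self, data, k):
        graphs = _all_connected_labeled(k, ("x", "y", "z"))
        adj, states = graphs[data.draw(st.integers(0, len(graphs) - 1))]
        perm = data.draw(st.permutations(range(k)))
        padj = [[adj[perm[i]][perm[j]] for j in range(k)] for i in range(k)]
        pstates = [states[perm[i]] for i in range(k)]
        assert (
            canonical_colored(padj, pstates).colored_motif_id
            == canonical_colored(adj, states).colored_motif_id
        )


class TestCensus:
    def test_single_all_active_triangle(self, triangle_net):
        census = motif_census(triangle_net, 3)
        assert census.colored_counts == {"3:111:active;active;active": 1}
        assert census.type_counts == {"I": 1}

    def test_triangle_contains_no_induced_path(self, triangle_net):
        census = motif_census(triangle_net, 3)
        assert census.type_counts.get("II", 0) == 0

    @pytest.mark.parametrize("k", [3, 4])
    def test_census_matches_brute_force(self, small_random_net, k):
        census = motif_census(small_random_net, k)
        oracle = brute_force_census(small_random_net, k)
        assert len(oracle) == len(census.colored_counts)
        for (adj, states), count in oracle:
            cid = canonical_colored(adj, states).colored_motif_id
            assert census.colored_counts[cid] == count

    @pytest.mark.parametrize("k", [3, 4])
    def test_colored_counts_sum_to_type_counts(self, small_random_net, k):
        census = motif_census(small_random_net, k)
        per_type = {}
        for cid, n in census.colored_counts.items():
            label = census.colored_motifs[cid].motif_type.label
            per_type[label] = per_type.get(label, 0) + n
        assert per_type == census.type_counts

    def test_census_invariant_under_node_renaming(self, small_random_net):
        net = small_random_net
        mapping = {n: f"z{i}" for i, n in enumerate(reversed(net.nodes()))}
        renamed = StateNetwork.from_edges(
            [(mapping[u], mapping[v]) for u, v in net.edges()],
            {mapping[n]: s for n, s in net.states.items()},
        )
        assert motif_census(net, 3) == motif_census(renamed, 3)

    def test_instance_lists_match_counts(self, planted_net):
        census = motif_census(planted_net, 3, record_instances=True)
        for cid, n in census.colored_counts.items():
            assert len(census.instances[cid]) == n

    def test_instances_stored_in_canonical_state_order(self, path4_net):
        net = StateNetwork.from_edges(
            [("a", "b"), ("b", "c")],
            {"a": "weak", "b": "active", "c": "repressed"},
        )
        census = motif_census(net, 3, record_instances=True)
        (cid,) = census.colored_counts
        (instance,) = census.instances[cid]
        cm = census.colored_motifs[cid]
        assert tuple(net.state_of(n) for n in instance) == cm.position_states


class TestColoredMotifCounting:
    def test_triangle_four_states_gives_twenty(self, triangle_type):
        assert count_possible_colored_motifs(triangle_type, 4) == 20

    def test_path_four_states_gives_forty(self, path3_type):
        assert count_possible_colored_motifs(path3_type, 4) == 40

    def test_triangle_two_states_gives_four(self, triangle_type):
        assert count_possible_colored_motifs(triangle_type, 2) == 4

    def test_single_state_always_one(self):
        for k in (3, 4):
            for t in motif_types(k):
                assert count_possible_colored_motifs(t, 1) == 1

    def test_invalid_state_count(self, triangle_type):
        with pytest.raises(ValueError):
            count_possible_colored_motifs(triangle_type, 0)

    @pytest.mark.parametrize("n_states", [1, 2, 3, 4, 5])
    def test_matches_exhaustive_orbit_enumeration(self, n_states):
        for k in (3, 4):
            for t in motif_types(k):
                expected = orbit_count(t.adjacency().tolist(), n_states)
                assert count_possible_colored_motifs(t, n_states) == expected
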