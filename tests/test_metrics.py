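"""Centralities, components, prevalence counting, Fisher-Z arithmetic."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smoothnet.metrics import (
    LCCResult,
    average_correlations,
    correlation_difference,
    degree,
    degree_ranks,
    eigenvector_centrality,
    fisher_z,
    inverse_fisher_z,
    largest_connected_component,
    lcc_membership_fraction,
    link_prevalence,
    weight_vs_distance_profile,
)
from smoothnet.network import AdjacencyMatrix, BinaryNetwork
from smoothnet.parcellate import LinkGeometry


def from_nx(g, n=None):
    return BinaryNetwork.from_edges(n or g.number_of_nodes(), g.edges())


class TestDegree:
    def test_star_and_empty(self):
        star = from_nx(nx.star_graph(4))
        assert list(degree(star)) == [4, 1, 1, 1, 1]
        empty = BinaryNetwork.from_edges(5, [])
        assert list(degree(empty)) == [0] * 5

    def test_matches_adjacency_row_sums(self):
        g = nx.gnm_random_graph(10, 20, seed=3)
        net = from_nx(g)
        assert np.array_equal(degree(net), net.adjacency_matrix().sum(axis=0))


class TestDegreeRanks:
    def test_competition_ranking(self):
        assert list(degree_ranks(np.array([5, 3, 3, 1]))) == [1, 2, 2, 4]
        assert list(degree_ranks(np.array([2, 2, 2]))) == [1, 1, 1]

    @given(seed=st.integers(0, 100))
    def test_relabeling_permutes_ranks(self, seed):
        gen = np.random.default_rng(seed)
        degs = gen.integers(0, 10, size=12)
        perm = gen.permutation(12)
        assert np.array_equal(degree_ranks(degs)[perm], degree_ranks(degs[perm]))


class TestEigenvectorCentrality:
    def test_complete_graph_uniform(self):
        v = eigenvector_centrality(from_nx(nx.complete_graph(4)))
        assert np.allclose(v, 0.5, atol=1e-8)

    def test_path_graph_closed_form(self):
        # P3 leading eigenvector: center / leaf = sqrt(2)
        v = eigenvector_centrality(from_nx(nx.path_graph(3)))
        assert v[1] / v[0] == pytest.approx(math.sqrt(2), abs=1e-8)

    def test_star_center_leaf_ratio(self):
        v = eigenvector_centrality(from_nx(nx.star_graph(4)))
        assert v[0] / v[1] == pytest.approx(2.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_eigendecomposition_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(5, 13))
        m = int(gen.integers(n, n * (n - 1) // 2))
        g = nx.gnm_random_graph(n, m, seed=seed)
        net = from_nx(g, n)
        v = eigenvector_centrality(net)
        a = net.adjacency_matrix()
        w, vecs = np.linalg.eigh(a)
        oracle = np.abs(vecs[:, -1])
        assert np.allclose(v, oracle, atol=1e-6)
        assert v.min() >= 0 and np.linalg.norm(v) == pytest.approx(1.0)

    def test_bipartite_component_uses_direct_solve(self):
        # C4 is connected and bipartite: plain power iteration oscillates
        v = eigenvector_centrality(from_nx(nx.cycle_graph(4)))
        assert np.allclose(v, 0.5, atol=1e-8)

    def test_isolated_nodes_score_zero(self):
        net = BinaryNetwork.from_edges(5, [(0, 1), (1, 2), (0, 2)])
        v = eigenvector_centrality(net)
        assert v[3] == 0 and v[4] == 0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            eigenvector_centrality(BinaryNetwork.from_edges(4, []))


class TestLCC:
    def test_connected_graph_is_its_own_lcc(self):
        net = from_nx(nx.path_graph(6))
        assert largest_connected_component(net) == set(range(6))

    def test_two_components(self):
        net = BinaryNetwork.from_edges(6, [(0, 1), (2, 3), (3, 4)])
        res = largest_connected_component(net)
        assert res == {2, 3, 4} and not res.tied

    def test_size_tie_prefers_smallest_node(self):
        net = BinaryNetwork.from_edges(4, [(0, 1), (2, 3)])
        res = largest_connected_component(net)
        assert res == {0, 1} and res.tied

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bfs_from_every_node(self, seed):
        g = nx.gnm_random_graph(15, 12, seed=seed)
        net = from_nx(g, 15)
        # oracle: exhaustive BFS component enumeration
        best = frozenset()
        for start in range(15):
            seen, stack = {start}, [start]
            while stack:
                u = stack.pop()
                for a, b in net.edges:
                    for x, y in ((a, b), (b, a)):
                        if x == u and y not in seen:
                            seen.add(y)
                            stack.append(y)
            if len(seen) > len(best) or (len(seen) == len(best) and min(seen) < min(best)):
                best = frozenset(seen)
        assert largest_connected_component(net) == best


class TestCohortCounting:
    def test_lcc_fraction_counts_subjects(self):
        nets = [
            BinaryNetwork.from_edges(3, e)
            for e in ([(0, 1)], [(0, 2)], [(0, 1)])
        ]
        frac = lcc_membership_fraction(nets)
        assert np.allclose(frac, [1.0, 2 / 3, 1 / 3])

    def test_single_subject_is_indicator(self):
        nets = [BinaryNetwork.from_edges(4, [(1, 2)])]
        assert np.allclose(lcc_membership_fraction(nets), [0, 1, 1, 0])

    def test_subject_order_invariance(self):
        nets = [
            BinaryNetwork.from_edges(4, e)
            for e in ([(0, 1)], [(2, 3)], [(0, 3), (1, 3)])
        ]
        a = lcc_membership_fraction(nets)
        b = lcc_membership_fraction(nets[::-1])
        assert np.array_equal(a, b)
        assert a.max() <= 1.0

    def test_link_prevalence_counts_edges(self):
        nets = [
            BinaryNetwork.from_edges(3, e)
            for e in ([(0, 1)], [(0, 1), (1, 2)])
        ]
        prev = link_prevalence(nets)
        assert prev[0, 1] == 1.0 and prev[1, 2] == 0.5 and prev[0, 2] == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            lcc_membership_fraction([])


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-12)

    @given(r=st.floats(-0.999999, 0.999999))
    def test_round_trip(self, r):
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)

    def test_exact_one_is_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z)

    def test_average_correlations(self):
        assert average_correlations([0.5, 0.5]) == pytest.approx(0.5)
        assert average_correlations([0.3, -0.3]) == pytest.approx(0.0, abs=1e-12)
        expected = math.tanh((math.atanh(0.2) + math.atanh(0.8)) / 2)
        assert average_correlations([0.2, 0.8]) == pytest.approx(expected, abs=1e-12)

    def test_correlation_difference(self):
        assert correlation_difference(0.4, 0.4) == 0.0
        assert correlation_difference(0.5, 0.0) == pytest.approx(
            0.5 * math.log(3), abs=1e-12
        )
        assert correlation_difference(0.2, 0.7) == pytest.approx(
            -correlation_difference(0.7, 0.2), abs=1e-12
        )


class TestWeightDistanceProfile:
    def geometry(self):
        d = np.array(
            [
                [0.0, 5.0, 15.0],
                [5.0, 0.0, 25.0],
                [15.0, 25.0, 0.0],
            ]
        )
        return LinkGeometry(d)

    def test_equal_weights_fill_bins(self):
        w = np.full((3, 3), 0.4)
        np.fill_diagonal(w, 0.0)
        prof = weight_vs_distance_profile(
            AdjacencyMatrix(weights=w), self.geometry(), np.array([0.0, 10, 20, 30])
        )
        assert np.allclose(prof.bins.mean_weight, 0.4)
        assert list(prof.bins.n_pairs) == [1, 1, 1]

    def test_single_pair_bins_return_the_weight(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.8
        w[0, 2] = w[2, 0] = -0.2
        w[1, 2] = w[2, 1] = 0.1
        prof = weight_vs_distance_profile(
            AdjacencyMatrix(weights=w), self.geometry(), np.array([0.0, 10, 20, 30])
        )
        assert list(prof.bins.mean_weight) == pytest.approx([0.8, -0.2, 0.1])

    def test_empty_bin_reported_as_missing(self):
        w = np.zeros((3, 3))
        prof = weight_vs_distance_profile(
            AdjacencyMatrix(weights=w),
            self.geometry(),
            np.array([0.0, 10, 20, 30, 40]),
        )
        assert math.isnan(prof.bins.mean_weight.iloc[3])
        assert prof.bins.n_pairs.iloc[3] == 0

    def test_uncovered_distances_rejected(self):
        w = np.zeros((3, 3))
        with pytest.raises(ValueError):
            weight_vs_distance_profile(
                AdjacencyMatrix(weights=w), self.geometry(), np.array([0.0, 10.0])
            )

    def test_homotopic_pairs_reported_separately(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        prof = weight_vs_distance_profile(
            AdjacencyMatrix(weights=w),
            self.geometry(),
            np.array([0.0, 10, 20, 30]),
            homotopic_pairs=((1, 2),),
        )
        assert prof.homotopic is not None
        assert prof.homotopic.weight.iloc[0] == 0.9
        assert prof.homotopic.distance_mm.iloc[0] == 5.0


def test_lcc_result_set_semantics():
    res = LCCResult(nodes=frozenset({1, 2, 5}))
    assert 2 in res and len(res) == 3 and list(res) == [1, 2, 5]
    assert res == {1, 2, 5}
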