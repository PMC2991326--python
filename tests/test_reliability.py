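"""Reliability core: sampling, exact oracles, composition and combinatorics."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppidecon.errors import InvalidArgumentError, SizeLimitError
from ppidecon.graphs import ConnectivityMatrix, Graph, ProbabilisticGraph
from ppidecon.reliability import (clique_conn, connected_edge_counts,
                                  estimate_connectivity, exact_connectivity,
                                  gamma_connected, parallel_prob,
                                  sample_realization, sampling_half_width,
                                  series_prob)


def brute_force_connectivity(graph: Graph, p: float) -> dict:
    """Independent oracle: enumerate all edge subsets directly."""
    edges = graph.sorted_edges()
    verts = graph.sorted_vertices()
    out = {pair: 0.0 for pair in itertools.combinations(verts, 2)}
    for r in range(len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            prob = p ** r * (1 - p) ** (len(edges) - r)
            g = nx.Graph()
            g.add_nodes_from(verts)
            g.add_edges_from(subset)
            for u, v in out:
                if nx.has_path(g, u, v):
                    out[(u, v)] += prob
    return out


class TestSampleRealization:
    def test_certainty_keeps_every_edge(self, triangle, rng):
        pg = ProbabilisticGraph(triangle, 1.0)
        assert sample_realization(pg, rng).edges == triangle.edges

    def test_near_zero_survival_empties_the_graph(self, triangle, rng):
        pg = ProbabilisticGraph(triangle, 1e-12)
        assert sample_realization(pg, rng).edges == frozenset()

    def test_single_edge_survival_frequency(self, rng):
        pg = ProbabilisticGraph(Graph.from_edges([(0, 1)]), 0.5)
        hits = sum(sample_realization(pg, rng).n_edges for _ in range(20000))
        assert abs(hits - 10000) <= 3 * 139  # 3x the 95% binomial band


class TestEstimateConnectivity:
    def test_edgeless_graph_is_all_zero(self, rng):
        pg = ProbabilisticGraph(Graph(frozenset(range(4)), frozenset()), 0.5)
        M = estimate_connectivity(pg, 100, rng)
        off = M.values[~np.eye(4, dtype=bool)]
        assert np.all(off == 0.0)

    def test_single_edge_estimate_within_tolerance(self, rng):
        pg = ProbabilisticGraph(Graph.from_edges([(0, 1)]), 0.5)
        M = estimate_connectivity(pg, 20000, rng)
        assert abs(M[(0, 1)] - 0.5) <= 0.007
        assert M.delta == pytest.approx(0.00693, abs=1e-4)

    def test_triangle_pairs_near_exact_value(self, triangle, rng):
        M = estimate_connectivity(ProbabilisticGraph(triangle, 0.5), 50000, rng)
        for u, v in itertools.combinations(range(3), 2):
            assert abs(M[(u, v)] - 0.625) <= 0.005

    def test_reproducible_under_fixed_seed(self, triangle):
        pg = ProbabilisticGraph(triangle, 0.5)
        a = estimate_connectivity(pg, 2000, np.random.default_rng(7)).values
        b = estimate_connectivity(pg, 2000, np.random.default_rng(7)).values
        assert np.array_equal(a, b)

    def test_rejects_non_positive_sample_count(self, triangle, rng):
        with pytest.raises(InvalidArgumentError):
            estimate_connectivity(ProbabilisticGraph(triangle, 0.5), 0, rng)


class TestExactConnectivity:
    @pytest.mark.parametrize("k,expected", [(2, 0.5), (3, 5 / 8), (4, 3 / 4)])
    def test_small_cliques(self, k, expected):
        g = Graph.from_edges([(i, j) for i in range(k) for j in range(i + 1, k)])
        M = exact_connectivity(ProbabilisticGraph(g, 0.5))
        for u, v in itertools.combinations(range(k), 2):
            assert M[(u, v)] == pytest.approx(expected)

    def test_series_path_with_heterogeneous_probabilities(self):
        g = Graph.from_edges([("a", "b"), ("b", "c")])
        pg = ProbabilisticGraph(g, 0.5, {("a", "b"): 0.5, ("b", "c"): 0.25})
        assert exact_connectivity(pg)[("a", "c")] == pytest.approx(0.125)

    def test_matches_brute_force_on_random_graphs(self):
        for seed in range(5):
            nxg = nx.gnm_random_graph(6, 9, seed=seed)
            g = Graph.from_edges(nxg.edges(), vertices=range(6))
            M = exact_connectivity(ProbabilisticGraph(g, 0.5))
            oracle = brute_force_connectivity(g, 0.5)
            for pair, val in oracle.items():
                assert M[pair] == pytest.approx(val, abs=1e-12)

    def test_tree_closed_form(self):
        # reliability through a tree is p̂^(path length)
        for seed in (0, 1):
            t = nx.random_labeled_tree(30, seed=seed)
            g = Graph.from_edges(t.edges(), vertices=range(30))
            M = exact_connectivity(ProbabilisticGraph(g, 0.5))
            dist = dict(nx.all_pairs_shortest_path_length(t))
            for u, v in itertools.combinations(range(30), 2):
                assert M[(u, v)] == pytest.approx(0.5 ** dist[u][v])

    def test_refuses_oversized_blocks(self):
        g = Graph.from_edges([(i, j) for i in range(8) for j in range(i + 1, 8)])
        with pytest.raises(SizeLimitError):
            exact_connectivity(ProbabilisticGraph(g, 0.5))

    def test_disconnected_pairs_have_zero_connectivity(self):
        g = Graph.from_edges([(0, 1), (2, 3)])
        M = exact_connectivity(ProbabilisticGraph(g, 0.5))
        assert M[(0, 2)] == 0.0
        assert M[(1, 3)] == 0.0


class TestComposition:
    def test_series_examples(self):
        assert series_prob(0.5, 0.5) == 0.25
        assert series_prob(1.0, 0.37) == 0.37

    def test_parallel_examples(self):
        assert parallel_prob(0.5, 0.5) == 0.75
        assert parallel_prob(0.42, 0.0) == 0.42

    def test_composition_reproduces_triangle(self):
        # direct edge in parallel with the two-edge path
        assert parallel_prob(0.5, series_prob(0.5, 0.5)) == pytest.approx(5 / 8)
        assert series_prob(0.5, 0.25) == pytest.approx(0.125)

    @pytest.mark.parametrize("fn", [series_prob, parallel_prob])
    def test_out_of_range_rejected(self, fn):
        with pytest.raises(InvalidArgumentError):
            fn(1.2, 0.5)
        with pytest.raises(InvalidArgumentError):
            fn(0.5, -0.1)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_parallel_dominates_series(self, p1, p2):
        assert parallel_prob(p1, p2) >= series_prob(p1, p2)

    def test_series_parallel_graph_against_oracle(self):
        # a-b in parallel with a-c-b, all in series with b-d
        g = Graph.from_edges([("a", "b"), ("a", "c"), ("c", "b"), ("b", "d")])
        M = exact_connectivity(ProbabilisticGraph(g, 0.5))
        ab = parallel_prob(0.5, series_prob(0.5, 0.5))
        assert M[("a", "b")] == pytest.approx(ab)
        assert M[("a", "d")] == pytest.approx(series_prob(ab, 0.5))


class TestGammaConnected:
    def enumerate_connected(self, n):
        pairs = list(itertools.combinations(range(n), 2))
        count = 0
        for mask in range(1 << len(pairs)):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(p for i, p in enumerate(pairs) if (mask >> i) & 1)
            if nx.is_connected(g):
                count += 1
        return count

    def test_base_case(self):
        assert gamma_connected(1) == 1

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_exhaustive_enumeration(self, n):
        assert gamma_connected(n) == self.enumerate_connected(n)

    def test_recurrence_self_consistency_at_six(self):
        assert gamma_connected(6) == 26704

    def test_rejects_non_positive(self):
        with pytest.raises(InvalidArgumentError):
            gamma_connected(0)

    def test_edge_counts_sum_to_gamma(self):
        for n in range(1, 7):
            assert sum(connected_edge_counts(n)) == gamma_connected(n)


class TestCliqueConn:
    @pytest.mark.parametrize("k,expected", [(2, 0.5), (3, 0.625), (5, 874 / 1024)])
    def test_half_survival_closed_form(self, k, expected):
        assert clique_conn(k, 0.5) == pytest.approx(expected)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_agrees_with_exact_oracle(self, k):
        g = Graph.from_edges([(i, j) for i in range(k) for j in range(i + 1, k)])
        M = exact_connectivity(ProbabilisticGraph(g, 0.5), edge_cap=15)
        assert clique_conn(k, 0.5) == pytest.approx(M[(0, 1)], abs=1e-12)

    @pytest.mark.parametrize("p", [0.3, 0.7])
    def test_general_survival_against_oracle(self, p):
        g = Graph.from_edges([(i, j) for i in range(4) for j in range(i + 1, 4)])
        M = exact_connectivity(ProbabilisticGraph(g, p))
        assert clique_conn(4, p) == pytest.approx(M[(0, 1)], abs=1e-12)

    def test_monotone_in_clique_size(self):
        vals = [clique_conn(k, 0.5) for k in range(2, 9)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_rejects_degenerate_size(self):
        with pytest.raises(InvalidArgumentError):
            clique_conn(1, 0.5)


class TestSamplingHalfWidth:
    def test_printed_tolerances(self):
        assert round(sampling_half_width(20000, 0.95), 3) == 0.007
        assert round(sampling_half_width(500, 0.95), 2) == 0.04

    def test_quadrupling_samples_halves_width(self):
        assert sampling_half_width(4000, 0.95) == pytest.approx(
            sampling_half_width(1000, 0.95) / 2)

    def test_invalid_confidence(self):
        with pytest.raises(InvalidArgumentError):
            sampling_half_width(100, 1.0)
        with pytest.raises(InvalidArgumentError):
            sampling_half_width(0, 0.95)


class TestMonteCarloAgainstExact:
    def test_within_three_delta_on_random_graphs(self):
        rng = np.random.default_rng(99)
        for seed in range(10):
            nxg = nx.gnm_random_graph(6, 9, seed=100 + seed)
            g = Graph.from_edges(nxg.edges(), vertices=range(6))
            pg = ProbabilisticGraph(g, 0.5)
            exact = exact_connectivity(pg)
            est = estimate_connectivity(pg, 20000, rng)
            assert np.max(np.abs(exact.values - est.values)) <= 3 * est.delta
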