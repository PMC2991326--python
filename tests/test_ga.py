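"""Phase III: genetic-algorithm operators and driver."""

import itertools

import numpy as np
import pytest

from ppidecon.decomposition import DecompositionResult, decompose, reduce_instance
from ppidecon.dense import DenseRegionSet, sweep_dense_regions
from ppidecon.errors import DegenerateCutError, InvalidArgumentError
from ppidecon.ga import (Candidate, CutPartition, GAConfig, avg_connectivity,
                         crossover, decode, evaluate_fitness, init_population,
                         mutate, run_ga, sample_sparse_cut, select_parents)
from ppidecon.graphs import ConnectivityMatrix, Graph, ProbabilisticGraph
from ppidecon.netgen import generate_fixture
from ppidecon.reliability import exact_connectivity


def all_maybe_instance(graph, p=0.5):
    """Reduced instance with every pair undetermined (no Phase-I flags)."""
    M = exact_connectivity(ProbabilisticGraph(graph, p))
    dec = DecompositionResult(core_vertices=set(M.vertex_order))
    return reduce_instance(M, dec), M


class TestAvgConnectivity:
    def test_arithmetic(self):
        vals = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]])
        M = ConnectivityMatrix([0, 1, 2], vals)
        assert avg_connectivity(M, 0) == pytest.approx(0.75 / 3)

    def test_zero_row(self):
        vals = np.eye(3)
        M = ConnectivityMatrix([0, 1, 2], vals)
        assert avg_connectivity(M, 1) == 0.0

    def test_star_center_exceeds_leaves(self):
        g = Graph.from_edges([("s", c) for c in "abcd"])
        M = exact_connectivity(ProbabilisticGraph(g, 0.5))
        assert avg_connectivity(M, "s") == pytest.approx(2.0 / 5)
        for leaf in "abcd":
            assert avg_connectivity(M, leaf) == pytest.approx(1.25 / 5)
            assert avg_connectivity(M, "s") > avg_connectivity(M, leaf)

    def test_unknown_vertex(self):
        M = ConnectivityMatrix([0], np.ones((1, 1)))
        with pytest.raises(InvalidArgumentError):
            avg_connectivity(M, 99)


class TestInitPopulation:
    def test_empty_candidate_pairs_give_empty_candidates(self, path4_matrix):
        dec = decompose(path4_matrix)
        inst = reduce_instance(path4_matrix, dec)
        pop = init_population(inst, [], GAConfig(population_size=5), np.random.default_rng(0))
        assert all(c.edge_indices == () for c in pop)

    def test_dense_region_edges_forced_into_every_candidate(self):
        g = generate_fixture("planted_clique", {"n": 12, "k": 5, "seed": 3})
        inst, M = all_maybe_instance(g)
        dense = sweep_dense_regions(M, (5,))
        assert dense[0].regions  # the K5 is detected
        clique = dense[0].regions[0]
        forced = {inst.maybe_index[e] for e in
                  (tuple(sorted(p)) for p in itertools.combinations(sorted(clique), 2))}
        pop = init_population(inst, dense, GAConfig(population_size=8),
                              np.random.default_rng(1))
        for c in pop:
            assert forced <= set(c.edge_indices)

    def test_identical_seed_identical_population(self):
        g = generate_fixture("cycle", {"n": 6})
        inst, M = all_maybe_instance(g)
        p1 = init_population(inst, [], GAConfig(population_size=6), np.random.default_rng(5))
        p2 = init_population(inst, [], GAConfig(population_size=6), np.random.default_rng(5))
        assert [c.edge_indices for c in p1] == [c.edge_indices for c in p2]

    def test_candidates_are_connected(self):
        g = generate_fixture("cycle", {"n": 8})
        inst, M = all_maybe_instance(g)
        import networkx as nx
        for c in init_population(inst, [], GAConfig(population_size=10),
                                 np.random.default_rng(2)):
            assert nx.is_connected(decode(c, inst).graph.to_networkx())


class TestEvaluateFitness:
    def test_empty_matrix_and_candidate_match_everywhere(self):
        vals = np.eye(4)
        M = ConnectivityMatrix(list(range(4)), vals, delta=0.007)
        dec = DecompositionResult(core_vertices=set(range(4)))
        inst = reduce_instance(M, dec)
        f = evaluate_fitness(Candidate(()), inst, M, GAConfig(), np.random.default_rng(0))
        assert f == 6  # all C(4,2) pairs

    def test_missing_edge_scores_zero(self):
        vals = np.array([[1.0, 0.5], [0.5, 1.0]])
        M = ConnectivityMatrix([0, 1], vals, delta=0.007)
        dec = DecompositionResult(core_vertices={0, 1})
        inst = reduce_instance(M, dec)
        f = evaluate_fitness(Candidate(()), inst, M, GAConfig(), np.random.default_rng(0))
        assert f == 0

    def test_true_graph_attains_near_perfect_fitness(self):
        g = generate_fixture("cycle", {"n": 6})
        inst, M = all_maybe_instance(g)
        truth = Candidate(tuple(inst.maybe_index[e] for e in g.sorted_edges()))
        f = evaluate_fitness(truth, inst, M, GAConfig(fitness_samples=500),
                             np.random.default_rng(3))
        assert f >= 13  # 15 pairs, ≥95% within tolerance each


class TestSampleSparseCut:
    def inst_of(self, n):
        g = generate_fixture("cycle", {"n": n})
        inst, _ = all_maybe_instance(g)
        return inst

    def test_singleton_blocks_balance_evenly(self):
        inst = self.inst_of(10)
        cut = sample_sparse_cut(inst, [], np.random.default_rng(0))
        assert {len(cut.side1), len(cut.side2)} == {5}

    def test_regions_never_split(self):
        inst = self.inst_of(12)
        ds = DenseRegionSet(k=5, threshold=0.8,
                            regions=[frozenset(range(5)), frozenset(range(5, 10))])
        for seed in range(5):
            cut = sample_sparse_cut(inst, [ds], np.random.default_rng(seed))
            for r in ds.regions:
                assert r <= cut.side1 or r <= cut.side2

    def test_degenerate_when_one_block_dominates(self):
        inst = self.inst_of(10)
        ds = DenseRegionSet(k=5, threshold=0.8, regions=[frozenset(range(9))])
        with pytest.raises(DegenerateCutError):
            sample_sparse_cut(inst, [ds], np.random.default_rng(0))


class TestCrossover:
    def make_inst(self):
        g = Graph.from_edges([(1, 2), (3, 4), (1, 3), (2, 4)])
        inst, _ = all_maybe_instance(g)
        return inst

    def test_identical_parents_clone(self):
        inst = self.make_inst()
        cut = CutPartition(side1={1, 2}, side2={3, 4})
        c = Candidate((0, 2, 4))
        a, b = crossover(c, c, cut, inst)
        assert a.edge_indices == c.edge_indices == b.edge_indices

    def test_unshared_crossing_edges_dropped(self):
        inst = self.make_inst()
        cut = CutPartition(side1={1, 2}, side2={3, 4})
        e = inst.maybe_index
        g1 = Candidate((e[(1, 2)], e[(3, 4)], e[(1, 3)]))
        g2 = Candidate((e[(1, 2)], e[(3, 4)], e[(2, 4)]))
        a, b = crossover(g1, g2, cut, inst)
        expect = tuple(sorted((e[(1, 2)], e[(3, 4)])))
        assert a.edge_indices == expect and b.edge_indices == expect

    def test_shared_crossing_edge_survives(self):
        inst = self.make_inst()
        cut = CutPartition(side1={1, 2}, side2={3, 4})
        e = inst.maybe_index
        g1 = Candidate((e[(1, 2)], e[(3, 4)], e[(1, 3)]))
        g2 = Candidate((e[(1, 2)], e[(3, 4)], e[(1, 3)], e[(2, 4)]))
        a, b = crossover(g1, g2, cut, inst)
        expect = tuple(sorted((e[(1, 2)], e[(3, 4)], e[(1, 3)])))
        assert a.edge_indices == expect and b.edge_indices == expect


class TestMutate:
    def test_zero_rate_connected_candidate_unchanged(self):
        g = generate_fixture("cycle", {"n": 5})
        inst, _ = all_maybe_instance(g)
        truth = Candidate(tuple(inst.maybe_index[e] for e in g.sorted_edges()))
        out = mutate(truth, inst, GAConfig(mutation_rate=0.0), np.random.default_rng(0))
        assert out.edge_indices == truth.edge_indices

    def test_repair_bridges_split_components(self):
        g = Graph.from_edges([(0, 1), (1, 2), (2, 3), (3, 0)])
        inst, _ = all_maybe_instance(g)
        e = inst.maybe_index
        split = Candidate((e[(0, 1)], e[(2, 3)]))  # two components
        out = mutate(split, inst, GAConfig(mutation_rate=0.0), np.random.default_rng(0))
        import networkx as nx
        assert nx.is_connected(decode(out, inst).graph.to_networkx())

    def test_deterministic_under_seed(self):
        g = generate_fixture("cycle", {"n": 7})
        inst, _ = all_maybe_instance(g)
        c = Candidate(tuple(range(5)))
        o1 = mutate(c, inst, GAConfig(mutation_rate=0.3), np.random.default_rng(9))
        o2 = mutate(c, inst, GAConfig(mutation_rate=0.3), np.random.default_rng(9))
        assert o1.edge_indices == o2.edge_indices


class TestSelectParents:
    def test_equal_fitness_uniform(self):
        pop = [Candidate((0,), fitness=10), Candidate((1,), fitness=10)]
        picks = {select_parents(pop, np.random.default_rng(s))[0].edge_indices
                 for s in range(20)}
        assert picks == {(0,), (1,)}

    def test_worst_candidate_never_selected(self):
        pop = [Candidate((0,), fitness=5), Candidate((1,), fitness=10)]
        for s in range(30):
            p1, p2 = select_parents(pop, np.random.default_rng(s))
            assert p1.edge_indices == (1,) and p2.edge_indices == (1,)

    def test_linear_weighting(self):
        pop = [Candidate((0,), fitness=0), Candidate((1,), fitness=5),
               Candidate((2,), fitness=10)]
        rng = np.random.default_rng(0)
        counts = {(): 0, (1,): 0, (2,): 0}
        n = 3000
        hits = [select_parents(pop, rng)[0].edge_indices for _ in range(n)]
        f1 = hits.count((1,)) / n
        f2 = hits.count((2,)) / n
        assert hits.count((0,)) == 0
        assert f2 / f1 == pytest.approx(2.0, rel=0.15)

    def test_empty_population_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_parents([], np.random.default_rng(0))


class TestRunGA:
    def test_empty_candidate_pairs_short_circuit(self, path4_matrix):
        dec = decompose(path4_matrix)
        inst = reduce_instance(path4_matrix, dec)
        best, hist = run_ga(inst, inst.matrix, [], GAConfig(), np.random.default_rng(0))
        assert best.edge_indices == ()

    def test_reaches_exhaustive_optimum_on_small_core(self):
        g = Graph.from_edges([(0, 1), (1, 2), (2, 3), (0, 3), (0, 2)])
        inst, M = all_maybe_instance(g)
        cfg = GAConfig(population_size=30, generations=30, elitism_count=3)
        best, hist = run_ga(inst, M, [], cfg, np.random.default_rng(42))
        # oracle: evaluate every subset with one fixed seed block
        seed = 123
        oracle = max(
            evaluate_fitness(Candidate(s), inst, M, cfg, np.random.default_rng(seed))
            for r in range(len(inst.e_maybe) + 1)
            for s in itertools.combinations(range(len(inst.e_maybe)), r))
        refit = evaluate_fitness(best, inst, M, cfg, np.random.default_rng(seed))
        assert refit == oracle

    def test_history_is_monotone_nondecreasing(self):
        g = generate_fixture("cycle", {"n": 6})
        inst, M = all_maybe_instance(g)
        _, hist = run_ga(inst, M, [], GAConfig(population_size=10, generations=10),
                         np.random.default_rng(0))
        assert all(a <= b for a, b in zip(hist.best_fitness, hist.best_fitness[1:]))

    def test_deterministic_under_seed(self):
        g = generate_fixture("cycle", {"n": 6})
        inst, M = all_maybe_instance(g)
        cfg = GAConfig(population_size=8, generations=6)
        b1, h1 = run_ga(inst, M, [], cfg, np.random.default_rng(3))
        b2, h2 = run_ga(inst, M, [], cfg, np.random.default_rng(3))
        assert b1.edge_indices == b2.edge_indices
        assert h1.best_fitness == h2.best_fitness

    def test_history_tsv(self, tmp_path):
        g = generate_fixture("cycle", {"n": 5})
        inst, M = all_maybe_instance(g)
        _, hist = run_ga(inst, M, [], GAConfig(population_size=6, generations=3),
                         np.random.default_rng(0))
        out = tmp_path / "hist.tsv"
        hist.to_tsv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t") == ["generation", "best_fitness",
                                        "mean_fitness", "wall_seconds"]
        assert len(lines) == 5
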