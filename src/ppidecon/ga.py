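"""Phase III: cut-based genetic algorithm on the hard core.

The residual inference problem — which candidate pairs of the densely
connected core are direct interactions — is solved as a search over edge
subsets that maximizes the number of vertex pairs whose Monte-Carlo
connectivity matches the observed matrix within the tolerance δ.  The
search is a generational genetic algorithm with

* candidates encoded as sorted index lists into the candidate-pair table
  (forced meta-edges are implicit in every candidate),
* an initial population grown by preferential attachment with the vertex
  order weighted by average observed connectivity (a degree surrogate),
  dense-region edges included in every candidate,
* crossover guided by sparse balanced cuts that never split a merged dense
  region, so within-side structure survives mating,
* mutation as independent membership flips (~5-10% of current edges)
  followed by a greedy connectivity repair,
* selection proportional to fitness(c) − minFit, with elitism.

Fitness sampling reuses one block of random seeds per generation (common
random numbers) so that ranking noise is correlated across candidates.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .dense import DenseRegionSet, merged_blocks
from .decomposition import ReducedInstance
from .errors import (DegenerateCutError, InfeasibleInstanceError,
                     InvalidArgumentError)
from .graphs import ConnectivityMatrix, Edge, Graph, ProbabilisticGraph, Vertex, canonical_edge
from .reliability import estimate_connectivity, parallel_prob, sampling_half_width


@dataclass(frozen=True)
class Candidate:
    """A GA individual: sorted candidate-pair indices plus cached fitness.

    ``discrepancy`` caches the per-candidate-pair residual M − P̂ from the
    last fitness evaluation; mutation uses it to aim its flips.
    """

    edge_indices: Tuple[int, ...]
    fitness: Optional[int] = None
    discrepancy: Optional[np.ndarray] = field(default=None, compare=False,
                                              repr=False)

    def __post_init__(self):
        idx = tuple(sorted(set(self.edge_indices)))
        object.__setattr__(self, "edge_indices", idx)

    def with_fitness(self, f: int,
                     discrepancy: Optional[np.ndarray] = None) -> "Candidate":
        return replace(self, fitness=f, discrepancy=discrepancy)


@dataclass
class GAConfig:
    population_size: int = 500
    mutation_rate: float = 0.075
    fitness_samples: int = 500
    generations: int = 200
    time_budget: Optional[float] = None   # seconds; whichever limit hits first
    elitism_count: int = 5
    confidence: float = 0.95

    def __post_init__(self):
        if self.population_size < 2:
            raise InvalidArgumentError("population_size must be >= 2")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise InvalidArgumentError("mutation_rate must be in [0, 1]")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in ("population_size", "mutation_rate", "fitness_samples",
                      "generations", "time_budget", "elitism_count",
                      "confidence"):
                fh.write(f"{f}: {getattr(self, f)}\n")

    @staticmethod
    def from_file(path) -> "GAConfig":
        kwargs = {}
        casts = {"population_size": int, "fitness_samples": int,
                 "generations": int, "elitism_count": int,
                 "mutation_rate": float, "time_budget": float,
                 "confidence": float}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition(":")
                key, val = key.strip(), val.strip()
                if key not in casts:
                    raise InvalidArgumentError(f"unknown GA setting {key!r}")
                kwargs[key] = None if val == "None" else casts[key](val)
        return GAConfig(**kwargs)


@dataclass
class CutPartition:
    side1: Set[Vertex]
    side2: Set[Vertex]


@dataclass
class GAHistory:
    generations: List[int] = field(default_factory=list)
    best_fitness: List[int] = field(default_factory=list)
    mean_fitness: List[float] = field(default_factory=list)
    wall_seconds: List[float] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("generation\tbest_fitness\tmean_fitness\twall_seconds\n")
            for g, b, m, w in zip(self.generations, self.best_fitness,
                                  self.mean_fitness, self.wall_seconds):
                fh.write(f"{g}\t{b}\t{m:.2f}\t{w:.2f}\n")


# --------------------------------------------------------------- decoding

def decode(c: Candidate, inst: ReducedInstance) -> ProbabilisticGraph:
    """Probabilistic graph over the core: meta-edges keep their derived
    survival probabilities, selected candidate edges get p̂; a selected edge
    parallel to a meta-edge composes with it."""
    p_hat = inst.matrix.p_hat
    survival: Dict[Edge, float] = {m.pair: m.probability for m in inst.e_yes}
    for i in c.edge_indices:
        e = inst.e_maybe[i]
        if e in survival:
            survival[e] = parallel_prob(survival[e], p_hat)
        else:
            survival[e] = p_hat
    g = Graph.from_edges(survival.keys(), vertices=inst.core_vertices)
    return ProbabilisticGraph(g, p_hat=p_hat, survival=survival)


def avg_connectivity(M: ConnectivityMatrix, u: Vertex) -> float:
    """(1/|V|)·Σ_{v≠u} M(u,v): a proxy for the degree of u in the hidden graph."""
    i = M.index(u)
    return float((M.values[i].sum() - 1.0) / M.n)


# --------------------------------------------------------------- fitness

def evaluate_fitness(c: Candidate, inst: ReducedInstance, M: ConnectivityMatrix,
                     cfg: GAConfig, rng: np.random.Generator) -> int:
    """Count of vertex pairs whose sampled connectivity matches M within δ,
    where δ = max(matrix δ, half-width of the fitness sampler)."""
    return evaluate_candidate(c, inst, M, cfg, rng).fitness


def evaluate_candidate(c: Candidate, inst: ReducedInstance,
                       M: ConnectivityMatrix, cfg: GAConfig,
                       rng: np.random.Generator) -> Candidate:
    """Evaluate fitness and cache the per-pair discrepancy M − P̂."""
    n = M.n
    if n < 2:
        return c.with_fitness(0)
    pg = decode(c, inst)
    est = estimate_connectivity(pg, cfg.fitness_samples, rng,
                                confidence=cfg.confidence)
    # align orders (both sorted, but be safe)
    perm = [est.vertex_order.index(v) for v in M.vertex_order]
    P = est.values[np.ix_(perm, perm)]
    delta = max(M.delta, sampling_half_width(cfg.fitness_samples, cfg.confidence))
    iu, iv = np.triu_indices(n, k=1)
    fit = int(np.count_nonzero(np.abs(P[iu, iv] - M.values[iu, iv]) <= delta + 1e-12))
    D = M.values - P
    idx = np.array([[M.index(u), M.index(v)] for u, v in inst.e_maybe],
                   dtype=np.int64) if inst.e_maybe else np.empty((0, 2), dtype=np.int64)
    disc = D[idx[:, 0], idx[:, 1]] if len(idx) else np.empty(0)
    return c.with_fitness(fit, discrepancy=disc)


# ---------------------------------------------------------- initialization

def _repair(indices: Set[int], inst: ReducedInstance, M: ConnectivityMatrix) -> Set[int]:
    """Greedy connectivity repair: while the decoded graph is disconnected,
    add the candidate edge with the highest observed connectivity that joins
    two components; stop when no candidate edge can join any."""
    g = nx.Graph()
    g.add_nodes_from(inst.core_vertices)
    g.add_edges_from(m.pair for m in inst.e_yes)
    g.add_edges_from(inst.e_maybe[i] for i in indices)
    while True:
        comps = list(nx.connected_components(g))
        if len(comps) <= 1:
            return indices
        label = {}
        for ci, comp in enumerate(comps):
            for v in comp:
                label[v] = ci
        best, best_val = None, -1.0
        for i, (u, v) in enumerate(inst.e_maybe):
            if i not in indices and label[u] != label[v]:
                val = M[(u, v)]
                if val > best_val:
                    best, best_val = i, val
        if best is None:
            return indices  # disconnected instance: nothing can join
        indices.add(best)
        g.add_edge(*inst.e_maybe[best])


def init_population(inst: ReducedInstance, dense: Sequence[DenseRegionSet],
                    cfg: GAConfig, rng: np.random.Generator) -> List[Candidate]:
    """Preferential-attachment seeding of the population.

    Vertices enter in a random order biased by average connectivity; each
    new vertex attaches 1-2 candidate edges to earlier vertices chosen
    proportionally to their current degree.  All dense-region edges that
    are candidate pairs are included in every individual.
    """
    core = inst.core_vertices
    n = len(core)
    M = inst.matrix
    forced = {inst.maybe_index[canonical_edge(u, v)]
              for ds in dense for r in ds.regions
              for u in r for v in r
              if u != v and canonical_edge(u, v) in inst.maybe_index}
    if not inst.e_maybe or n < 2:
        return [Candidate(tuple(sorted(forced))) for _ in range(cfg.population_size)]
    weights = np.array([avg_connectivity(M, v) for v in core])
    weights = weights + 1e-9
    pop = []
    mask = plausible_mask(inst)
    adj_pairs: Dict[Vertex, List[int]] = {v: [] for v in core}
    for i, (u, v) in enumerate(inst.e_maybe):
        if mask[i]:
            adj_pairs[u].append(i)
            adj_pairs[v].append(i)
    for _ in range(cfg.population_size):
        # Gumbel-perturbed log-weights: equivalent to successive sampling
        # without replacement proportional to avg connectivity
        keys = np.log(weights) + rng.gumbel(size=n)
        order = np.argsort(-keys)
        added: List[Vertex] = []
        pos = {}
        degree: Dict[Vertex, int] = {}
        chosen: Set[int] = set(forced)
        for oi in order:
            w = core[oi]
            if added:
                cand = [i for i in adj_pairs[w]
                        if (inst.e_maybe[i][0] if inst.e_maybe[i][1] == w
                            else inst.e_maybe[i][1]) in pos]
                if cand:
                    k = min(int(rng.integers(1, 3)), len(cand))
                    ws = np.array([degree[(inst.e_maybe[i][0]
                                           if inst.e_maybe[i][1] == w
                                           else inst.e_maybe[i][1])] + 1.0
                                   for i in cand])
                    pick = rng.choice(len(cand), size=k, replace=False,
                                      p=ws / ws.sum())
                    for j in pick:
                        i = cand[j]
                        chosen.add(i)
                        a, b = inst.e_maybe[i]
                        degree[a] = degree.get(a, 0) + 1
                        degree[b] = degree.get(b, 0) + 1
            added.append(w)
            pos[w] = True
            degree.setdefault(w, 0)
        chosen = _repair(chosen, inst, M)
        pop.append(Candidate(tuple(sorted(chosen))))
    return pop


# ----------------------------------------------------------- GA operators

def sample_sparse_cut(inst: ReducedInstance, dense: Sequence[DenseRegionSet],
                      rng: np.random.Generator, imbalance: float = 0.2,
                      attempts: int = 50) -> CutPartition:
    """Random balanced partition of contracted dense blocks.

    Merged dense super-regions are weighted by vertex count and never
    split; the two sides must balance within ``imbalance`` of the total
    weight, else the cut is degenerate.
    """
    blocks = merged_blocks(dense, inst.core_vertices)
    if len(blocks) < 2:
        raise DegenerateCutError("core contracts to fewer than two blocks")
    wts = np.array([len(b) for b in blocks], dtype=float)
    total = wts.sum()
    best = None
    best_gap = np.inf
    for _ in range(attempts):
        perm = rng.permutation(len(blocks))
        w1 = 0.0
        side1 = []
        for i in perm:  # greedy: fill the lighter side
            if w1 + wts[i] <= total / 2 or not side1:
                side1.append(i)
                w1 += wts[i]
        gap = abs(total - 2 * w1)
        if gap < best_gap:
            best_gap, best = gap, side1
        if gap <= imbalance * total:
            break
    if best_gap > imbalance * total:
        raise DegenerateCutError(
            f"no balanced block partition (best imbalance {best_gap / total:.2f})")
    s1 = {v for i in best for v in blocks[i]}
    s2 = {v for i in range(len(blocks)) if i not in set(best) for v in blocks[i]}
    return CutPartition(side1=s1, side2=s2)


def crossover(g1: Candidate, g2: Candidate, cut: CutPartition,
              inst: ReducedInstance) -> Tuple[Candidate, Candidate]:
    """E' = E1(G1) ∪ E2(G2) ∪ (E12(G1) ∩ E12(G2)) and the mirror image.

    Within-side edge sets are inherited wholesale; crossing edges survive
    only when both parents agree.  Connectivity repair is deferred to
    mutation.
    """
    def classify(i: int) -> int:
        u, v = inst.e_maybe[i]
        in1 = (u in cut.side1) + (v in cut.side1)
        return {2: 1, 0: 2, 1: 0}[in1]  # 1: both side1, 2: both side2, 0: crossing

    s1, s2 = set(g1.edge_indices), set(g2.edge_indices)
    child1, child2 = set(), set()
    for i in s1 | s2:
        side = classify(i)
        if side == 0:
            if i in s1 and i in s2:
                child1.add(i)
                child2.add(i)
        elif side == 1:
            if i in s1:
                child1.add(i)
            if i in s2:
                child2.add(i)
        else:
            if i in s2:
                child1.add(i)
            if i in s1:
                child2.add(i)
    disc = None
    if g1.discrepancy is not None and g2.discrepancy is not None:
        disc = (g1.discrepancy + g2.discrepancy) / 2.0
    return (Candidate(tuple(sorted(child1)), discrepancy=disc),
            Candidate(tuple(sorted(child2)), discrepancy=disc))


def mutate(c: Candidate, inst: ReducedInstance, cfg: GAConfig,
           rng: np.random.Generator) -> Candidate:
    """Flip candidate-pair memberships (≈ mutation_rate of current edges
    change) and greedily repair connectivity."""
    total = len(inst.e_maybe)
    if total == 0:
        return c
    present = set(c.edge_indices)
    n_e = len(present)
    out = set(present)
    if cfg.mutation_rate > 0 and n_e > 0:
        expected = cfg.mutation_rate * n_e
        present_mask = np.zeros(total, dtype=bool)
        present_mask[list(present)] = True
        # Flips stay independent with ~mutation_rate x |edges| expected
        # changes, but their probabilities are aimed: an edge whose pair the
        # candidate already over-connects (P̂ > M) is the best deletion, a
        # pair the candidate under-connects (M > P̂) the best insertion.
        # Without an evaluation to guide them, insertions fall back to an
        # observed-connectivity bias and deletions to uniform.
        if c.discrepancy is not None and len(c.discrepancy) == total:
            D = c.discrepancy
            w_del = np.maximum(0.0, -D) + 0.01
            w_add = np.maximum(0.0, D) ** 2 + 1e-6
        else:
            w_del = np.ones(total)
            w_add = _insertion_weights(inst) + 1e-9
        w_del = np.where(present_mask, w_del, 0.0)
        w_add = np.where(present_mask, 0.0, w_add)
        p_del = np.minimum(1.0, expected * w_del / max(w_del.sum(), 1e-12))
        p_add = np.minimum(1.0, expected * w_add / max(w_add.sum(), 1e-12))
        flips = rng.random(total)
        out = {int(i) for i in np.flatnonzero(
            np.where(present_mask, flips >= p_del, flips < p_add))}
    out = _repair(out, inst, inst.matrix)
    if _n_components(out, inst) > _n_components_available(inst):
        raise InfeasibleInstanceError("instance admits no connected completion")
    return Candidate(tuple(sorted(out)))


def plausible_mask(inst: ReducedInstance) -> np.ndarray:
    """Admissibility screen over candidate pairs.

    Under the survival model a direct edge (u, v) guarantees
    P(u, v) ≥ p̂ — additional paths can only raise two-terminal
    reliability — so a pair observed at M(u, v) < p̂ − 2δ cannot be a
    direct interaction.  Search operators only ever introduce plausible
    pairs; the encoding itself is unchanged.
    """
    m = getattr(inst, "_plausible_mask", None)
    if m is None:
        M = inst.matrix
        cut = M.p_hat - 2 * M.delta - 1e-12
        m = np.array([M[e] >= cut for e in inst.e_maybe])
        inst._plausible_mask = m
    return m


def _insertion_weights(inst: ReducedInstance) -> np.ndarray:
    w = getattr(inst, "_insertion_weights", None)
    if w is None:
        M = inst.matrix
        w = np.array([M[e] ** 2 for e in inst.e_maybe])
        w[~plausible_mask(inst)] = 0.0
        inst._insertion_weights = w
    return w


def _n_components(indices: Set[int], inst: ReducedInstance) -> int:
    g = nx.Graph()
    g.add_nodes_from(inst.core_vertices)
    g.add_edges_from(m.pair for m in inst.e_yes)
    g.add_edges_from(inst.e_maybe[i] for i in indices)
    return nx.number_connected_components(g) if len(g) else 0


def _n_components_available(inst: ReducedInstance) -> int:
    g = nx.Graph()
    g.add_nodes_from(inst.core_vertices)
    g.add_edges_from(m.pair for m in inst.e_yes)
    g.add_edges_from(inst.e_maybe)
    return nx.number_connected_components(g) if len(g) else 0


def select_parents(pop: Sequence[Candidate],
                   rng: np.random.Generator) -> Tuple[Candidate, Candidate]:
    """Two draws with probability ∝ fitness(c) − minFit (uniform on ties)."""
    if not pop:
        raise InvalidArgumentError("empty population")
    fits = np.array([c.fitness for c in pop], dtype=float)
    if np.any(np.isnan(fits)):
        raise InvalidArgumentError("all candidates must have evaluated fitness")
    w = fits - fits.min()
    if w.sum() <= 0:
        w = np.ones(len(pop))
    w = w / w.sum()
    i, j = rng.choice(len(pop), size=2, p=w)
    return pop[int(i)], pop[int(j)]


# ----------------------------------------------------------------- driver

def run_ga(inst: ReducedInstance, M: ConnectivityMatrix,
           dense: Sequence[DenseRegionSet], cfg: GAConfig,
           rng: np.random.Generator) -> Tuple[Candidate, GAHistory]:
    """Generational GA with elitism; returns the best candidate ever seen
    and the per-generation best-fitness history (non-decreasing)."""
    history = GAHistory()
    if not inst.e_maybe:
        return Candidate(()), history
    t0 = time.time()
    pop = init_population(inst, dense, cfg, rng)
    best: Optional[Candidate] = None

    def evaluate_all(cands: List[Candidate], gen_seed: int) -> List[Candidate]:
        # common random numbers: same seed block for every candidate
        return [evaluate_candidate(c, inst, M, cfg,
                                   np.random.default_rng(gen_seed))
                for c in cands]

    for gen in range(cfg.generations + 1):
        gen_seed = int(rng.integers(0, 2 ** 31 - 1))
        pop = evaluate_all(pop, gen_seed)
        gen_best = max(pop, key=lambda c: c.fitness)
        if best is None or gen_best.fitness > best.fitness:
            best = gen_best
        history.generations.append(gen)
        history.best_fitness.append(best.fitness)
        history.mean_fitness.append(float(np.mean([c.fitness for c in pop])))
        history.wall_seconds.append(time.time() - t0)
        if gen == cfg.generations:
            break
        if cfg.time_budget is not None and time.time() - t0 > cfg.time_budget:
            break
        elite = sorted(pop, key=lambda c: -c.fitness)[:cfg.elitism_count]
        nxt: List[Candidate] = list(elite)
        while len(nxt) < cfg.population_size:
            p1, p2 = select_parents(pop, rng)
            try:
                cut = sample_sparse_cut(inst, dense, rng)
                c1, c2 = crossover(p1, p2, cut, inst)
            except DegenerateCutError:
                c1, c2 = p1, p2
            nxt.append(mutate(c1, inst, cfg, rng))
            if len(nxt) < cfg.population_size:
                nxt.append(mutate(c2, inst, cfg, rng))
        pop = nxt
    return best, history
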