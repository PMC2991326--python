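"""Orchestration of the three inference phases plus evaluation metrics.

``run_inference`` takes a connectivity matrix and returns the predicted
direct-interaction graph: Phase I (recursive cut-edge/1-cut detection and
degree-2 flagging to a fixpoint), Phase II (dense-region detection over a
sweep of clique sizes), instance reduction, and Phase III (the cut-based
genetic algorithm on the hard core).  The final edge set is the union of
the detected cut edges, the degree-2 edges, the expansion of the forced
meta-edges back into their constituent chains, and the GA-selected
candidate pairs.  All randomness derives from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .decomposition import (DecompositionResult, ReducedInstance, decompose,
                            reduce_instance)
from .dense import DEFAULT_K_SWEEP, DenseRegionSet, sweep_dense_regions
from .errors import InvalidArgumentError
from .ga import Candidate, GAConfig, GAHistory, run_ga
from .graphs import ConnectivityMatrix, Edge, Graph, canonical_edge


@dataclass
class InferenceConfig:
    ga: GAConfig = field(default_factory=GAConfig)
    k_sweep: Sequence[int] = DEFAULT_K_SWEEP
    seed: int = 0


@dataclass
class InferenceResult:
    graph: Graph
    decomposition: DecompositionResult
    dense: List[DenseRegionSet]
    instance: ReducedInstance
    ga_best: Candidate
    ga_history: GAHistory

    @property
    def phase1_edges(self) -> Set[Edge]:
        return set(self.decomposition.cut_edges) | set(self.decomposition.degree2_edges)


@dataclass
class EvaluationReport:
    """Edge-level confusion counts and the derived FDR/FNR percentages."""

    tp: int
    fp: int
    fn: int
    breakdown: dict = field(default_factory=dict)

    @property
    def fdr(self) -> float:
        return 100.0 * self.fp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def fnr(self) -> float:
        return 100.0 * self.fn / (self.tp + self.fn) if self.tp + self.fn else 0.0

    def summary(self) -> str:
        lines = [f"TP\t{self.tp}", f"FP\t{self.fp}", f"FN\t{self.fn}",
                 f"FDR(%)\t{self.fdr:.2f}", f"FNR(%)\t{self.fnr:.2f}"]
        for phase, rep in self.breakdown.items():
            lines.append(f"[{phase}] TP={rep.tp} FP={rep.fp} FN={rep.fn} "
                         f"FDR={rep.fdr:.2f}% FNR={rep.fnr:.2f}%")
        return "\n".join(lines) + "\n"


def run_inference(M: ConnectivityMatrix,
                  cfg: Optional[InferenceConfig] = None) -> InferenceResult:
    cfg = cfg or InferenceConfig()
    rng = np.random.default_rng(cfg.seed)
    if M.n == 0:
        empty = Graph(frozenset(), frozenset())
        return InferenceResult(empty, DecompositionResult(), [],
                               ReducedInstance([], M, [], set(), []),
                               Candidate(()), GAHistory())
    dec = decompose(M)
    dense = sweep_dense_regions(M, cfg.k_sweep) if M.n >= min(cfg.k_sweep, default=5) else []
    inst = reduce_instance(M, dec)
    # restrict dense regions to the core for GA guidance
    core = set(inst.core_vertices)
    dense_core = [DenseRegionSet(k=ds.k, threshold=ds.threshold,
                                 regions=[frozenset(r & core)
                                          for r in ds.regions if len(r & core) > 1])
                  for ds in dense]
    ga_rng = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
    best, history = run_ga(inst, inst.matrix, dense_core, cfg.ga, ga_rng)
    edges: Set[Edge] = set(dec.cut_edges) | set(dec.degree2_edges)
    for me in inst.e_yes:  # expand meta-edges back into their chains
        for path in me.paths:
            for a, b in zip(path, path[1:]):
                edges.add(canonical_edge(a, b))
    edges |= {inst.e_maybe[i] for i in best.edge_indices}
    graph = Graph.from_edges(edges, vertices=M.vertex_order)
    return InferenceResult(graph, dec, dense, inst, best, history)


def evaluate_prediction(predicted: Graph, truth: Graph) -> EvaluationReport:
    """Edge-level confusion of a prediction against the hidden truth."""
    if predicted.vertices != truth.vertices:
        raise InvalidArgumentError("prediction and truth must share the vertex universe")
    tp = len(predicted.edges & truth.edges)
    fp = len(predicted.edges - truth.edges)
    fn = len(truth.edges - predicted.edges)
    return EvaluationReport(tp=tp, fp=fp, fn=fn)


def evaluate_phases(result: InferenceResult, truth: Graph) -> EvaluationReport:
    """Full report with a per-phase breakdown (cut edges, degree-2 edges,
    dense-region edges, GA-selected edges)."""
    rep = evaluate_prediction(result.graph, truth)
    parts = {
        "1-cut": set(result.decomposition.cut_edges),
        "degree-2": set(result.decomposition.degree2_edges),
        "dense": {e for ds in result.dense for e in ds.region_edges},
        "ga": {result.instance.e_maybe[i] for i in result.ga_best.edge_indices},
    }
    for name, edges in parts.items():
        tp = len(edges & truth.edges)
        fp = len(edges - truth.edges)
        rep.breakdown[name] = EvaluationReport(tp=tp, fp=fp, fn=0)
    return rep
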