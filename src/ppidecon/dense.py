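"""Phase II: detection of dense regions (putative k-cliques / complexes).

Within a k-clique every vertex pair stays connected with probability at
least CliqueConn(k, p̂) — the two-terminal reliability of K_k — because any
additional structure outside the clique can only raise connectivity.
Thresholding the connectivity matrix at t_k = CliqueConn(k, p̂) − δ (the δ
slack absorbs sampling noise) therefore keeps every true k-clique complete
inside the threshold graph, and maximal-clique enumeration within each
connected component recovers the candidate regions.  False discoveries are
expected (dense quasi-cliques pass the same filter) and tolerated: regions
only seed and guide the genetic search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .errors import InvalidArgumentError
from .graphs import ConnectivityMatrix, Edge, Graph, Vertex, canonical_edge
from .reliability import clique_conn

DEFAULT_K_SWEEP = (7, 6, 5)
COMPONENT_GUARD = 60


@dataclass
class DenseRegionSet:
    k: int
    threshold: float
    regions: List[frozenset] = field(default_factory=list)
    region_edges: Set[Edge] = field(default_factory=set)

    def __post_init__(self):
        self.region_edges = set(self.region_edges) | {
            canonical_edge(u, v) for r in self.regions
            for u in r for v in r if str(u) < str(v)}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                ids = "\t".join(str(v) for v in sorted(r, key=str))
                fh.write(f"{self.k}\t{self.threshold:.6f}\t{ids}\n")


def build_threshold_graph(M: ConnectivityMatrix, t: float) -> Graph:
    """G_t = (V, {(u,v) : M(u,v) ≥ t})."""
    if not (0.0 <= t <= 1.0):
        raise InvalidArgumentError(f"threshold {t} outside [0, 1]")
    edges = [(M.vertex_order[i], M.vertex_order[j])
             for i in range(M.n) for j in range(i + 1, M.n)
             if M.values[i, j] >= t]
    return Graph.from_edges(edges, vertices=M.vertex_order)


def detect_dense_regions(M: ConnectivityMatrix, k: int,
                         component_guard: int = COMPONENT_GUARD) -> DenseRegionSet:
    """Maximal cliques of size ≥ k in the threshold graph at t_k − δ.

    Components larger than ``component_guard`` are reported whole as a
    single region rather than enumerated (clique enumeration can blow up;
    threshold components are small in practice).
    """
    if k < 3:
        raise InvalidArgumentError(f"minimum clique size must be >= 3, got {k}")
    t = clique_conn(k, M.p_hat) - M.delta
    g = build_threshold_graph(M, t).to_networkx()
    regions: List[frozenset] = []
    for comp in nx.connected_components(g):
        if len(comp) < k:
            continue
        if len(comp) > component_guard:
            regions.append(frozenset(comp))
            continue
        for clique in nx.find_cliques(g.subgraph(comp)):
            if len(clique) >= k:
                regions.append(frozenset(clique))
    regions.sort(key=lambda r: sorted(map(str, r)))
    return DenseRegionSet(k=k, threshold=t, regions=regions)


def sweep_dense_regions(M: ConnectivityMatrix,
                        ks: Sequence[int] = DEFAULT_K_SWEEP) -> List[DenseRegionSet]:
    """Run the detector for each k (descending); a region that is a subset of
    one already found at a larger k is dropped (larger k takes precedence)."""
    out: List[DenseRegionSet] = []
    kept: List[frozenset] = []
    for k in sorted(ks, reverse=True):
        ds = detect_dense_regions(M, k)
        fresh = [r for r in ds.regions
                 if not any(r <= other for other in kept)]
        kept.extend(fresh)
        out.append(DenseRegionSet(k=k, threshold=ds.threshold, regions=fresh))
    return out


def merged_blocks(region_sets: Iterable[DenseRegionSet],
                  universe: Iterable[Vertex]) -> List[frozenset]:
    """Disjoint super-regions: overlapping regions merged by union-find,
    remaining vertices as singleton blocks (used to weight crossover cuts)."""
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    universe = list(universe)
    for v in universe:
        parent[v] = v
    uni = set(universe)
    for ds in region_sets:
        for r in ds.regions:
            members = [v for v in r if v in uni]
            for a, b in zip(members, members[1:]):
                union(a, b)
    groups = {}
    for v in universe:
        groups.setdefault(find(v), set()).add(v)
    return sorted((frozenset(g) for g in groups.values()),
                  key=lambda b: sorted(map(str, b)))
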