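"""Phase I: weakly connected vertices and reduction to the hard core.

A cut edge (bridge) of the hidden network leaves a signature in the
connectivity matrix: its endpoints connect with probability exactly p̂, and
the two sides of the cut factorize (every cross pair satisfies
P(s,t) = P(s,u)·p̂·P(v,t)).  Recursively splitting on detected cut edges
resolves every *1-cut vertex* — a vertex all of whose incident edges are
cut edges.  Degree-2 vertices satisfy a separate triple of necessary
conditions and are flagged (not removed) together with their two incident
edges.  What remains after both detectors reach a fixpoint is the densely
connected *hard core*; forced degree-2 chains between core vertices are
contracted to meta-edges with derived survival probabilities, and the
remaining candidate pairs are indexed for the genetic search.

Tolerances: with a sampled matrix of half-width δ, the equality test of the
cut-edge criterion uses a ±2δ window (≈4 standard errors, so that none of
the hundreds of true cut edges is lost to sampling noise), while the
three-factor product tests use τ = 3δ to absorb first-order error
accumulation.  On exact matrices (δ = 0) all tests are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .errors import IntegrityError, InvalidArgumentError
from .graphs import ConnectivityMatrix, Edge, Vertex, canonical_edge

# tolerance multipliers (see module docstring)
COND1_SCALE = 2.0
TAU_SCALE = 3.0


def contract_parallel_paths(path_lengths: Sequence[int], p_hat: float) -> float:
    """Survival probability of a meta-edge bundling independent parallel paths.

    A path of L direct interactions survives with p̂^L; the bundle connects
    its endpoints unless every path fails: 1 − Π_i (1 − p̂^{L_i}).
    """
    if not path_lengths:
        raise InvalidArgumentError("at least one path length is required")
    if any(L < 1 for L in path_lengths):
        raise InvalidArgumentError("path lengths must be >= 1")
    fail = 1.0
    for L in path_lengths:
        fail *= 1.0 - p_hat ** L
    return 1.0 - fail


@dataclass
class DecompositionResult:
    """Cut edges, 1-cut vertices and degree-2 predictions extracted in Phase I."""

    cut_edges: Set[Edge] = field(default_factory=set)
    one_cut_vertices: Set[Vertex] = field(default_factory=set)
    degree2_vertices: Set[Vertex] = field(default_factory=set)
    degree2_edges: Set[Edge] = field(default_factory=set)
    degree2_neighbors: Dict[Vertex, Tuple[Vertex, Vertex]] = field(default_factory=dict)
    component_tree: Optional[dict] = None
    core_vertices: Set[Vertex] = field(default_factory=set)

    def to_report(self) -> str:
        lines = ["[CUT_EDGES]"]
        lines += [f"{u}\t{v}" for u, v in sorted(map(tuple, self.cut_edges), key=str)]
        lines.append("[ONE_CUT]")
        lines += [str(v) for v in sorted(self.one_cut_vertices, key=str)]
        lines.append("[DEG2]")
        for s in sorted(self.degree2_vertices, key=str):
            u, v = self.degree2_neighbors[s]
            lines.append(f"{s}\t{u}\t{v}")
        return "\n".join(lines) + "\n"


@dataclass
class MetaEdge:
    """A bundle of forced parallel degree-2 chains between two core vertices."""

    u: Vertex
    v: Vertex
    probability: float
    paths: List[List[Vertex]]  # each path as full vertex sequence u..v

    @property
    def pair(self) -> Edge:
        return canonical_edge(self.u, self.v)


@dataclass
class ReducedInstance:
    """The hard core: V3+, forced meta-edges, forbidden pairs, candidate pairs."""

    core_vertices: List[Vertex]
    matrix: ConnectivityMatrix
    e_yes: List[MetaEdge]
    e_no: Set[Edge]
    e_maybe: List[Edge]  # position in the list is the stable integer index

    def __post_init__(self):
        self.maybe_index = {e: i for i, e in enumerate(self.e_maybe)}

    def to_report(self) -> str:
        lines = ["[E_YES]"]
        for me in self.e_yes:
            lines.append(f"{me.u}\t{me.v}\t{me.probability:.6f}\t"
                         + ";".join("-".join(map(str, p)) for p in me.paths))
        lines.append("[E_NO]")
        lines += [f"{u}\t{v}" for u, v in sorted(map(tuple, self.e_no), key=str)]
        lines.append("[E_MAYBE]")
        lines += [f"{i}\t{u}\t{v}" for i, (u, v) in enumerate(self.e_maybe)]
        return "\n".join(lines) + "\n"


# ------------------------------------------------------------- cut edges

def check_cut_edge(M: ConnectivityMatrix, u: Vertex, v: Vertex,
                   subset: Optional[Sequence[int]] = None
                   ) -> Tuple[bool, Optional[Tuple[List[Vertex], List[Vertex]]]]:
    """Test whether (u, v) carries the cut-edge signature in M.

    Condition (i): M(u,v) lies within ±2δ of p̂.  Condition (ii): with
    V_u = {x : M(x,u) ≥ M(x,v)} and V_v its complement, every cross pair
    satisfies |M(s,t) − M(s,u)·p̂·M(v,t)| ≤ 3δ.  The self entries
    M(u,u) = M(v,v) = 1 take part in the products.  Returns the partition
    (as vertex lists) when the test passes; ``subset`` restricts the test
    to a sub-problem given as row indices.
    """
    ok, part, _ = _cut_edge_residual(M, u, v, subset)
    return ok, part


def _cut_edge_residual(M: ConnectivityMatrix, u: Vertex, v: Vertex,
                       subset: Optional[Sequence[int]] = None):
    """Cut-edge test returning the worst condition-(ii) residual.

    A series bottleneck through a nearby cut vertex can mimic a bridge
    within tolerance; its factorization residual is systematically larger
    than a true bridge's, so the recursion splits on the best-fitting
    candidate first (see ``_split``).
    """
    iu, iv = M.index(u), M.index(v)
    if iu == iv:
        raise InvalidArgumentError("u and v must differ")
    idx = np.asarray(subset if subset is not None else range(M.n), dtype=int)
    vals = M.values
    if abs(vals[iu, iv] - M.p_hat) > COND1_SCALE * M.delta + 1e-12:
        return False, None, np.inf
    side_u = vals[idx, iu] >= vals[idx, iv]
    Vu = idx[side_u]
    Vv = idx[~side_u]
    if len(Vv) == 0 or len(Vu) == 0:
        return False, None, np.inf
    lhs = vals[np.ix_(Vu, Vv)]
    rhs = np.outer(vals[Vu, iu], vals[iv, Vv]) * M.p_hat
    tau = TAU_SCALE * M.delta + 1e-12
    residual = float(np.max(np.abs(lhs - rhs)))
    if residual > tau:
        return False, None, np.inf
    part = ([M.vertex_order[i] for i in Vu], [M.vertex_order[i] for i in Vv])
    return True, part, residual


def decompose_one_cut(M: ConnectivityMatrix,
                      subset: Optional[Sequence[int]] = None) -> DecompositionResult:
    """Recursive cut-edge detection (the 1-cut part of Phase I).

    Splits the matrix on every detected cut edge (lexicographic vertex-id
    order), recursing into the two induced sub-problems until no pair
    qualifies.  A vertex left in a singleton leaf with at least one detected
    incident cut edge is a 1-cut vertex.  Vertices of non-singleton leaves
    form the unresolved residue (``core_vertices``).
    """
    res = DecompositionResult()
    idx0 = list(subset if subset is not None else range(M.n))
    # Pre-split by the "possibly connected" relation so disconnected inputs
    # are handled per component.
    vals = M.values
    g = nx.Graph()
    g.add_nodes_from(idx0)
    thr = max(COND1_SCALE * M.delta, 1e-12)
    for i, j in itertools.combinations(idx0, 2):
        if vals[i, j] > thr:
            g.add_edge(i, j)
    trees = []
    for comp in nx.connected_components(g):
        trees.append(_split(M, sorted(comp), res))
    res.component_tree = {"components": trees}
    res.core_vertices = {v for t in trees for leaf in _leaves(t)
                         if len(leaf) > 1 for v in leaf}
    return res


def _split(M: ConnectivityMatrix, idx: List[int], res: DecompositionResult) -> dict:
    vals = M.values
    p, d = M.p_hat, M.delta
    idx_arr = np.asarray(idx)
    # condition-(i) prefilter, then split on the best-fitting candidate:
    # the smallest factorization residual (ties broken lexicographically)
    sub = vals[np.ix_(idx_arr, idx_arr)]
    cand = np.argwhere(np.triu(np.abs(sub - p) <= COND1_SCALE * d + 1e-12, k=1))
    best = None
    for a, b in cand:
        i, j = idx_arr[a], idx_arr[b]
        u, v = M.vertex_order[i], M.vertex_order[j]
        ok, part, residual = _cut_edge_residual(M, u, v, subset=idx)
        if ok and (best is None or residual < best[0]):
            best = (residual, u, v, part)
    if best is not None:
        _, u, v, part = best
        res.cut_edges.add(canonical_edge(u, v))
        Vu = [M.index(x) for x in part[0]]
        Vv = [M.index(x) for x in part[1]]
        return {"vertices": [M.vertex_order[i] for i in idx],
                "cut_edge": canonical_edge(u, v),
                "left": _split(M, sorted(Vu), res),
                "right": _split(M, sorted(Vv), res)}
    leaf = {"vertices": [M.vertex_order[i] for i in idx]}
    if len(idx) == 1:
        w = M.vertex_order[idx[0]]
        if any(w in e for e in res.cut_edges):
            res.one_cut_vertices.add(w)
    return leaf


def _leaves(tree: dict):
    if "cut_edge" in tree:
        yield from _leaves(tree["left"])
        yield from _leaves(tree["right"])
    else:
        yield tree["vertices"]


# ---------------------------------------------------------- degree-2 flags

def detect_degree_two(M: ConnectivityMatrix,
                      subset: Optional[Sequence[int]] = None
                      ) -> Tuple[Set[Vertex], Set[Edge], Dict[Vertex, Tuple[Vertex, Vertex]]]:
    """Flag vertices carrying the degree-2 signature; return (V2, E2, neighbors).

    s is flagged when (i) every off-diagonal row entry is below
    2p̂ − p̂² + δ, (ii) the two largest entries agree within 2δ (an exact
    three-way tie — e.g. a star centre on an exact matrix — is an ambiguous
    neighbourhood and is rejected), and (iii) every remaining entry stays
    below max(M(u,t), M(v,t)) + 3δ for the two argmax vertices u, v.  On
    noisy matrices a third entry may fall within noise of the top two; the
    stable argmax pair is kept, so a predicted neighbour can occasionally
    be wrong, mirroring the small false-discovery rate this detector is
    expected to carry.
    """
    idx = list(subset if subset is not None else range(M.n))
    vals = M.values
    p, d = M.p_hat, M.delta
    bound = 2 * p - p * p + d + 1e-12
    tau = TAU_SCALE * d + 1e-12
    V2: Set[Vertex] = set()
    E2: Set[Edge] = set()
    nbrs: Dict[Vertex, Tuple[Vertex, Vertex]] = {}
    idx_arr = np.asarray(idx)
    for a, i in enumerate(idx):
        others = idx_arr[idx_arr != i]
        if len(others) < 2:
            continue
        row = vals[i, others]
        if np.max(row) >= bound:
            continue
        order = np.argsort(-row, kind="stable")
        v1, v2 = row[order[0]], row[order[1]]
        v3 = row[order[2]] if len(order) > 2 else -np.inf
        if v1 - v2 > 2 * d + 1e-12:       # the top two must tie
            continue
        if v2 - v3 <= 1e-12 and len(order) > 2:   # exact wider tie: ambiguous
            continue
        u_i, w_i = others[order[0]], others[order[1]]
        rest = others[(others != u_i) & (others != w_i)]
        if len(rest):
            cap = np.maximum(vals[u_i, rest], vals[w_i, rest]) + tau
            if np.any(vals[i, rest] >= cap):
                continue
        s = M.vertex_order[i]
        u, w = M.vertex_order[u_i], M.vertex_order[w_i]
        V2.add(s)
        E2.add(canonical_edge(s, u))
        E2.add(canonical_edge(s, w))
        nbrs[s] = (u, w)
    return V2, E2, nbrs


# ------------------------------------------------------------- fixpoint

def decompose(M: ConnectivityMatrix) -> DecompositionResult:
    """Run cut-edge and degree-2 detection alternately to a fixpoint.

    1-cut vertices are removed from the active set (their matrix entries are
    unaffected by the removal of cut edges); degree-2 vertices are marked
    but kept, as their removal would perturb the remaining entries.
    """
    res = DecompositionResult()
    active = list(range(M.n))
    while True:
        changed = False
        part = decompose_one_cut(M, subset=active)
        res.cut_edges |= part.cut_edges
        new_one_cut = part.one_cut_vertices - res.one_cut_vertices
        if new_one_cut:
            changed = True
            res.one_cut_vertices |= new_one_cut
            active = [i for i in active
                      if M.vertex_order[i] not in res.one_cut_vertices]
        V2, E2, nbrs = detect_degree_two(M, subset=active)
        if not (V2 <= res.degree2_vertices):
            changed = True
        res.degree2_vertices |= V2
        res.degree2_edges |= E2
        res.degree2_neighbors.update(nbrs)
        if res.component_tree is None:
            res.component_tree = part.component_tree
        if not changed:
            break
    res.core_vertices = ({M.vertex_order[i] for i in active}
                         - res.degree2_vertices)
    return res


# -------------------------------------------------------------- reduction

def reduce_instance(M: ConnectivityMatrix, dec: DecompositionResult) -> ReducedInstance:
    """Assemble the hard-core instance from a Phase-I decomposition.

    Forced degree-2 chains between core vertices become meta-edges whose
    survival probability combines the parallel paths; chains sharing an
    interior vertex with another chain (branching) are ambiguous and are
    left to the candidate pairs instead.  Every pair incident to a flagged
    degree-2 vertex, other than its two predicted edges, is forbidden.
    """
    for s in dec.degree2_vertices:
        for t in dec.degree2_neighbors.get(s, ()):
            if t not in M._index:
                raise IntegrityError(f"degree-2 neighbour {t!r} of {s!r} not in matrix")
    core = sorted(dec.core_vertices, key=str)
    core_set = set(core)
    deg2 = dec.degree2_vertices - core_set

    # Walk maximal chains of degree-2 vertices.  Consecutive flagged vertices
    # must list each other among their two predicted neighbours; a chain is
    # usable only if both walks terminate at (distinct) core vertices.
    meta: List[MetaEdge] = []
    meta_pairs: Dict[Edge, List[List[Vertex]]] = {}
    visited: Set[Vertex] = set()
    for s in sorted(deg2, key=str):
        if s in visited:
            continue
        chain = [s]
        visited.add(s)
        ok = True
        ends = []
        for direction in (0, 1):
            prev = s
            cur = dec.degree2_neighbors[s][direction]
            while True:
                if cur in core_set:
                    ends.append(cur)
                    break
                if cur not in deg2 or cur in visited:
                    ok = False  # branch into a used vertex or a deg2 cycle
                    break
                nb = dec.degree2_neighbors[cur]
                if prev not in nb:
                    ok = False  # non-reciprocal prediction: ambiguous
                    break
                visited.add(cur)
                if direction == 0:
                    chain.insert(0, cur)
                else:
                    chain.append(cur)
                nxt = nb[0] if nb[1] == prev else nb[1]
                prev, cur = cur, nxt
            if not ok:
                break
        if not ok or len(ends) != 2 or ends[0] == ends[1]:
            continue
        path = [ends[0]] + chain + [ends[1]]
        pair = canonical_edge(ends[0], ends[1])
        if pair[0] != path[0]:
            path = path[::-1]
        meta_pairs.setdefault(pair, []).append(path)
    for pair, paths in sorted(meta_pairs.items(), key=str):
        prob = contract_parallel_paths([len(p) - 1 for p in paths], M.p_hat)
        meta.append(MetaEdge(pair[0], pair[1], prob, paths))

    e_no: Set[Edge] = set()
    universe = core_set | deg2
    for s in deg2:
        allowed = set(dec.degree2_neighbors[s])
        for t in universe:
            if t != s and t not in allowed:
                e_no.add(canonical_edge(s, t))
    # A meta-edge encodes forced *chains*; a direct edge between the same
    # core pair is still undetermined, so every core pair is a candidate.
    e_maybe = [canonical_edge(u, v) for u, v in itertools.combinations(core, 2)]
    matrix = M.restrict(core) if core else ConnectivityMatrix([], np.zeros((0, 0)),
                                                              p_hat=M.p_hat,
                                                              delta=M.delta,
                                                              n_samples=M.n_samples)
    return ReducedInstance(core, matrix, meta, e_no, e_maybe)
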