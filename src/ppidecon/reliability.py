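"""Two-terminal network reliability: sampling, exact oracles and combinatorics.

The hidden direct-interaction network is modelled as a probabilistic graph
in which every edge survives the purification process independently with
probability p̂.  The probability that two vertices remain connected in a
random realization (the two-terminal reliability) is what a saturating set
of AP-MS experiments observes.  Exact computation is #P-complete in
general, so this module offers

* a Monte-Carlo estimator (one connected-component labelling per
  realization, all same-component pairs incremented at once),
* an exact oracle for small instances, factorized over biconnected
  components through the block-cut tree (series composition is exact
  across cut vertices),
* closed-form combinatorics for cliques (via the number of connected
  labelled graphs, counted by edges), and
* the worst-case binomial half-width used as the sampling tolerance δ.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm

from .errors import InvalidArgumentError, SizeLimitError
from .graphs import ConnectivityMatrix, Graph, ProbabilisticGraph

DEFAULT_EXACT_EDGE_CAP = 22


# --------------------------------------------------------------- sampling

def sample_realization(pg: ProbabilisticGraph, rng: np.random.Generator) -> Graph:
    """Draw one realization: each edge kept independently with its survival probability."""
    edges = pg.graph.sorted_edges()
    if not edges:
        return Graph(pg.graph.vertices, frozenset())
    probs = np.array([pg.edge_probability(u, v) for u, v in edges])
    keep = rng.random(len(edges)) < probs
    kept = [e for e, k in zip(edges, keep) if k]
    return Graph(pg.graph.vertices, frozenset(kept))


def estimate_connectivity(pg: ProbabilisticGraph, n_samples: int,
                          rng: np.random.Generator, confidence: float = 0.95,
                          batch_size: int = 256) -> ConnectivityMatrix:
    """Monte-Carlo estimate of the connectivity matrix.

    Entry (u, v) is the fraction of realizations in which u and v fall in
    the same connected component.  Realizations are processed in batches:
    each batch is labelled with a single sparse connected-components call on
    a block-diagonal union of the sampled subgraphs.
    """
    if n_samples < 1:
        raise InvalidArgumentError(f"n_samples must be >= 1, got {n_samples}")
    order = pg.graph.sorted_vertices()
    n = len(order)
    index = {v: i for i, v in enumerate(order)}
    edge_idx, probs = pg.edge_arrays(index)
    m = len(probs)
    counts = np.zeros((n, n), dtype=np.int64)
    done = 0
    while done < n_samples:
        b = min(batch_size, n_samples - done)
        if m:
            keep = rng.random((b, m)) < probs[None, :]
            offs = (np.arange(b, dtype=np.int64) * n)[:, None]
            rows = np.broadcast_to(edge_idx[:, 0], (b, m))[keep] + offs.repeat(m, 1)[keep]
            cols = np.broadcast_to(edge_idx[:, 1], (b, m))[keep] + offs.repeat(m, 1)[keep]
            data = np.ones(len(rows), dtype=np.int8)
            adj = sp.coo_matrix((data, (rows, cols)), shape=(b * n, b * n))
            _, labels = connected_components(adj, directed=False)
            labels = labels.reshape(b, n)
            counts += (labels[:, :, None] == labels[:, None, :]).sum(axis=0)
        else:
            counts += b * np.eye(n, dtype=np.int64)
        done += b
    values = counts / n_samples
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0
    delta = sampling_half_width(n_samples, confidence)
    return ConnectivityMatrix(order, values, p_hat=pg.p_hat, delta=delta,
                              n_samples=n_samples)


# ------------------------------------------------------------ exact oracle

def _enumerate_block(n: int, edges: Sequence[Tuple[int, int]],
                     probs: Sequence[float]) -> np.ndarray:
    """All-pairs reliability of one small (biconnected) block by subset enumeration."""
    m = len(edges)
    P = np.zeros((n, n))
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    q = np.asarray(probs, dtype=float)
    for mask in range(1 << m):
        prob = 1.0
        for j in range(m):
            prob *= q[j] if (mask >> j) & 1 else 1.0 - q[j]
        if prob == 0.0:
            continue
        for x in range(n):
            parent[x] = x
        for j in range(m):
            if (mask >> j) & 1:
                a, b = find(edges[j][0]), find(edges[j][1])
                if a != b:
                    parent[a] = b
        roots: Dict[int, List[int]] = {}
        for x in range(n):
            roots.setdefault(find(x), []).append(x)
        for members in roots.values():
            for a, b in itertools.combinations(members, 2):
                P[a, b] += prob
    P = P + P.T
    np.fill_diagonal(P, 1.0)
    return P


def exact_connectivity(pg: ProbabilisticGraph,
                       edge_cap: int = DEFAULT_EXACT_EDGE_CAP) -> ConnectivityMatrix:
    """Exact connectivity matrix by enumeration over biconnected blocks.

    Reliability factorizes over the block-cut tree: for u, v in the same
    component, P(u, v) is the product over the blocks along the unique tree
    path of the within-block reliabilities between entry and exit vertices.
    Each block is solved by enumerating its 2^|E| edge subsets; a block with
    more than ``edge_cap`` edges is refused.
    """
    order = pg.graph.sorted_vertices()
    n = len(order)
    index = {v: i for i, v in enumerate(order)}
    g = pg.graph.to_networkx()
    values = np.zeros((n, n))
    np.fill_diagonal(values, 1.0)

    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        blocks = [tuple(sorted(b, key=lambda e: (index[e[0]], index[e[1]])))
                  for b in nx.biconnected_component_edges(sub)]
        for b in blocks:
            if len(b) > edge_cap:
                raise SizeLimitError(
                    f"biconnected block with {len(b)} edges exceeds the exact-"
                    f"enumeration cap of {edge_cap}")
        # Reliability within each block, then series composition along the
        # block-cut tree.
        block_rel: List[Tuple[List, np.ndarray]] = []
        for b in blocks:
            verts = sorted({x for e in b for x in e}, key=lambda v: index[v])
            vmap = {v: i for i, v in enumerate(verts)}
            e_local = [(vmap[u], vmap[v]) for u, v in b]
            probs = [pg.edge_probability(u, v) for u, v in b]
            block_rel.append((verts, _enumerate_block(len(verts), e_local, probs)))
        # Block-cut tree: nodes are ('B', i) and ('C', cutvertex).
        tree = nx.Graph()
        cuts = set(nx.articulation_points(sub))
        home: Dict = {}
        for i, (verts, _) in enumerate(block_rel):
            tree.add_node(("B", i))
            for v in verts:
                if v in cuts:
                    tree.add_edge(("B", i), ("C", v))
                else:
                    home[v] = ("B", i)
        for v in cuts:
            home[v] = ("C", v)
        comp_list = sorted(comp, key=lambda v: index[v])
        paths = dict(nx.all_pairs_shortest_path(tree)) if len(tree) else {}
        for u, v in itertools.combinations(comp_list, 2):
            hu, hv = home[u], home[v]
            if hu == hv and hu[0] == "B":
                verts, P = block_rel[hu[1]]
                p = P[verts.index(u), verts.index(v)]
            else:
                path = paths[hu][hv]
                p = 1.0
                entry = u
                for node in path:
                    if node[0] != "B":
                        continue
                    verts, P = block_rel[node[1]]
                    inside = [x for x in path if x[0] == "C" and x[1] in verts]
                    # exit vertex: the next cut vertex on the path, or v itself
                    later = [x[1] for x in path[path.index(node) + 1:] if x[0] == "C"]
                    exit_v = next((c for c in later if c in verts), v)
                    p *= P[verts.index(entry), verts.index(exit_v)]
                    entry = exit_v
            values[index[u], index[v]] = values[index[v], index[u]] = p
    return ConnectivityMatrix(order, values, p_hat=pg.p_hat, delta=0.0, n_samples=0)


# -------------------------------------------------- composition & counting

def series_prob(p1: float, p2: float) -> float:
    """Reliability of two independent connections joined in series."""
    _check_prob(p1)
    _check_prob(p2)
    return p1 * p2


def parallel_prob(p1: float, p2: float) -> float:
    """Reliability of two independent connections joined in parallel."""
    _check_prob(p1)
    _check_prob(p2)
    return p1 + p2 - p1 * p2


def _check_prob(p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise InvalidArgumentError(f"probability {p} outside [0, 1]")


@lru_cache(maxsize=None)
def gamma_connected(n: int) -> int:
    """Number of connected simple graphs on n labelled vertices (exact integer).

    γ_1 = 1 and
    γ_n = 2^C(n,2) − (1/n)·Σ_{i=1..n−1} i·C(n,i)·2^C(n−i,2)·γ_i.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if n == 1:
        return 1
    total = 2 ** math.comb(n, 2)
    s = sum(i * math.comb(n, i) * 2 ** math.comb(n - i, 2) * gamma_connected(i)
            for i in range(1, n))
    assert s % n == 0
    return total - s // n


@lru_cache(maxsize=None)
def connected_edge_counts(n: int) -> Tuple[int, ...]:
    """Coefficients c_j = number of connected graphs on n labelled vertices
    with exactly j edges, j = 0..C(n,2).

    Computed from the generating-polynomial identity
    (1+x)^C(n,2) = Σ_i C(n−1, i−1) · C_i(x) · (1+x)^C(n−i,2),
    where C_i(x) is the edge-generating polynomial of connected graphs on i
    labelled vertices (the polynomial containing vertex 1, say).
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if n == 1:
        return (1,)
    total = _binom_poly(math.comb(n, 2))
    for i in range(1, n):
        ci = connected_edge_counts(i)
        term = _poly_mul(ci, _binom_poly(math.comb(n - i, 2)))
        coef = math.comb(n - 1, i - 1)
        total = _poly_sub(total, tuple(coef * t for t in term))
    return tuple(total)


def _binom_poly(m: int) -> Tuple[int, ...]:
    return tuple(math.comb(m, j) for j in range(m + 1))


def _poly_mul(a, b):
    out = [0] * (len(a) + len(b) - 1)
    for i, x in enumerate(a):
        if x:
            for j, y in enumerate(b):
                out[i + j] += x * y
    return tuple(out)


def _poly_sub(a, b):
    out = list(a) + [0] * max(0, len(b) - len(a))
    for j, y in enumerate(b):
        out[j] -= y
    return tuple(out)


def clique_conn(k: int, p_hat: float = 0.5) -> float:
    """Two-terminal reliability of the complete graph K_k between a fixed pair.

    The component containing the two terminals spans some i-subset that
    includes both; summing over the subset size,

        P = Σ_{i=2..k} C(k−2, i−2) · C_i(p̂) · (1−p̂)^{i·(k−i)},

    where C_i(p̂) = Σ_j c_{i,j} p̂^j (1−p̂)^{C(i,2)−j} is the probability
    that i given vertices induce a connected spanning subgraph.  At
    p̂ = 1/2 this reduces to Σ_i C(k−2, i−2)·γ_i / 2^{C(k,2)−C(k−i,2)}.
    """
    if k < 2:
        raise InvalidArgumentError(f"clique size must be >= 2, got {k}")
    _check_prob(p_hat)
    q = 1.0 - p_hat
    total = 0.0
    for i in range(2, k + 1):
        cj = connected_edge_counts(i)
        ci = sum(c * p_hat ** j * q ** (math.comb(i, 2) - j)
                 for j, c in enumerate(cj))
        total += math.comb(k - 2, i - 2) * ci * q ** (i * (k - i))
    return float(total)


def sampling_half_width(n_samples: int, confidence: float = 0.95) -> float:
    """Worst-case (p = 0.5) half-width of a binomial confidence interval.

    δ = z_{1−α/2} / (2·√n): the largest half-width of the normal
    approximation to the sampling error of a connectivity estimate, used as
    the additive tolerance attached to Monte-Carlo matrices.
    """
    if n_samples < 1:
        raise InvalidArgumentError(f"n_samples must be >= 1, got {n_samples}")
    if not (0.0 < confidence < 1.0):
        raise InvalidArgumentError(f"confidence must be in (0, 1), got {confidence}")
    z = norm.ppf(0.5 + confidence / 2.0)
    return float(z / (2.0 * math.sqrt(n_samples)))
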