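"""Comparison methods: randomized hill-climbing and a random-edge baseline.

Hill-climbing starts from a spanning tree sampled with edge preference
proportional to the observed connectivity, then repeatedly samples the
current candidate's connectivity matrix, draws a vertex pair proportional
to its discrepancy D(u,v) = |M(u,v) − P(u,v)|, and toggles the edge in the
direction that reduces the discrepancy — rejecting removals that would
disconnect the graph.
"""

from __future__ import annotations

import math
from typing import Optional

import networkx as nx
import numpy as np

from .errors import InvalidArgumentError
from .graphs import ConnectivityMatrix, Graph, ProbabilisticGraph, canonical_edge
from .reliability import estimate_connectivity


def random_spanning_tree(M: ConnectivityMatrix, rng: np.random.Generator) -> Graph:
    """Weighted randomized growth: repeatedly attach a non-tree vertex through
    a frontier pair drawn with probability proportional to M(u, v)."""
    n = M.n
    if n < 2:
        raise InvalidArgumentError("need at least two vertices")
    in_tree = np.zeros(n, dtype=bool)
    in_tree[int(rng.integers(n))] = True
    edges = []
    vals = M.values
    for _ in range(n - 1):
        ti = np.flatnonzero(in_tree)
        oi = np.flatnonzero(~in_tree)
        w = vals[np.ix_(ti, oi)].ravel()
        if w.sum() <= 0:
            w = np.ones_like(w)
        pick = int(rng.choice(len(w), p=w / w.sum()))
        u = ti[pick // len(oi)]
        v = oi[pick % len(oi)]
        edges.append((M.vertex_order[u], M.vertex_order[v]))
        in_tree[v] = True
    return Graph.from_edges(edges, vertices=M.vertex_order)


def hill_climb(M: ConnectivityMatrix, max_iters: int, n_samples: int = 500,
               rng: Optional[np.random.Generator] = None,
               start: Optional[Graph] = None) -> Graph:
    """Randomized local search on the discrepancy to the observed matrix."""
    if max_iters < 0:
        raise InvalidArgumentError("max_iters must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    g = (start or random_spanning_tree(M, rng)).to_networkx()
    n = M.n
    order = M.vertex_order
    iu, iv = np.triu_indices(n, k=1)
    for _ in range(max_iters):
        pg = ProbabilisticGraph(Graph.from_networkx(g), p_hat=M.p_hat)
        P = estimate_connectivity(pg, n_samples, rng).values
        D = np.abs(M.values - P)[iu, iv]
        if D.sum() <= 0:
            break
        k = int(rng.choice(len(D), p=D / D.sum()))
        u, v = order[iu[k]], order[iv[k]]
        muv, puv = M.values[iu[k], iv[k]], P[iu[k], iv[k]]
        if g.has_edge(u, v) and muv < puv:
            g.remove_edge(u, v)
            if not nx.is_connected(g):
                g.add_edge(u, v)  # rejected move; iteration consumed
        elif not g.has_edge(u, v) and muv > puv:
            g.add_edge(u, v)
    return Graph.from_networkx(g)


def random_edge_baseline(n_vertices: int, m_edges: int,
                         rng: np.random.Generator) -> Graph:
    """m distinct vertex pairs drawn uniformly without replacement."""
    total = math.comb(n_vertices, 2)
    if m_edges > total:
        raise InvalidArgumentError(f"{m_edges} edges exceed C({n_vertices},2) = {total}")
    pairs = [(i, j) for i in range(n_vertices) for j in range(i + 1, n_vertices)]
    pick = rng.choice(total, size=m_edges, replace=False) if m_edges else []
    return Graph.from_edges([pairs[int(i)] for i in pick], vertices=range(n_vertices))
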