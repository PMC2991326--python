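"""Synthetic ground-truth networks: scale-free generators and fixtures.

Two growth models emulate the topology of protein-interaction networks:

* ``pam`` — preferential attachment with attachment factor 1.5: growth
  starts from a single edge and every new vertex attaches 1 or 2 edges
  (uniformly) to existing vertices chosen proportionally to their degree.
  Such graphs are triangle-sparse: a new vertex brings at most two edges,
  so no 4-clique can ever close and the clique number is at most 3.
* ``dm`` — duplication model: starting from a triangle, each step picks an
  existing vertex with probability proportional to its degree, duplicates
  it, and retains each copied edge independently (retention 0.5 by
  default, redrawing when no edge survives so the graph stays connected).
  Duplication copies shared neighbourhoods and therefore produces far more
  triangles and dense clusters than preferential attachment.

``generate_fixture`` builds the small deterministic graphs used across the
test-suite (paths, cycles, cliques, random trees, planted cliques).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .errors import InvalidArgumentError
from .graphs import Graph


@dataclass
class GeneratorConfig:
    model: str = "pam"                 # pam | dm | tree | clique | planted
    n_vertices: int = 1000
    attachment_low: int = 1            # pam: min edges per new vertex
    attachment_high: int = 2           # pam: max edges per new vertex
    retention: float = 0.5             # dm: per-edge copy retention
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_vertices < 2:
            raise InvalidArgumentError("n_vertices must be >= 2")
        if not (1 <= self.attachment_low <= self.attachment_high):
            raise InvalidArgumentError("need 1 <= attachment_low <= attachment_high")
        if not (0.0 < self.retention <= 1.0):
            raise InvalidArgumentError("retention must be in (0, 1]")


def generate_pam(cfg: GeneratorConfig, rng: np.random.Generator) -> Graph:
    """Preferential-attachment growth (expected edge count ≈ 1.5·(n−2)+1)."""
    n = cfg.n_vertices
    degree = np.zeros(n, dtype=np.int64)
    edges = [(0, 1)]
    degree[0] = degree[1] = 1
    for w in range(2, n):
        k = int(rng.integers(cfg.attachment_low, cfg.attachment_high + 1))
        k = min(k, w)
        p = degree[:w] / degree[:w].sum()
        targets = rng.choice(w, size=k, replace=False, p=p)
        for t in targets:
            edges.append((int(t), w))
            degree[t] += 1
            degree[w] += 1
    return Graph.from_edges(edges, vertices=range(n),
                            metadata={"model": "pam", "n": n})


def generate_dm(cfg: GeneratorConfig, rng: np.random.Generator) -> Graph:
    """Duplication-model growth from a seed triangle.

    The duplicate is not connected to its parent; duplications retaining
    zero edges are redrawn so the graph stays connected.
    """
    n = cfg.n_vertices
    if n < 3:
        raise InvalidArgumentError("duplication model needs n >= 3")
    adj = {0: {1, 2}, 1: {0, 2}, 2: {0, 1}}
    degree = np.zeros(n, dtype=np.int64)
    degree[:3] = 2
    for w in range(3, n):
        while True:
            p = degree[:w] / degree[:w].sum()
            parent = int(rng.choice(w, p=p))
            nbrs = list(adj[parent])
            keep = [v for v in nbrs if rng.random() < cfg.retention]
            if keep:
                break
        adj[w] = set(keep)
        degree[w] = len(keep)
        for v in keep:
            adj[v].add(w)
            degree[v] += 1
    edges = [(u, v) for u, nb in adj.items() for v in nb if u < v]
    return Graph.from_edges(edges, vertices=range(n),
                            metadata={"model": "dm", "n": n,
                                      "retention": cfg.retention})


def generate_fixture(kind: str, params: dict,
                     rng: Optional[np.random.Generator] = None) -> Graph:
    """Canonical small graphs used across the tests.

    kinds: ``path`` (n), ``cycle`` (n), ``clique`` (k), ``tree`` (n, seed),
    ``planted_clique`` (n, k, seed) — a random-tree backbone with one K_k
    planted on randomly chosen vertices (recorded in the metadata).
    """
    if kind == "path":
        n = params["n"]
        if n < 2:
            raise InvalidArgumentError("path needs n >= 2")
        return Graph.from_edges([(i, i + 1) for i in range(n - 1)])
    if kind == "cycle":
        n = params["n"]
        if n < 3:
            raise InvalidArgumentError("cycle needs n >= 3")
        return Graph.from_edges([(i, (i + 1) % n) for i in range(n)])
    if kind == "clique":
        k = params["k"]
        if k < 2:
            raise InvalidArgumentError("clique needs k >= 2")
        return Graph.from_edges([(i, j) for i in range(k) for j in range(i + 1, k)])
    if kind == "tree":
        n = params["n"]
        seed = params.get("seed", 0)
        t = nx.random_labeled_tree(n, seed=seed)
        return Graph.from_edges(t.edges(), vertices=range(n))
    if kind == "planted_clique":
        n, k = params["n"], params["k"]
        seed = params.get("seed", 0)
        if k > n:
            raise InvalidArgumentError("clique size exceeds vertex count")
        rng = rng or np.random.default_rng(seed)
        t = nx.random_labeled_tree(n, seed=seed)
        members = sorted(rng.choice(n, size=k, replace=False).tolist())
        edges = list(t.edges()) + [(members[i], members[j])
                                   for i in range(k) for j in range(i + 1, k)]
        return Graph.from_edges(edges, vertices=range(n),
                                metadata={"clique": members})
    raise InvalidArgumentError(f"unknown fixture kind {kind!r}")
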