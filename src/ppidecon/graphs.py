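"""Core data containers: graphs, probabilistic graphs and connectivity matrices.

A :class:`Graph` is a plain undirected simple graph over opaque, sortable
vertex ids.  A :class:`ProbabilisticGraph` attaches to every edge a survival
probability -- the chance that the physical interaction it represents
survives an affinity-purification experiment.  A :class:`ConnectivityMatrix`
holds, for every vertex pair, the probability that the two vertices remain
connected after each edge independently survives or breaks, together with
the sampling tolerance attached to those estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from .errors import InvalidArgumentError

Vertex = Hashable
Edge = Tuple[Vertex, Vertex]


def canonical_edge(u: Vertex, v: Vertex) -> Edge:
    """Return the unordered pair (u, v) in canonical (sorted) order."""
    if u == v:
        raise InvalidArgumentError(f"self-loop ({u!r}, {u!r}) is not a valid edge")
    return (u, v) if _key(u) <= _key(v) else (v, u)


def _key(v: Vertex):
    # Sort heterogeneous vertex ids deterministically.
    return (str(type(v).__name__), v) if not isinstance(v, (int, str)) else (("int", v) if isinstance(v, int) else ("str", v))


@dataclass(frozen=True)
class Graph:
    """An undirected simple graph: a vertex set and a set of unordered pairs."""

    vertices: frozenset
    edges: frozenset
    metadata: Optional[dict] = field(default=None, compare=False)

    @staticmethod
    def from_edges(edges: Iterable[Edge], vertices: Iterable[Vertex] = (),
                   metadata: Optional[dict] = None) -> "Graph":
        es = frozenset(canonical_edge(u, v) for u, v in edges)
        vs = set(vertices)
        for u, v in es:
            vs.add(u)
            vs.add(v)
        return Graph(frozenset(vs), es, metadata)

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise InvalidArgumentError("graph contains a self-loop")
            if u not in self.vertices or v not in self.vertices:
                raise InvalidArgumentError(f"edge ({u!r}, {v!r}) has an unlisted endpoint")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_vertices(self) -> List[Vertex]:
        return sorted(self.vertices, key=_key)

    def sorted_edges(self) -> List[Edge]:
        return sorted(self.edges, key=lambda e: (_key(e[0]), _key(e[1])))

    def has_edge(self, u: Vertex, v: Vertex) -> bool:
        return canonical_edge(u, v) in self.edges

    def degree(self, v: Vertex) -> int:
        return sum(1 for e in self.edges if v in e)

    def neighbors(self, v: Vertex) -> set:
        return {u if w == v else w for u, w in self.edges if v in (u, w)} - {v}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    @staticmethod
    def from_networkx(g: nx.Graph) -> "Graph":
        return Graph.from_edges(g.edges(), vertices=g.nodes())


@dataclass(frozen=True)
class ProbabilisticGraph:
    """A graph whose edges survive independently with given probabilities.

    ``survival`` overrides the uniform default ``p_hat`` per edge; every
    probability must lie in (0, 1].
    """

    graph: Graph
    p_hat: float = 0.5
    survival: Mapping[Edge, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.p_hat <= 1.0):
            raise InvalidArgumentError(f"p_hat must be in (0, 1], got {self.p_hat}")
        canon = {}
        for (u, v), p in dict(self.survival).items():
            e = canonical_edge(u, v)
            if e not in self.graph.edges:
                raise InvalidArgumentError(f"survival given for non-edge {e!r}")
            if not (0.0 < p <= 1.0):
                raise InvalidArgumentError(f"survival probability {p} for {e!r} outside (0, 1]")
            canon[e] = float(p)
        object.__setattr__(self, "survival", canon)

    def edge_probability(self, u: Vertex, v: Vertex) -> float:
        return self.survival.get(canonical_edge(u, v), self.p_hat)

    def edge_arrays(self, index: Mapping[Vertex, int]) -> Tuple[np.ndarray, np.ndarray]:
        """Edges as an (m, 2) int array plus an (m,) survival-probability array."""
        edges = self.graph.sorted_edges()
        if not edges:
            return np.empty((0, 2), dtype=np.int64), np.empty(0)
        idx = np.array([[index[u], index[v]] for u, v in edges], dtype=np.int64)
        probs = np.array([self.edge_probability(u, v) for u, v in edges])
        return idx, probs


class ConnectivityMatrix:
    """Symmetric matrix of pairwise connection probabilities.

    ``values[i, j]`` estimates the probability that vertices ``vertex_order[i]``
    and ``vertex_order[j]`` end up in the same connected component of a random
    realization of the hidden direct-interaction graph.  ``delta`` is the
    additive sampling tolerance attached to every entry (0 for exact
    matrices), ``n_samples`` the Monte-Carlo sample count (0 if analytic).
    """

    def __init__(self, vertex_order: List[Vertex], values: np.ndarray,
                 p_hat: float = 0.5, delta: float = 0.0, n_samples: int = 0):
        values = np.asarray(values, dtype=float)
        n = len(vertex_order)
        if values.shape != (n, n):
            raise InvalidArgumentError(f"matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12):
            raise InvalidArgumentError("connectivity matrix must be symmetric")
        if values.size and (values.min() < -1e-12 or values.max() > 1 + 1e-12):
            raise InvalidArgumentError("connectivity values must lie in [0, 1]")
        if not np.allclose(np.diag(values), 1.0):
            raise InvalidArgumentError("diagonal entries must equal 1")
        self.vertex_order = list(vertex_order)
        self.values = np.clip(values, 0.0, 1.0)
        self.p_hat = float(p_hat)
        self.delta = float(delta)
        self.n_samples = int(n_samples)
        self._index = {v: i for i, v in enumerate(self.vertex_order)}
        if len(self._index) != n:
            raise InvalidArgumentError("duplicate vertex ids in vertex_order")

    @property
    def n(self) -> int:
        return len(self.vertex_order)

    def index(self, v: Vertex) -> int:
        try:
            return self._index[v]
        except KeyError:
            raise InvalidArgumentError(f"unknown vertex {v!r}") from None

    def __getitem__(self, pair: Edge) -> float:
        u, v = pair
        return float(self.values[self.index(u), self.index(v)])

    def restrict(self, vertices: Iterable[Vertex]) -> "ConnectivityMatrix":
        """Submatrix over the given vertices (kept in this matrix's order)."""
        keep = [v for v in self.vertex_order if v in set(vertices)]
        idx = [self._index[v] for v in keep]
        return ConnectivityMatrix(keep, self.values[np.ix_(idx, idx)],
                                  p_hat=self.p_hat, delta=self.delta,
                                  n_samples=self.n_samples)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path) -> None:
        """Write as TSV: header row of vertex ids, first column vertex ids."""
        with open(path, "w") as fh:
            fh.write("#p_hat=%.6f\tdelta=%.6f\tn_samples=%d\n"
                     % (self.p_hat, self.delta, self.n_samples))
            fh.write("\t" + "\t".join(str(v) for v in self.vertex_order) + "\n")
            for i, v in enumerate(self.vertex_order):
                row = "\t".join("%.6f" % x for x in self.values[i])
                fh.write(f"{v}\t{row}\n")

    @staticmethod
    def from_tsv(path) -> "ConnectivityMatrix":
        p_hat, delta, n_samples = 0.5, 0.0, 0
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if lines and lines[0].startswith("#"):
            meta = dict(tok.split("=") for tok in lines[0][1:].split("\t"))
            p_hat = float(meta.get("p_hat", 0.5))
            delta = float(meta.get("delta", 0.0))
            n_samples = int(meta.get("n_samples", 0))
            lines = lines[1:]
        header = lines[0].split("\t")[1:]
        order = [_parse_id(t) for t in header]
        vals = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]])
        # Round-trip at 6 decimals can leave symmetric entries off by <1e-6.
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 1.0)
        return ConnectivityMatrix(order, vals, p_hat=p_hat, delta=delta,
                                  n_samples=n_samples)


def _parse_id(token: str):
    try:
        return int(token)
    except ValueError:
        return token


# --------------------------------------------------------------- edge lists

def write_edge_list(graph: Graph, path, survival: Optional[Mapping[Edge, float]] = None,
                    header: Optional[str] = None) -> None:
    """Two-column TSV edge list, optional third column of survival probabilities."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for u, v in graph.sorted_edges():
            if survival is not None:
                fh.write(f"{u}\t{v}\t{survival.get(canonical_edge(u, v), ''):.6f}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_edge_list(path) -> Tuple[Graph, Dict[Edge, float]]:
    edges, survival = [], {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            u, v = _parse_id(parts[0]), _parse_id(parts[1])
            edges.append((u, v))
            if len(parts) > 2 and parts[2]:
                survival[canonical_edge(u, v)] = float(parts[2])
    return Graph.from_edges(edges), survival
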