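"""Core graph representation and shortest-path machinery.

The :class:`Network` type is a thin, immutable-ish wrapper around a symmetric
``scipy.sparse`` adjacency matrix plus an array of opaque node labels.  All
distance computations go through ``scipy.sparse.csgraph`` so that even
multi-million-node synthetic fixtures stay fast; :mod:`networkx` is used only
for interoperability (GraphML, edge betweenness).

Graphs are undirected and simple: self-loops are dropped, parallel edges
collapse keeping the minimum weight, and all weights are strictly positive
(interpreted as lengths).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "DistanceVector",
    "load_edgelist",
    "write_edgelist",
    "load_graphml",
    "largest_component",
    "distances_from",
    "distance_matrix",
    "network_radius",
    "average_degree",
    "average_degree_from_counts",
]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list input; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        self.lineno = lineno
        super().__init__(message if lineno is None else f"line {lineno}: {message}")


@dataclass(frozen=True)
class DistanceVector(Mapping):
    """Shortest-path distances from a single source node.

    Behaves as a mapping from reachable node label to distance (hop count for
    unweighted networks, sum of edge weights for weighted ones).  Unreachable
    nodes are absent.
    """

    source: str
    labels: tuple[str, ...]
    values: np.ndarray  # parallel to ``labels``; finite

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    def __getitem__(self, label: str) -> float:
        return float(self.values[self._index[label]])

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(self.labels, self.values)}

    @property
    def eccentricity(self) -> float:
        """Largest distance from the source to any reachable node."""
        return float(self.values.max())


class Network:
    """An undirected, simple graph with opaque string labels.

    Parameters
    ----------
    labels
        Node labels in index order.  Labels are opaque: integer-like labels
        are not renumbered.
    adjacency
        Symmetric ``N x N`` sparse matrix of positive edge lengths.
    weighted
        Whether edge weights carry meaning (``False`` means every edge has
        length 1).
    """

    def __init__(self, labels, adjacency: sp.csr_array, weighted: bool = False):
        labels = tuple(str(x) for x in labels)
        if len(labels) < 1:
            raise ValueError("a network needs at least one node")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels")
        adjacency = sp.csr_array(adjacency)
        if adjacency.shape != (len(labels), len(labels)):
            raise ValueError("adjacency shape does not match label count")
        self.labels = labels
        self.weighted = bool(weighted)
        self._adj = adjacency
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        weighted: bool = False,
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from ``(u, v)`` or ``(u, v, w)`` tuples.

        Self-loops are dropped with a warning; duplicate edges collapse,
        keeping the minimum weight.  ``extra_nodes`` adds isolated nodes.
        """
        best: dict[tuple[str, str], float] = {}
        order: dict[str, None] = {}
        n_loops = 0
        for e in edges:
            if weighted:
                u, v, w = str(e[0]), str(e[1]), float(e[2])
                if w <= 0:
                    raise ValueError(f"non-positive weight {w} on edge ({u}, {v})")
            else:
                u, v = str(e[0]), str(e[1])
                w = 1.0
            order.setdefault(u)
            order.setdefault(v)
            if u == v:
                n_loops += 1
                continue
            key = (u, v) if u < v else (v, u)
            prev = best.get(key)
            if prev is None or w < prev:
                best[key] = w
        if n_loops:
            logger.warning("dropped %d self-loop(s)", n_loops)
        for lab in extra_nodes:
            order.setdefault(str(lab))
        labels = list(order)
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        if best:
            ij = np.array([(index[u], index[v]) for u, v in best], dtype=np.int64)
            w = np.fromiter(best.values(), dtype=float, count=len(best))
            rows = np.concatenate([ij[:, 0], ij[:, 1]])
            cols = np.concatenate([ij[:, 1], ij[:, 0]])
            data = np.concatenate([w, w])
            adj = sp.csr_array((data, (rows, cols)), shape=(n, n))
        else:
            adj = sp.csr_array((n, n), dtype=float)
        return cls(labels, adj, weighted=weighted)

    @classmethod
    def from_arrays(
        cls,
        labels,
        src: np.ndarray,
        dst: np.ndarray,
        weights: np.ndarray | None = None,
        weighted: bool = False,
    ) -> "Network":
        """Fast constructor from parallel index arrays (one entry per edge).

        Assumes the edge set is already simple (no loops or duplicates);
        generators use this path to stay fast at millions of nodes.
        """
        labels = tuple(str(x) for x in labels)
        n = len(labels)
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        if weights is None:
            weights = np.ones(len(src), dtype=float)
        else:
            weights = np.asarray(weights, dtype=float)
            if np.any(weights <= 0):
                raise ValueError("all edge weights must be strictly positive")
        rows = np.concatenate([src, dst])
        cols = np.concatenate([dst, src])
        data = np.concatenate([weights, weights])
        adj = sp.csr_array((data, (rows, cols)), shape=(n, n))
        return cls(labels, adj, weighted=weighted)

    @classmethod
    def from_networkx(cls, g, weighted: bool = False) -> "Network":
        edges = (
            (u, v, d.get("weight", 1.0)) for u, v, d in g.edges(data=True)
        ) if weighted else g.edges()
        return cls.from_edges(edges, weighted=weighted, extra_nodes=g.nodes())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        coo = sp.triu(self._adj).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            if self.weighted:
                g.add_edge(self.labels[i], self.labels[j], weight=float(w))
            else:
                g.add_edge(self.labels[i], self.labels[j])
        return g

    # -- basic accessors --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return self._adj.nnz // 2

    @property
    def adjacency(self) -> sp.csr_array:
        return self._adj

    def index(self, label: str) -> int:
        try:
            return self._index[str(label)]
        except KeyError:
            raise KeyError(f"node {label!r} not in network") from None

    def __contains__(self, label) -> bool:
        return str(label) in self._index

    def degrees(self) -> np.ndarray:
        """Unweighted degree of every node, in label order."""
        return np.diff(self._adj.indptr)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate ``(u, v, w)`` with u-index < v-index."""
        coo = sp.triu(self._adj).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.labels[i], self.labels[j], float(w)

    def has_edge(self, u: str, v: str) -> bool:
        i, j = self.index(u), self.index(v)
        return bool(self._adj[[i], [j]] != 0)

    def subgraph(self, keep: np.ndarray) -> "Network":
        """Induced subgraph on the node indices ``keep`` (order preserved)."""
        keep = np.asarray(keep)
        sub = self._adj[keep][:, keep]
        labels = [self.labels[i] for i in keep]
        return Network(labels, sp.csr_array(sub), weighted=self.weighted)

    def drop_edges(self, pairs: Iterable[tuple[str, str]]) -> "Network":
        """Copy of the network with the given edges removed."""
        adj = self._adj.tolil()
        for u, v in pairs:
            i, j = self.index(u), self.index(v)
            adj[i, j] = 0.0
            adj[j, i] = 0.0
        return Network(self.labels, sp.csr_array(adj), weighted=self.weighted)

    def is_connected(self) -> bool:
        ncomp, _ = csgraph.connected_components(self._adj, directed=False)
        return ncomp == 1

    def __repr__(self) -> str:
        kind = "weighted" if self.weighted else "unweighted"
        return f"<Network {kind} N={self.n_nodes} E={self.n_edges}>"


# -- file I/O -------------------------------------------------------------


def load_edgelist(path, weighted: bool = False) -> Network:
    """Read a whitespace-delimited edge list.

    One edge per line: ``u v`` or, with ``weighted=True``, ``u v w``.  Lines
    starting with ``#`` and blank lines are ignored.  Malformed lines raise
    :class:`EdgeListParseError` carrying the line number.
    """
    edges = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if weighted:
                if len(toks) != 3:
                    raise EdgeListParseError(
                        f"expected 'u v w', got {line!r}", lineno
                    )
                try:
                    w = float(toks[2])
                except ValueError:
                    raise EdgeListParseError(
                        f"bad weight {toks[2]!r}", lineno
                    ) from None
                if w <= 0:
                    raise EdgeListParseError(
                        f"non-positive weight {w}", lineno
                    )
                edges.append((toks[0], toks[1], w))
            else:
                if len(toks) != 2:
                    raise EdgeListParseError(
                        f"expected 'u v', got {line!r}", lineno
                    )
                edges.append((toks[0], toks[1]))
    if not edges:
        raise EdgeListParseError(f"no edges found in {path}")
    return Network.from_edges(edges, weighted=weighted)


def write_edgelist(net: Network, path) -> None:
    """Write the network back out in the same edge-list format."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in net.edges():
            if net.weighted:
                fh.write(f"{u} {v} {w:.12g}\n")
            else:
                fh.write(f"{u} {v}\n")


def load_graphml(path, weighted: bool = False) -> Network:
    """Read a GraphML file (via networkx) for interoperability."""
    import networkx as nx

    g = nx.read_graphml(path)
    if g.is_directed():
        logger.warning("directed GraphML input symmetrized")
        g = g.to_undirected()
    return Network.from_networkx(g, weighted=weighted)


# -- operations -----------------------------------------------------------


def largest_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Size ties break toward the component containing the smallest node label.
    Logs a warning whenever nodes are dropped.
    """
    ncomp, comp = csgraph.connected_components(net.adjacency, directed=False)
    if ncomp == 1:
        return net
    sizes = np.bincount(comp, minlength=ncomp)
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) == 1:
        chosen = candidates[0]
    else:
        chosen = min(
            candidates,
            key=lambda c: min(
                net.labels[i] for i in np.flatnonzero(comp == c)
            ),
        )
    keep = np.flatnonzero(comp == chosen)
    dropped = net.n_nodes - len(keep)
    logger.warning(
        "kept largest component (%d nodes); dropped %d node(s)", len(keep), dropped
    )
    return net.subgraph(keep)


def _sp_distances(net: Network, indices=None) -> np.ndarray:
    """Shortest-path distances via csgraph (BFS for unweighted graphs)."""
    return csgraph.dijkstra(
        net.adjacency,
        directed=False,
        indices=indices,
        unweighted=not net.weighted,
    )


def distances_from(net: Network, source: str) -> DistanceVector:
    """Exact shortest-path distances from ``source`` to all reachable nodes."""
    i = net.index(source)
    dist = _sp_distances(net, indices=i)
    finite = np.isfinite(dist)
    labels = tuple(net.labels[j] for j in np.flatnonzero(finite))
    return DistanceVector(net.labels[i], labels, dist[finite])


def distance_matrix(net: Network) -> np.ndarray:
    """All-pairs shortest-path distance matrix (dense ``N x N``).

    Quadratic in memory; intended for the analysis-sized graphs every
    multifractal computation runs on, not for multi-million-node fixtures.
    """
    return _sp_distances(net)


def network_radius(net: Network, dist: np.ndarray | None = None) -> float:
    """Diameter: the maximum pairwise shortest-path distance.

    This is the largest radius any growing box needs, which is how the
    normalization scale ``d`` is used downstream.
    """
    if dist is None:
        dist = distance_matrix(net)
    if np.isinf(dist).any():
        raise ValueError(
            "network is disconnected; reduce with largest_component() first"
        )
    return float(dist.max())


def average_degree(net: Network) -> float:
    """Mean degree 2E/N."""
    return average_degree_from_counts(net.n_nodes, net.n_edges)


def average_degree_from_counts(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 1:
        raise ValueError("need at least one node")
    return 2.0 * n_edges / n_nodes
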