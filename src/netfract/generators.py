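"""Reference network constructors used for validation and synthetic tests.

Every generator is deterministic under a fixed seed and returns a
:class:`~netfract.graph.Network`.  The stochastic models (Erdős–Rényi,
Watts–Strogatz rewiring, Barabási–Albert preferential attachment) implement
the textbook mechanisms directly rather than delegating to networkx, so the
exact sampling scheme is pinned down and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Network

__all__ = [
    "GeneratorConfig",
    "ring_lattice",
    "erdos_renyi",
    "watts_strogatz",
    "barabasi_albert",
    "weighted_fractal",
    "uv_flower",
    "make_network",
]


@dataclass
class GeneratorConfig:
    """Bag of generator parameters; only the fields a model needs are read.

    ``n``: node count.  ``p``: edge/rewiring probability.  ``k``: neighbors
    per node in the ring lattice (even).  ``m``/``m0``: attachment count and
    seed-clique size for preferential attachment.  ``b``/``f``: branching
    copies and scaling factor of the weighted self-similar tree.  ``u``/``v``
    plus ``generations``: flower recursion parameters.
    """

    model: str = ""
    n: int = 0
    p: float = 0.0
    k: int = 0
    m: int = 0
    m0: int | None = None
    b: int = 0
    f: float = 0.0
    u: int = 0
    v: int = 0
    generations: int = 1
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.k and (self.k % 2 or self.k >= self.n):
            raise ValueError("k must be even and smaller than n")
        if self.m:
            m0 = self.m if self.m0 is None else self.m0
            if not self.m <= m0 < self.n:
                raise ValueError("need m <= m0 < n")
        if self.b and self.b < 2:
            raise ValueError("b must be >= 2")
        if self.b and not 0.0 < self.f < 1.0:
            raise ValueError("f must be in (0, 1)")
        if self.u or self.v:
            if self.u < 1 or self.v < 1 or self.u + self.v < 3:
                raise ValueError("need u, v >= 1 and u + v >= 3")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def ring_lattice(n: int, k: int) -> Network:
    """Ring of ``n`` nodes, each linked to its ``k`` nearest neighbors.

    Node ``i`` is joined to ``i ± 1, ..., i ± k/2`` (mod n), giving exactly
    ``n*k/2`` edges.
    """
    if k % 2:
        raise ValueError(f"k must be even, got {k}")
    if not 0 < k < n:
        raise ValueError("need 0 < k < n")
    i = np.arange(n)
    src, dst = [], []
    for off in range(1, k // 2 + 1):
        src.append(i)
        dst.append((i + off) % n)
    return Network.from_arrays(
        [str(x) for x in range(n)], np.concatenate(src), np.concatenate(dst)
    )


def erdos_renyi(n: int, p: float, seed: int | None = None) -> Network:
    """G(n, p): each of the n(n-1)/2 pairs is an edge with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    return Network.from_arrays(
        [str(x) for x in range(n)], iu[mask], ju[mask]
    )


def watts_strogatz(n: int, k: int, p: float, seed: int | None = None) -> Network:
    """Small-world rewiring of a ring lattice.

    Each lattice edge ``(u, v)`` is independently rewired with probability
    ``p`` to ``(u, w)`` with ``w`` drawn uniformly from the nodes that are
    neither ``u`` nor current neighbors of ``u``.  If no eligible target
    exists the edge is left in place, so node and edge counts never change.
    The output may be disconnected at intermediate ``p``; callers that need
    reachability should reduce to the largest component.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    base = ring_lattice(n, k)
    if p == 0.0:
        return base
    rng = np.random.default_rng(seed)
    adj: list[set[int]] = [set() for _ in range(n)]
    edge_list: list[tuple[int, int]] = []
    for off in range(1, k // 2 + 1):
        for u in range(n):
            v = (u + off) % n
            edge_list.append((u, v))
            adj[u].add(v)
            adj[v].add(u)
    for idx, (u, v) in enumerate(edge_list):
        if rng.random() >= p:
            continue
        forbidden = adj[u]
        # eligible targets: not u, not already adjacent to u
        n_eligible = n - 1 - len(forbidden)
        if n_eligible <= 0:
            continue
        while True:
            w = int(rng.integers(n))
            if w != u and w not in forbidden:
                break
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].add(w)
        adj[w].add(u)
        edge_list[idx] = (u, w)
    src = np.fromiter((e[0] for e in edge_list), dtype=np.int64)
    dst = np.fromiter((e[1] for e in edge_list), dtype=np.int64)
    return Network.from_arrays([str(x) for x in range(n)], src, dst)


def barabasi_albert(
    n: int, m: int, m0: int | None = None, seed: int | None = None
) -> Network:
    """Preferential attachment growth from a complete seed graph.

    Starts from the complete graph on ``m0`` nodes (default ``m0 = m``); each
    arriving node attaches to ``m`` distinct existing nodes, sampled without
    replacement with probability proportional to current degree.
    """
    if m0 is None:
        m0 = m
    if not 1 <= m <= m0 < n:
        raise ValueError("need 1 <= m <= m0 < n")
    rng = np.random.default_rng(seed)
    deg = np.zeros(n, dtype=np.int64)
    src, dst = [], []
    for i in range(m0):
        for j in range(i + 1, m0):
            src.append(i)
            dst.append(j)
    deg[:m0] = m0 - 1
    for new in range(m0, n):
        weights = deg[:new].astype(float)
        chosen: list[int] = []
        for _ in range(m):
            total = weights.sum()
            if total <= 0:  # pragma: no cover - seed graph guarantees degree
                break
            t = rng.random() * total
            target = int(np.searchsorted(np.cumsum(weights), t, side="right"))
            chosen.append(target)
            weights[target] = 0.0  # without replacement
        for t in chosen:
            src.append(new)
            dst.append(t)
            deg[t] += 1
        deg[new] = len(chosen)
    return Network.from_arrays(
        [str(x) for x in range(n)],
        np.array(src, dtype=np.int64),
        np.array(dst, dtype=np.int64),
    )


def weighted_fractal(b: int, f: float, generations: int) -> Network:
    """Self-similar weighted tree with branching ``b`` and scaling ``f``.

    The root sits at level 0; every node at level ``g-1`` has ``b`` children
    joined by edges of length ``(1/f)**g``.  The cumulative mass seen from
    the root then scales with radius as ``r**(ln b / ln(1/f))``, the closed
    form its mass-radius exponent is validated against.
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    if not 0.0 < f < 1.0:
        raise ValueError(f"f must be in (0, 1), got {f}")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    counts = [b**g for g in range(generations + 1)]
    n = int(sum(counts))
    child = np.arange(1, n, dtype=np.int64)
    parent = (child - 1) // b  # children of node i are b*i+1 .. b*i+b
    levels = np.repeat(np.arange(generations + 1), counts)
    w = (1.0 / f) ** levels[child].astype(float)
    return Network.from_arrays(
        [str(x) for x in range(n)], parent, child, weights=w, weighted=True
    )


def uv_flower(u: int, v: int, generations: int) -> Network:
    """(u, v)-flower: recursively replace each edge by parallel u- and v-paths.

    Generation 1 is a cycle of length ``u + v``; generation ``g`` has
    ``(u + v)**g`` edges and ``N_g = N_{g-1} + (u + v - 2) * E_{g-1}`` nodes.
    """
    if u < 1 or v < 1 or u + v < 3:
        raise ValueError("need u, v >= 1 and u + v >= 3")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    n = u + v
    edges = [(i, (i + 1) % n) for i in range(n)]
    for _ in range(1, generations):
        new_edges = []
        for a, bnode in edges:
            for path_len in (u, v):
                prev = a
                for _step in range(path_len - 1):
                    new_edges.append((prev, n))
                    prev = n
                    n += 1
                new_edges.append((prev, bnode))
        edges = new_edges
    src = np.fromiter((e[0] for e in edges), dtype=np.int64)
    dst = np.fromiter((e[1] for e in edges), dtype=np.int64)
    return Network.from_arrays([str(x) for x in range(n)], src, dst)


def join_at_hubs(a: Network, b: Network,
                 prefixes: tuple[str, str] = ("a:", "b:")) -> Network:
    """Disjoint union of two networks plus one edge between their hubs.

    The hub of each network is its highest-degree node (ties: first in label
    order).  Labels are prefixed to keep the two halves distinct.
    """
    pa, pb = prefixes
    edges = [(pa + u, pa + v) for u, v, _ in a.edges()]
    edges += [(pb + u, pb + v) for u, v, _ in b.edges()]
    hub_a = a.labels[int(np.argmax(a.degrees()))]
    hub_b = b.labels[int(np.argmax(b.degrees()))]
    edges.append((pa + hub_a, pb + hub_b))
    return Network.from_edges(edges)


_MODELS = {
    "ring": lambda c: ring_lattice(c.n, c.k),
    "er": lambda c: erdos_renyi(c.n, c.p, c.seed),
    "ws": lambda c: watts_strogatz(c.n, c.k, c.p, c.seed),
    "ba": lambda c: barabasi_albert(c.n, c.m, c.m0, c.seed),
    "fractal": lambda c: weighted_fractal(c.b, c.f, c.generations),
    "flower": lambda c: uv_flower(c.u, c.v, c.generations),
}


def make_network(config: GeneratorConfig) -> Network:
    """Dispatch on ``config.model`` (ring, er, ws, ba, fractal, flower)."""
    config.validate()
    try:
        builder = _MODELS[config.model]
    except KeyError:
        raise ValueError(
            f"unknown model {config.model!r}; choose from {sorted(_MODELS)}"
        ) from None
    return builder(config)
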