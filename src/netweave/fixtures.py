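"""Seeded synthetic graph generators and canonical tiny fixtures.

Two random families cover the qualitative extremes a fabric layout makes
visible: Erdős–Rényi G(n, m) graphs (no degree structure; featureless edge
patterns and, at low mean degree, a lower boundary approaching the
45-degree limit) and Barabási–Albert preferential-attachment graphs (heavy
degree tail; a sawtooth of shrinking edge wedges down the rows).  Both are
deterministic per seed and emit valid :class:`~netweave.model.Network`
objects with zero-padded node names (so lexicographic tie-breaks coincide
with numeric order) and the fixed relation label ``ee``.

The canonical fixtures are the hand-checkable worked examples shared by
the test-suites of every layout module.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .model import Link, Network, ValidationError

__all__ = ["er_gnm", "ba_graph", "canonical", "CANONICAL_NAMES"]

RELATION = "ee"


def _name(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def er_gnm(n: int, m: int, seed: int) -> Network:
    """Uniform simple graph with exactly ``n`` nodes and ``m`` edges."""
    if not 0 <= m <= n * (n - 1) // 2:
        raise ValidationError(f"edge count {m} out of range for n={n}")
    g = nx.gnm_random_graph(n, m, seed=seed)
    width = len(str(n - 1)) if n > 1 else 1
    net = Network()
    for i in range(n):
        net.add_node(_name(i, width))
    for u, v in g.edges():
        net.add_link(Link(_name(u, width), _name(v, width), RELATION))
    return net


def ba_graph(n: int, m_per_step: int, seed: int) -> Network:
    """Preferential-attachment simple graph.

    Vertex 1 starts alone; vertex i (i >= 2) attaches min(m_per_step, i-1)
    edges to distinct earlier vertices drawn with probability proportional
    to (current degree + 1) — the +1 keeps isolated early vertices
    reachable.  Total edges = sum_i min(m_per_step, i-1), independent of
    the sampling kernel.
    """
    if not (n > m_per_step >= 1):
        raise ValidationError("require n > m_per_step >= 1")
    rng = np.random.default_rng(seed)
    degrees = np.zeros(n, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    for i in range(1, n):
        k = min(m_per_step, i)
        weights = (degrees[:i] + 1).astype(np.float64)
        targets = rng.choice(i, size=k, replace=False,
                             p=weights / weights.sum())
        for t in targets:
            edges.append((int(t), i))
            degrees[t] += 1
            degrees[i] += 1
    width = len(str(n - 1)) if n > 1 else 1
    net = Network()
    for i in range(n):
        net.add_node(_name(i, width))
    for u, v in edges:
        net.add_link(Link(_name(u, width), _name(v, width), RELATION))
    return net


def _net(pairs, relation=RELATION, lone=()):
    return Network.from_links(
        [Link(a, b, rel) for a, b, rel in
         ((p[0], p[1], p[2] if len(p) > 2 else relation) for p in pairs)],
        lone_nodes=lone,
    )


_CANONICAL = {
    "single_edge": lambda: _net([("A", "B", "pp")]),
    "path3": lambda: _net([("A", "B", "pp"), ("B", "C", "pp")]),
    "star4": lambda: _net([("H", "a", "pp"), ("H", "b", "pp"),
                           ("H", "c", "pp")]),
    "triangle": lambda: _net([("A", "B", "pp"), ("A", "C", "pp"),
                              ("B", "C", "pp")]),
    "triangle_pendant": lambda: _net([("A", "B", "pp"), ("A", "C", "pp"),
                                      ("B", "C", "pp"), ("A", "D", "pp")]),
    "two_components": lambda: _net([("D", "E", "pp"), ("D", "F", "pp"),
                                    ("E", "F", "pp"), ("A", "B", "pp")]),
    "multi_relation_pair": lambda: _net([("A", "B", "x-t1"),
                                         ("A", "B", "y-t2")]),
}

CANONICAL_NAMES = tuple(sorted(_CANONICAL))


def canonical(name: str) -> Network:
    """A fixed tiny fixture by name (see :data:`CANONICAL_NAMES`)."""
    try:
        factory = _CANONICAL[name]
    except KeyError:
        raise ValidationError(
            f"unknown fixture {name!r}; choose from {CANONICAL_NAMES}"
        ) from None
    return factory()
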