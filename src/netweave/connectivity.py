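"""Similarity-driven node ordering with sticky-chain placement.

The goal is long runs of adjacent rows whose nodes have near-identical
connectivity (matching edge wedges).  Every linked node pair gets a
similarity coefficient computed once, up front, from the static network,
with direction and duplicate relations collapsed:

* cosine — dot product of the two 0/1 connectivity n-vectors over the
  product of their Euclidean norms, i.e. |N_j ∩ N_m| / sqrt(|N_j| |N_m|);
* Jaccard — |N_j ∩ N_m| / |N_j ∪ N_m|,

where N_v is the distinct-neighbor set of v (v itself only if self-looped).
Both are symmetric and lie in [0, 1].

Placement grows the placed list P one node at a time from the front F (the
unplaced nodes adjacent to P).  A plain greedy rule — take the front node
with the best coefficient on an edge into P — abandons a rich region as
soon as a marginally better coefficient appears anywhere on the front.  To
make the walk sticky, an ordered chain of the r most recently used placed
nodes is kept: if the best front edge overall has coefficient S_b (from
placed node A) but some chain node C has an edge to the front with
coefficient S_d > S_b * t, the chain candidate wins.  A chain win moves C
to the head and inserts the new node behind it; a global win empties the
chain and restarts it as [A, new node]; the chain is then trimmed to r.
With t = 1 chain wins are impossible and the layout degenerates to pure
greedy placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import Network, NodeOrder, ValidationError

__all__ = ["SimilarityParams", "similarity_coefficients",
           "assign_rows_connectivity"]

#: Chain defaults: long enough for stickiness to show on clustered networks,
#: threshold high enough that clearly better front edges still win.
DEFAULT_CHAIN_SIZE = 20
DEFAULT_THRESHOLD = 0.9


@dataclass(frozen=True)
class SimilarityParams:
    """Similarity measure plus the sticky-chain knobs r (size) and t
    (threshold fraction in [0, 1])."""

    measure: str = "jaccard"
    chain_size: int = DEFAULT_CHAIN_SIZE
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.measure not in ("cosine", "jaccard"):
            raise ValidationError(f"unknown similarity measure {self.measure!r}")
        if self.chain_size < 1:
            raise ValidationError("chain size r must be >= 1")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError("threshold t must lie in [0, 1]")


def similarity_coefficients(network: Network,
                            measure: str = "jaccard"
                            ) -> dict[frozenset, float]:
    """One coefficient per distinct linked (unordered) endpoint pair.

    Self-loops produce no pair entry; duplicate relations collapse to a
    single shared coefficient.
    """
    if measure not in ("cosine", "jaccard"):
        raise ValidationError(f"unknown similarity measure {measure!r}")
    adj = network.adjacency()
    coeffs: dict[frozenset, float] = {}
    for link in network.links:
        if link.is_self_loop:
            continue
        pair = frozenset((link.source, link.target))
        if pair in coeffs:
            continue
        na, nb = adj[link.source], adj[link.target]
        shared = len(na & nb)
        if measure == "cosine":
            denom = math.sqrt(len(na) * len(nb))
        else:
            denom = len(na | nb)
        coeffs[pair] = shared / denom if denom else 0.0
    return coeffs


def assign_rows_connectivity(network: Network,
                             params: SimilarityParams | None = None,
                             _trace: dict | None = None) -> NodeOrder:
    """Sticky-chain placement; returns a bijection node -> row 1..n.

    Seeds (initially and on every exhausted component) are the
    highest-degree unplaced node, ties lexicographic.  ``_trace``, if given,
    collects diagnostics (currently ``max_chain_len``).
    """
    params = params or SimilarityParams()
    adj = network.adjacency()
    deg = {v: len(nbrs) for v, nbrs in adj.items()}
    coeffs = similarity_coefficients(network, params.measure)

    def coeff(u: str, v: str) -> float:
        return coeffs.get(frozenset((u, v)), 0.0)

    placed: list[str] = []
    placed_set: set[str] = set()
    unplaced = set(network.nodes)
    # front bookkeeping: for each front node, its placed neighbors
    front: dict[str, set[str]] = {}
    chain: list[str] = []
    max_chain = 0

    def place(node: str) -> None:
        placed.append(node)
        placed_set.add(node)
        unplaced.remove(node)
        front.pop(node, None)
        for nbr in adj[node]:
            if nbr in unplaced:
                front.setdefault(nbr, set()).add(node)

    def best_front_edge() -> tuple[float, str, str]:
        """(S_b, front node, placed node A); ties -> smallest front name,
        then smallest placed name."""
        best = (-1.0, "", "")
        for f in front:
            for p in front[f]:
                s = coeff(p, f)
                cand = (s, f, p)
                if (s > best[0]
                        or (s == best[0] and (f, p) < (best[1], best[2]))):
                    best = cand
        return best

    def best_chain_edge() -> tuple[float, str, str] | None:
        """(S_d, front node, chain node C); ties -> most recently used C
        (earliest chain slot), then smallest front name."""
        best: tuple[float, str, str] | None = None
        for c in chain:  # slot 1 first: earlier slots win ties by order
            c_best: tuple[float, str] | None = None
            for f, plc in front.items():
                if c in plc:
                    s = coeff(c, f)
                    if (c_best is None or s > c_best[0]
                            or (s == c_best[0] and f < c_best[1])):
                        c_best = (s, f)
            if c_best is not None and (best is None or c_best[0] > best[0]):
                best = (c_best[0], c_best[1], c)
        return best

    while unplaced:
        if not front:
            # new component (or lone nodes): empty the chain and re-seed
            chain.clear()
            seed = min(unplaced, key=lambda v: (-deg[v], v))
            place(seed)
            continue
        s_b, f_node, a_node = best_front_edge()
        chain_best = best_chain_edge()
        if chain_best is not None and chain_best[0] > s_b * params.threshold:
            s_d, new_node, used = chain_best
            chain.remove(used)
        else:
            new_node, used = f_node, a_node
            chain.clear()
        chain.insert(0, used)
        chain.insert(1, new_node)
        del chain[params.chain_size:]
        max_chain = max(max_chain, len(chain))
        place(new_node)

    if _trace is not None:
        _trace["max_chain_len"] = max_chain
    return NodeOrder({name: row for row, name in enumerate(placed, start=1)})
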