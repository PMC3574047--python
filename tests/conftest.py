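"""Shared fixtures and random-network helpers for the test suite."""

from __future__ import annotations

import itertools
import random

import pytest

from netweave.model import Link, Network


def random_network(n: int, m: int, seed: int, *, directed_frac: float = 0.0,
                   multi_rel: bool = False, lone: int = 0) -> Network:
    """Seeded random simple graph as a Network, optionally with directed
    relations, duplicate-endpoint relations and lone nodes."""
    rng = random.Random(seed)
    names = [f"v{i:03d}" for i in range(n)]
    pairs = list(itertools.combinations(range(n), 2))
    rng.shuffle(pairs)
    net = Network()
    relations = ["aa", "bb", "cc"]
    for u, v in pairs[:m]:
        rel = rng.choice(relations) if multi_rel else "aa"
        directed = rng.random() < directed_frac
        net.add_link(Link(names[u], names[v], rel, directed=directed))
    for name in names:  # keep all n nodes even if unused by sampled pairs
        net.add_node(name)
    for i in range(lone):
        net.add_node(f"lone{i:02d}")
    return net


def build_sticky_network() -> tuple[Network, set[str]]:
    """Engineered chain-vs-decoy graph for stickiness tests.

    A 10-node chain whose consecutive pairs share dedicated leaf gadgets
    (entry pairs share more, so the walk enters the chain first), plus
    decoy nodes hanging off the chain head with intermediate similarity:
    above the mid-chain coefficients, below the entry ones.  Pure greedy
    defects to the decoys after three chain nodes; a sticky walk (small t)
    finishes the chain first.
    """
    links: list[Link] = []
    counter = itertools.count()

    def leaf() -> str:
        return f"z{next(counter):03d}"

    def add(a: str, b: str) -> None:
        links.append(Link(a, b, "ee"))

    chain = [f"c{i:02d}" for i in range(10)]
    shared_counts = [20, 16] + [6] * 7
    for i in range(9):
        add(chain[i], chain[i + 1])
        for _ in range(shared_counts[i]):
            z = leaf()
            add(chain[i], z)
            add(chain[i + 1], z)
    shared = [leaf() for _ in range(12)]
    for z in shared:
        add(chain[0], z)
    for j in range(3):
        d = f"d{j}"
        add(chain[0], d)
        for z in shared:
            add(d, z)
    return Network.from_links(links), set(chain)


def first_chain_run(order_nodes: list[str], members: set[str]) -> int:
    """Length of the first maximal consecutive block of ``members``."""
    run = 0
    started = False
    for v in order_nodes:
        if v in members:
            run += 1
            started = True
        elif started:
            break
    return run


@pytest.fixture
def sticky_network():
    return build_sticky_network()
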