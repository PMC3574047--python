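"""First-neighbor selections and compressed subset layouts.

A selection is built from seed nodes: it contains the seeds, all their
neighbors, and every link copy incident on at least one seed (both copies
when shadows are active).  Neighbor-neighbor links that touch no seed are
excluded.  Compression then squeezes out unused rows and columns while
preserving the relative order of everything retained — the subset view is
an order-isomorphic window onto the full layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .columns import ColumnAssignment
from .model import Link, Network, NodeOrder, ValidationError

__all__ = ["Selection", "first_neighbors", "compress"]


@dataclass(frozen=True)
class Selection:
    """Seed nodes plus the induced first-neighbor node and link-copy sets."""

    seeds: frozenset[str]
    nodes: frozenset[str]
    links: frozenset[Link]

    def __post_init__(self) -> None:
        for link in self.links:
            if link.source not in self.nodes or link.target not in self.nodes:
                raise ValidationError(
                    f"selected link {link} has an endpoint outside the selection"
                )

    def subnetwork(self) -> Network:
        """The selection as a standalone Network (for re-rendering)."""
        net = Network()
        for link in self.links:
            net.add_link(link)
        for node in self.nodes:
            net.add_node(node)
        return net


def first_neighbors(network: Network, seeds) -> Selection:
    """Seeds plus neighbors, plus every link copy incident on >= 1 seed."""
    seeds = frozenset(seeds)
    unknown = [s for s in seeds if s not in network]
    if unknown:
        raise ValidationError(f"unknown seed nodes: {sorted(unknown)}")
    nodes = set(seeds)
    links: set[Link] = set()
    for link in network.links:
        if link.source in seeds or link.target in seeds:
            links.add(link)
            nodes.add(link.source)
            nodes.add(link.target)
    return Selection(seeds, frozenset(nodes), frozenset(links))


def compress(order: NodeOrder, columns: ColumnAssignment, selection: Selection,
             drop_duplicate_copies: bool = False
             ) -> tuple[NodeOrder, ColumnAssignment]:
    """Renumber the selection onto rows 1..k / columns 1..m, preserving
    relative order.

    With ``drop_duplicate_copies`` (shadow layouts only) each link keeps a
    single copy: the one residing in a seed node's zone — for a seed's
    downward links that is the real copy, for its upward links the shadow
    copy; a seed-seed link keeps the real one.
    """
    for node in selection.nodes:
        if node not in order.row_of:
            raise ValidationError(f"selected node {node!r} missing from layout")
    for link in selection.links:
        if link not in columns.column_of:
            raise ValidationError(f"selected link {link} missing from layout")

    kept = set(selection.links)
    if drop_duplicate_copies and any(link.shadow for link in kept):
        by_pair: dict[tuple, list[Link]] = {}
        for link in kept:
            ident = (link.source, link.target, link.base_relation, link.directed)
            by_pair.setdefault(ident, []).append(link)
        kept = set()
        for copies in by_pair.values():
            in_seed = [l for l in copies
                       if columns.owner_of[l] in selection.seeds]
            pool = in_seed or copies
            # prefer the real copy when both land in seed zones
            kept.add(min(pool, key=lambda l: l.shadow))

    sub_nodes = sorted(selection.nodes, key=lambda v: order[v])
    new_rows = {v: i for i, v in enumerate(sub_nodes, start=1)}
    sub_links = sorted(kept, key=lambda l: columns.column_of[l])
    new_cols = {l: i for i, l in enumerate(sub_links, start=1)}

    sub_net = selection.subnetwork()
    # owners are inherited from the full layout, never recomputed
    owner_of = {l: columns.owner_of[l] for l in sub_links}
    from .columns import _extents, _zones  # shared derivations

    new_order = NodeOrder(new_rows)
    return new_order, ColumnAssignment(
        new_cols, owner_of,
        _zones(sub_net, owner_of, new_cols),
        _extents(sub_net, new_cols),
    )
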