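"""Edge-column assignment: one unique column per drawable link copy.

Given a node-row order, columns are handed out by scanning rows top to
bottom and filling each node's *zone* — the contiguous block of columns it
owns.  Zone membership depends on the mode:

* standard: a node owns the links whose upper (smaller-row) endpoint it is;
  every link appears once, width E = e.
* shadow: every link is duplicated (relation prefixed ``shdw``) so each
  endpoint owns one copy — the real copy sits in the upper endpoint's zone,
  the shadow copy in the lower endpoint's zone.  Width doubles (E = 2e) and
  each zone holds the node's complete incidence inventory.

Within a zone, copies are bucketed by the distal (far-endpoint) row, buckets
taken in increasing row so links are laid shortest first; within a bucket
the relation label orders copies lexicographically, a real copy precedes its
shadow, and for a directed pair with an identical relation the downward link
precedes the upward one.  Self-loops take the first bucket of their zone.
With link groups active, the zone is first partitioned by the group of each
copy's base relation, groups in the user-given order, and the above ordering
applies within each group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import Link, Network, NodeOrder, ValidationError

__all__ = ["ColumnAssignment", "LinkGroupSpec", "expand_shadows", "assign_columns"]


@dataclass(frozen=True)
class LinkGroupSpec:
    """Ordered suffix tags partitioning base relations into link groups."""

    tags: tuple[str, ...]

    def __init__(self, tags: Iterable[str]):
        tags = tuple(tags)
        if not tags:
            raise ValidationError("link group spec needs at least one tag")
        if any(not t for t in tags):
            raise ValidationError("link group tags must be non-empty")
        if len(set(tags)) != len(tags):
            raise ValidationError("link group tags must be pairwise distinct")
        object.__setattr__(self, "tags", tags)

    def group_index(self, base_relation: str) -> int:
        """Index of the unique tag the relation ends with."""
        matches = [i for i, tag in enumerate(self.tags)
                   if base_relation.endswith(tag)]
        if len(matches) != 1:
            raise ValidationError(
                f"relation {base_relation!r} matches {len(matches)} group tags; "
                "expected exactly 1"
            )
        return matches[0]

    def validate(self, network: Network) -> None:
        """Every base relation must end with exactly one listed tag."""
        offenders = sorted(
            {link.base_relation for link in network.links
             if sum(link.base_relation.endswith(t) for t in self.tags) != 1}
        )
        if offenders:
            raise ValidationError(
                f"relations not matched by exactly one group tag: {offenders}"
            )


@dataclass
class ColumnAssignment:
    """Bijection link copy -> column 1..E plus per-node zones and extents.

    ``zone_of`` maps each node to the half-open-free inclusive column
    interval ``(lo, hi)`` of the copies it owns (``None`` when it owns
    nothing); ``extent_of`` maps each node to the inclusive interval spanned
    by all columns incident on it (``None`` for lone nodes); ``owner_of``
    records which node's zone each copy landed in.
    """

    column_of: dict[Link, int]
    owner_of: dict[Link, str]
    zone_of: dict[str, tuple[int, int] | None]
    extent_of: dict[str, tuple[int, int] | None]

    @property
    def width(self) -> int:
        return len(self.column_of)

    def __getitem__(self, link: Link) -> int:
        return self.column_of[link]

    def by_column(self) -> list[Link]:
        """Link copies listed column 1 first."""
        return [l for l, _ in sorted(self.column_of.items(), key=lambda kv: kv[1])]

    @staticmethod
    def zone_owner(link: Link, order: NodeOrder) -> str:
        """Node whose zone holds this copy: upper endpoint for real copies,
        lower endpoint for shadow copies."""
        src_row, tgt_row = order[link.source], order[link.target]
        upper = link.source if src_row <= tgt_row else link.target
        lower = link.target if src_row <= tgt_row else link.source
        return lower if link.shadow else upper

    @classmethod
    def from_columns(cls, network: Network, order: NodeOrder,
                     column_of: Mapping[Link, int]) -> "ColumnAssignment":
        """Derive zones/extents from an externally supplied column map."""
        owner_of = {link: cls.zone_owner(link, order) for link in column_of}
        return cls(dict(column_of), owner_of,
                   _zones(network, owner_of, column_of),
                   _extents(network, column_of))


def _zones(network: Network, owner_of: Mapping[Link, str],
           column_of: Mapping[Link, int]) -> dict[str, tuple[int, int] | None]:
    zones: dict[str, tuple[int, int] | None] = {v: None for v in network.nodes}
    for link, col in column_of.items():
        owner = owner_of[link]
        cur = zones[owner]
        zones[owner] = (col, col) if cur is None else (min(cur[0], col),
                                                       max(cur[1], col))
    return zones


def _extents(network: Network,
             column_of: Mapping[Link, int]) -> dict[str, tuple[int, int] | None]:
    extents: dict[str, tuple[int, int] | None] = {v: None for v in network.nodes}
    for link, col in column_of.items():
        for node in (link.source, link.target):
            cur = extents[node]
            extents[node] = (col, col) if cur is None else (min(cur[0], col),
                                                            max(cur[1], col))
    return extents


def expand_shadows(network: Network) -> Network:
    """Duplicate every link with a ``shdw``-prefixed shadow twin (2e links)."""
    if network.has_shadows():
        raise ValidationError("network already contains shadow links")
    out = Network()
    for node in network.nodes:
        out.add_node(node)
    for link in network.links:
        out.add_link(link)
        out.add_link(link.shadow_copy())
    return out


def assign_columns(network: Network, order: NodeOrder,
                   mode: str = "standard",
                   groups: LinkGroupSpec | None = None) -> ColumnAssignment:
    """Assign every link copy a unique column by scanning rows top to bottom.

    ``mode`` is ``"standard"`` (network must carry no shadow copies) or
    ``"shadow"`` (network must already be expanded, see
    :func:`expand_shadows`).  Raises on a group spec that does not partition
    the base relations.
    """
    if mode not in ("standard", "shadow"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "standard" and network.has_shadows():
        raise ValidationError("standard mode on a shadow-expanded network")
    if mode == "shadow" and network.e > 0 and not network.has_shadows():
        raise ValidationError("shadow mode requires an expanded network")
    if groups is not None:
        groups.validate(network)

    # Gather each zone's copies with their full sort key, then emit zones in
    # row order.  Sort key per copy within a zone:
    #   (group, bucket, base relation, real-before-shadow, downward-first)
    # bucket = distal row; self-loops are forced into the first bucket.
    zone_members: dict[str, list[tuple]] = {v: [] for v in network.nodes}
    for link in network.links:
        owner = ColumnAssignment.zone_owner(link, order)
        src_row, tgt_row = order[link.source], order[link.target]
        if link.is_self_loop:
            bucket = 0
        else:
            bucket = tgt_row if order[owner] == src_row else src_row
        gidx = groups.group_index(link.base_relation) if groups else 0
        upward = 1 if link.directed and src_row > tgt_row else 0
        zone_members[owner].append(
            (gidx, bucket, link.base_relation, 1 if link.shadow else 0,
             upward, link)
        )

    column_of: dict[Link, int] = {}
    owner_of: dict[Link, str] = {}
    next_col = 1
    for node in order.by_row():
        for key in sorted(zone_members[node], key=lambda k: k[:5]):
            link = key[5]
            column_of[link] = next_col
            owner_of[link] = node
            next_col += 1

    return ColumnAssignment(column_of, owner_of,
                            _zones(network, owner_of, column_of),
                            _extents(network, column_of))
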