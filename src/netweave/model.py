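"""Core network data model and text-format I/O.

The in-memory model is deliberately small: a :class:`Network` is an ordered
set of node names plus a deduplicated sequence of :class:`Link` records.  A
layout is a pair of bijections — node name -> row (1..n) and link copy ->
column (1..E) — persisted as plain-text order files so that externally
computed orderings (e.g. cluster assignments) can drive a layout.

Supported text formats:

* SIF (Cytoscape simple interaction format): ``source<TAB>relation<TAB>target
  [target ...]`` per line, with a whitespace fallback for files that were
  never tabbed.  A single-token line declares a lone (degree-0) node.
* Node attribute files: a header line naming the attribute, then
  ``name = value`` records.
* Node-order / link-order files: ``Row`` / ``Column`` headers followed by
  ``name = row`` and ``source (relation) target = column`` records.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

__all__ = [
    "Link",
    "Network",
    "NodeOrder",
    "ParseError",
    "ValidationError",
    "SHADOW_PREFIX",
    "parse_sif",
    "parse_node_attributes",
    "degree",
    "write_sif",
    "write_order_files",
    "read_order_files",
    "link_key",
]

SHADOW_PREFIX = "shdw"


class ParseError(ValueError):
    """Malformed input text (carries file line numbers where possible)."""


class ValidationError(ValueError):
    """Structurally invalid model data (broken bijection, unknown node...)."""


@dataclass(frozen=True)
class Link:
    """One drawable link copy.

    ``relation`` is the label as displayed; for a shadow copy it carries the
    ``shdw`` prefix and ``base_relation`` strips it.  A shadow copy and its
    real counterpart agree on source, target and base relation.
    """

    source: str
    target: str
    relation: str
    directed: bool = False
    shadow: bool = False

    def __post_init__(self) -> None:
        if not self.relation:
            raise ValidationError("link relation must be non-empty")
        if self.shadow and not self.relation.startswith(SHADOW_PREFIX):
            raise ValidationError(
                f"shadow link relation must start with {SHADOW_PREFIX!r}: "
                f"{self.relation!r}"
            )

    @property
    def base_relation(self) -> str:
        """Relation label with any shadow prefix removed."""
        if self.shadow:
            return self.relation[len(SHADOW_PREFIX):]
        return self.relation

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target

    def shadow_copy(self) -> "Link":
        """The shadow twin of a real link."""
        if self.shadow:
            raise ValidationError("link is already a shadow copy")
        return replace(self, relation=SHADOW_PREFIX + self.relation, shadow=True)

    def dedup_key(self) -> tuple[str, str, str]:
        """Canonical (source, target, relation) identity for deduplication.

        Undirected links are canonicalized with the lexicographically smaller
        endpoint first, so (A,B,rel) and (B,A,rel) collide; directed links
        keep their orientation.
        """
        s, t = self.source, self.target
        if not self.directed and t < s:
            s, t = t, s
        return (s, t, self.relation)


def link_key(link: Link) -> str:
    """Canonical string key used in link-order files."""
    return f"{link.source} ({link.relation}) {link.target}"


@dataclass
class Network:
    """Deduplicated node set plus link list.

    Nodes keep first-appearance order.  No two links share the canonical
    (source, target, relation) identity; lone nodes are permitted.
    """

    _nodes: dict[str, None] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)
    _seen: set[tuple[str, str, str]] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def e(self) -> int:
        return len(self.links)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def add_node(self, name: str) -> None:
        self._nodes.setdefault(name, None)

    def add_link(self, link: Link) -> bool:
        """Add a link, registering endpoints; returns False on duplicate."""
        self.add_node(link.source)
        self.add_node(link.target)
        key = link.dedup_key()
        if key in self._seen:
            return False
        self._seen.add(key)
        self.links.append(link)
        return True

    @classmethod
    def from_links(cls, links: Iterable[Link], lone_nodes: Iterable[str] = ()) -> "Network":
        net = cls()
        for link in links:
            net.add_link(link)
        for node in lone_nodes:
            net.add_node(node)
        return net

    # --- derived views -------------------------------------------------

    def neighbors(self, node: str) -> set[str]:
        """Distinct neighbors of ``node`` (direction and relation collapsed).

        A self-looped node is its own neighbor.
        """
        if node not in self._nodes:
            raise ValidationError(f"unknown node: {node!r}")
        out: set[str] = set()
        for link in self.links:
            if link.source == node:
                out.add(link.target)
            elif link.target == node:
                out.add(link.source)
        return out

    def adjacency(self) -> dict[str, set[str]]:
        """Distinct-neighbor sets for every node (self-loops included)."""
        adj: dict[str, set[str]] = {name: set() for name in self._nodes}
        for link in self.links:
            adj[link.source].add(link.target)
            adj[link.target].add(link.source)
        return adj

    def has_shadows(self) -> bool:
        return any(link.shadow for link in self.links)


def degree(network: Network, node: str) -> int:
    """Distinct-neighbor count; duplicate relations between the same pair
    count once, direction is ignored, a self-loop contributes 1."""
    return len(network.neighbors(node))


@dataclass(frozen=True)
class NodeOrder:
    """Bijection node name -> row 1..n."""

    row_of: Mapping[str, int]

    def __post_init__(self) -> None:
        rows = sorted(self.row_of.values())
        if rows != list(range(1, len(self.row_of) + 1)):
            raise ValidationError("node rows must form a bijection onto 1..n")

    def __getitem__(self, node: str) -> int:
        return self.row_of[node]

    def __len__(self) -> int:
        return len(self.row_of)

    def node_at(self, row: int) -> str:
        return self.by_row()[row - 1]

    def by_row(self) -> list[str]:
        """Node names listed row 1 first."""
        return [name for name, _ in sorted(self.row_of.items(), key=lambda kv: kv[1])]


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def _split_fields(line: str) -> list[str]:
    # Tab-delimited per the format; whitespace fallback for untabbed files.
    if "\t" in line:
        fields = [f.strip() for f in line.split("\t")]
        while fields and fields[-1] == "":
            fields.pop()
        return fields
    return line.split()


def parse_sif(stream: TextIO | str, directed_relations: Iterable[str] = ()) -> Network:
    """Parse a SIF edge list into a :class:`Network`.

    Multi-target lines ``A rel B C`` expand pairwise to A-B, A-C.  Exact
    duplicates (canonical identity, see :meth:`Link.dedup_key`) are dropped,
    first occurrence wins.  Relations listed in ``directed_relations`` import
    as directed; everything else is undirected.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    directed = set(directed_relations)
    net = Network()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = _split_fields(line)
        if not fields:
            continue
        if len(fields) == 1:
            net.add_node(fields[0])
            continue
        if len(fields) == 2:
            raise ParseError(
                f"line {lineno}: SIF record has 2 fields; expected 1 "
                "(lone node) or >= 3 (source relation target...)"
            )
        source, relation, *targets = fields
        if not relation:
            raise ParseError(f"line {lineno}: empty relation field")
        if not source or any(t == "" for t in targets):
            raise ParseError(f"line {lineno}: empty node name field")
        for target in targets:
            net.add_link(
                Link(source, target, relation, directed=relation in directed)
            )
    return net


def write_sif(network: Network, stream: TextIO | None = None) -> str:
    """Serialize to canonical SIF: one link per line, lone nodes last.

    Parsing the output reproduces the network exactly (idempotence).
    """
    out = stream or io.StringIO()
    linked: set[str] = set()
    for link in network.links:
        out.write(f"{link.source}\t{link.relation}\t{link.target}\n")
        linked.add(link.source)
        linked.add(link.target)
    for node in network.nodes:
        if node not in linked:
            out.write(f"{node}\n")
    return out.getvalue() if stream is None else ""


# ---------------------------------------------------------------------------
# Node attribute files
# ---------------------------------------------------------------------------

def parse_node_attributes(stream: TextIO | str) -> dict[str, str]:
    """Parse a node-attribute file: header line, then ``name = value`` rows.

    Rows with an empty name column are skipped with a warning (dirty exports
    routinely contain them); a body line without ``=`` is a parse error.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()
    attrs: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected 'name = value'")
        name, _, value = line.partition("=")
        name = name.strip()
        value = value.strip()
        if not name:
            warnings.warn(
                f"line {lineno}: skipping row with missing name column",
                stacklevel=2,
            )
            continue
        attrs[name] = value
    return attrs


# ---------------------------------------------------------------------------
# Order files
# ---------------------------------------------------------------------------

def write_order_files(order: NodeOrder, columns) -> tuple[str, str]:
    """Serialize a layout as (node-order text, link-order text).

    Node file: header ``Row`` then ``name = row``; link file: header
    ``Column`` then ``source (relation) target = column`` with shadow copies
    keyed by their ``shdw``-prefixed relation.  Rows and columns are 1-based;
    records are emitted in row/column order; newline is LF.
    """
    node_lines = ["Row"]
    for row, name in enumerate(order.by_row(), start=1):
        node_lines.append(f"{name} = {row}")
    link_lines = ["Column"]
    for link, col in sorted(columns.column_of.items(), key=lambda kv: kv[1]):
        link_lines.append(f"{link_key(link)} = {col}")
    return "\n".join(node_lines) + "\n", "\n".join(link_lines) + "\n"


def _parse_assignments(text: str, what: str) -> list[tuple[str, int]]:
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"empty {what}-order file")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        name, sep, value = line.rpartition("=")
        if not sep:
            raise ParseError(f"line {lineno}: expected '<key> = <{what}>'")
        try:
            idx = int(value.strip())
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer {what} {value!r}") from exc
        out.append((name.strip(), idx))
    return out


def read_order_files(node_stream: TextIO | str, link_stream: TextIO | str,
                     network: Network):
    """Read a persisted layout back against ``network``.

    Enforces bijectivity and completeness: every node gets exactly one row in
    1..n, every link copy exactly one column in 1..E.  Link keys use the
    displayed (possibly ``shdw``-prefixed) relation; if any shadow keys are
    present the link file must cover both copies of every link.
    """
    from .columns import ColumnAssignment  # local import: avoid cycle

    if isinstance(node_stream, str):
        node_text = node_stream
    else:
        node_text = node_stream.read()
    if isinstance(link_stream, str):
        link_text = link_stream
    else:
        link_text = link_stream.read()

    row_of: dict[str, int] = {}
    used_rows: dict[int, str] = {}
    for name, row in _parse_assignments(node_text, "row"):
        if name not in network:
            raise ValidationError(f"node-order file names unknown node {name!r}")
        if name in row_of:
            raise ValidationError(f"node {name!r} assigned a row twice")
        if row in used_rows:
            raise ValidationError(
                f"row {row} assigned to both {used_rows[row]!r} and {name!r}"
            )
        row_of[name] = row
        used_rows[row] = name
    missing = [v for v in network.nodes if v not in row_of]
    if missing:
        raise ValidationError(f"node-order file omits nodes: {missing}")
    if sorted(row_of.values()) != list(range(1, network.n + 1)):
        raise ValidationError("node rows are not contiguous 1..n")
    order = NodeOrder(row_of)

    by_key = {link_key(link): link for link in network.links}
    column_of: dict[Link, int] = {}
    used_cols: dict[int, str] = {}
    for key, col in _parse_assignments(link_text, "column"):
        link = by_key.get(key)
        if link is None:
            raise ValidationError(f"link-order file names unknown link {key!r}")
        if link in column_of:
            raise ValidationError(f"link {key!r} assigned a column twice")
        if col in used_cols:
            raise ValidationError(
                f"column {col} assigned to both {used_cols[col]!r} and {key!r}"
            )
        column_of[link] = col
        used_cols[col] = key
    absent = [link_key(l) for l in network.links if l not in column_of]
    if absent:
        raise ValidationError(f"link-order file omits links: {absent}")
    if sorted(column_of.values()) != list(range(1, network.e + 1)):
        raise ValidationError("link columns are not contiguous 1..E")

    return order, ColumnAssignment.from_columns(network, order, column_of)
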