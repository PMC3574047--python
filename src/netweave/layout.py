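"""Default node-row assignment: breadth-first, degree-ordered traversal.

Rows are assigned by a breadth-first walk that starts from the most connected
component and visits neighbors in decreasing-degree order:

1. Seed: the highest-degree node not yet placed takes the next free row
   (components are therefore entered in order of their maximum-degree node).
2. For each placed row in turn, the row's node appends its still-unplaced
   neighbors, sorted by decreasing degree.
3. When the walk runs past the last placed row the current component is
   exhausted and the next seed is taken.

All edges are treated as undirected; duplicate relations between the same
endpoints are ignored for degree; every tie is broken by lexicographic
(ordinal, case-sensitive) node-name order.  Lone nodes have degree 0 and so
end up in the highest rows, sorted by name.
"""

from __future__ import annotations

from .model import Network, NodeOrder

__all__ = ["assign_rows"]


def assign_rows(network: Network) -> NodeOrder:
    """Breadth-first degree-ordered row assignment; bijection onto 1..n."""
    adj = network.adjacency()
    deg = {v: len(nbrs) for v, nbrs in adj.items()}
    unassigned = set(network.nodes)
    order: list[str] = []
    current = 0  # index into `order` of the row being expanded
    while unassigned:
        if current >= len(order):
            # current row is empty: re-seed from highest-degree unplaced node
            seed = min(unassigned, key=lambda v: (-deg[v], v))
            unassigned.remove(seed)
            order.append(seed)
        node = order[current]
        for nbr in sorted(adj[node] - {node}, key=lambda v: (-deg[v], v)):
            if nbr in unassigned:
                unassigned.remove(nbr)
                order.append(nbr)
        current += 1
    return NodeOrder({name: row for row, name in enumerate(order, start=1)})
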