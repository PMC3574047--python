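"""Edge-column assignment: standard, shadow and grouped modes."""

from __future__ import annotations

import pytest

from netweave.columns import (ColumnAssignment, LinkGroupSpec, assign_columns,
                              expand_shadows)
from netweave.fixtures import canonical
from netweave.layout import assign_rows
from netweave.model import Link, Network, ValidationError, link_key

from .conftest import random_network


def keys_by_column(cols: ColumnAssignment) -> list[str]:
    return [link_key(l) for l in cols.by_column()]


class TestExpandShadows:
    def test_single_edge_doubles(self):
        net = expand_shadows(canonical("single_edge"))
        assert net.e == 2
        assert sorted(l.shadow for l in net.links) == [False, True]

    def test_empty_network_stays_empty(self):
        assert expand_shadows(Network()).e == 0

    def test_triangle_preserves_base_relations(self):
        net = expand_shadows(canonical("triangle"))
        assert net.e == 6
        assert {l.base_relation for l in net.links} == {"pp"}

    def test_double_expansion_is_an_error(self):
        with pytest.raises(ValidationError, match="already"):
            expand_shadows(expand_shadows(canonical("triangle")))


class TestStandardMode:
    def test_path3_worked_example(self):
        net = canonical("path3")
        order = assign_rows(net)  # B:1 A:2 C:3
        cols = assign_columns(net, order)
        assert keys_by_column(cols) == ["A (pp) B", "B (pp) C"]
        assert cols.zone_of == {"B": (1, 2), "A": None, "C": None}
        assert cols.extent_of == {"A": (1, 1), "B": (1, 2), "C": (2, 2)}

    def test_zone_holds_links_with_upper_endpoint_here(self):
        net = canonical("triangle_pendant")
        order = assign_rows(net)  # A:1 B:2 C:3 D:4
        cols = assign_columns(net, order)
        for link in net.links:
            upper = min((link.source, link.target), key=lambda v: order[v])
            assert cols.owner_of[link] == upper

    def test_relation_tie_breaks_lexicographically(self):
        net = canonical("multi_relation_pair")
        cols = assign_columns(net, assign_rows(net))
        assert keys_by_column(cols) == ["A (x-t1) B", "A (y-t2) B"]

    def test_directed_pair_downward_before_upward(self):
        net = Network.from_links([Link("A", "B", "pd", directed=True),
                                  Link("B", "A", "pd", directed=True)])
        order = assign_rows(net)  # A:1 B:2
        cols = assign_columns(net, order)
        first = cols.by_column()[0]
        assert (first.source, first.target) == ("A", "B")  # downward first

    def test_self_loop_takes_first_bucket_of_its_zone(self):
        net = Network.from_links([Link("A", "A", "ss"), Link("A", "B", "pp")])
        order = assign_rows(net)
        cols = assign_columns(net, order)
        loop = next(l for l in net.links if l.is_self_loop)
        assert cols[loop] == 1

    def test_standard_mode_rejects_expanded_network(self):
        net = expand_shadows(canonical("triangle"))
        with pytest.raises(ValidationError):
            assign_columns(net, assign_rows(canonical("triangle")),
                           mode="standard")


class TestShadowMode:
    def test_triangle_worked_example(self):
        base = canonical("triangle")
        order = assign_rows(base)  # A:1 B:2 C:3
        cols = assign_columns(expand_shadows(base), order, mode="shadow")
        assert keys_by_column(cols) == [
            "A (pp) B", "A (pp) C",            # zone A: reals down to 2, 3
            "A (shdwpp) B", "B (pp) C",        # zone B: shadow up, real down
            "A (shdwpp) C", "B (shdwpp) C",    # zone C: shadows up
        ]
        for node in base.nodes:
            lo, hi = cols.zone_of[node]
            assert hi - lo + 1 == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_width_doubles_and_real_left_of_shadow(self, seed):
        net = random_network(14, 25, seed, multi_rel=True, directed_frac=0.3)
        order = assign_rows(net)
        std = assign_columns(net, order)
        sha = assign_columns(expand_shadows(net), order, mode="shadow")
        assert sha.width == 2 * std.width
        by_ident = {}
        for link, col in sha.column_of.items():
            ident = (link.source, link.target, link.base_relation)
            by_ident.setdefault(ident, {})[link.shadow] = col
        for cols_pair in by_ident.values():
            assert cols_pair[False] < cols_pair[True]

    @pytest.mark.parametrize("seed", range(8))
    def test_shadow_zone_is_the_full_incidence_inventory(self, seed):
        net = random_network(12, 22, seed, multi_rel=True)
        order = assign_rows(net)
        cols = assign_columns(expand_shadows(net), order, mode="shadow")
        owned: dict[str, int] = {v: 0 for v in net.nodes}
        for link in cols.column_of:
            owned[cols.owner_of[link]] += 1
        for v in net.nodes:
            incident = sum(1 for l in net.links if v in (l.source, l.target))
            assert owned[v] == incident

    def test_shadow_mode_requires_expanded_network(self):
        net = canonical("triangle")
        with pytest.raises(ValidationError, match="expanded"):
            assign_columns(net, assign_rows(net), mode="shadow")


class TestZoneStructure:
    @pytest.mark.parametrize("mode", ["standard", "shadow"])
    @pytest.mark.parametrize("seed", range(6))
    def test_bijectivity_and_zone_contiguity(self, seed, mode):
        net = random_network(15, 28, seed, multi_rel=True, lone=1)
        order = assign_rows(net)
        laid = expand_shadows(net) if mode == "shadow" else net
        cols = assign_columns(laid, order, mode=mode)
        assert sorted(cols.column_of.values()) == list(range(1, cols.width + 1))
        # zones: pairwise disjoint contiguous intervals in row order
        intervals = [(order[v], z) for v, z in cols.zone_of.items()
                     if z is not None]
        intervals.sort()
        covered = []
        for _, (lo, hi) in intervals:
            owned = sorted(c for l, c in cols.column_of.items()
                           if lo <= c <= hi)
            assert owned[0] == lo and owned[-1] == hi
            covered.append((lo, hi))
        for (a, b), (c, d) in zip(covered, covered[1:]):
            assert b < c  # disjoint and ordered by row

    @pytest.mark.parametrize("seed", range(6))
    def test_standard_zone_distal_rows_nondecreasing(self, seed):
        net = random_network(15, 30, seed, multi_rel=True)
        order = assign_rows(net)
        cols = assign_columns(net, order)
        per_zone: dict[str, list[tuple[int, int]]] = {}
        for link, col in cols.column_of.items():
            distal = max(order[link.source], order[link.target])
            per_zone.setdefault(cols.owner_of[link], []).append((col, distal))
        for items in per_zone.values():
            items.sort()
            distals = [d for _, d in items]
            assert distals == sorted(distals)

    @pytest.mark.parametrize("seed", range(6))
    def test_new_longer_link_preserves_prefix_zone_order(self, seed):
        """Adding a link whose upper endpoint sits lower never reorders the
        copies inside zones above it (the fabric grows, it does not shuffle)."""
        net = random_network(12, 20, seed)
        order = assign_rows(net)
        before = assign_columns(net, order)
        # add a fresh link between the two bottom rows (keeps order valid)
        u, v = order.node_at(net.n - 1), order.node_at(net.n)
        new = Link(u, v, "zz")
        grown = Network.from_links(list(net.links) + [new],
                                  lone_nodes=net.nodes)
        after = assign_columns(grown, order)
        cut = min(order[u], order[v])
        for node in net.nodes:
            if order[node] >= cut:
                continue
            old_zone = sorted((c, l) for l, c in before.column_of.items()
                              if before.owner_of[l] == node)
            new_zone = sorted((c, l) for l, c in after.column_of.items()
                              if after.owner_of[l] == node)
            assert [l for _, l in old_zone] == [l for _, l in new_zone]


class TestLinkGroups:
    def test_group_order_beats_lexicographic(self):
        net = canonical("multi_relation_pair")
        order = assign_rows(net)
        cols = assign_columns(net, order, groups=LinkGroupSpec(["t2", "t1"]))
        assert keys_by_column(cols) == ["A (y-t2) B", "A (x-t1) B"]

    def test_unmatched_relation_error_lists_offenders(self):
        net = canonical("multi_relation_pair")
        with pytest.raises(ValidationError, match="y-t2"):
            assign_columns(net, assign_rows(net),
                           groups=LinkGroupSpec(["t1"]))

    def test_shadow_copy_lands_in_same_group_as_real(self):
        net = expand_shadows(canonical("multi_relation_pair"))
        order = assign_rows(canonical("multi_relation_pair"))
        cols = assign_columns(net, order, mode="shadow",
                              groups=LinkGroupSpec(["t2", "t1"]))
        # zone of A (row 1): t2 group (real) then t1 group (real);
        # zone of B (row 2): shadows in the same group order
        assert keys_by_column(cols) == [
            "A (y-t2) B", "A (x-t1) B", "A (shdwy-t2) B", "A (shdwx-t1) B",
        ]

    def test_spec_validation(self):
        with pytest.raises(ValidationError):
            LinkGroupSpec([])
        with pytest.raises(ValidationError):
            LinkGroupSpec(["a", "a"])
        with pytest.raises(ValidationError):
            LinkGroupSpec(["a", ""])
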