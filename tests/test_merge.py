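from collections import Counter

import pytest

from ragmerge import (
    TreeError,
    all_merges_upto,
    are_isomorphic,
    build_catalog,
    data_vectors_for,
    enumerate_merges,
    merge_at,
    training_vectors,
)
from ragmerge.trees import path_tree, star_tree

from _oracles import brute_orbits

from reference_tables import AGGREGATION_EXAMPLE


class TestMergeAt:
    def test_order_and_neighborhood_union(self):
        t1, t2 = path_tree(4), star_tree(5)
        m = merge_at(t1, 1, t2, 0)
        assert m.order == t1.order + t2.order - 1
        # the identified vertex keeps u's neighbors and gains v's degree
        assert m.degree(1) == t1.degree(1) + t2.degree(0)

    def test_k2_with_k2_gives_path3(self):
        k2 = path_tree(2)
        assert are_isomorphic(merge_at(k2, 0, k2, 1), path_tree(3))

    def test_published_order6_anchors(self, catalog):
        p3, s4 = path_tree(3), star_tree(4)
        leaf_leaf = merge_at(p3, 0, s4, 1)
        assert catalog.entry_for(leaf_leaf).index == "6.2"
        support_support = merge_at(p3, 1, s4, 0)
        assert are_isomorphic(support_support, star_tree(6))
        assert catalog.entry_for(support_support).index == "6.6"

    def test_invalid_vertex(self):
        with pytest.raises(TreeError):
            merge_at(path_tree(3), 7, path_tree(3), 0)


class TestEnumerateMerges:
    def test_table_for_3_1_with_4_2(self, catalog):
        """The worked 3.1 + 4.2 example: 4 orbit classes, frequencies 6/3/2/1."""
        rows = enumerate_merges(
            catalog.by_index("3.1"), catalog.by_index("4.2"), catalog
        )
        assert len(rows) == 4
        assert sum(r.frequency for r in rows) == 12
        table = {
            r.result_index: (r.deg_v1, r.type_v1, r.deg_v2, r.type_v2, r.frequency)
            for r in rows
        }
        assert table == {
            "6.2": (1, "leaf", 1, "leaf", 6),
            "6.4": (2, "support", 1, "leaf", 3),
            "6.5": (1, "leaf", 3, "support", 2),
            "6.6": (2, "support", 3, "support", 1),
        }
        assert {r.result_color for r in rows} == {"red", "blue", "black"}

    def test_k2_self_merge_single_class(self, catalog):
        e = catalog.by_index("2.1")
        rows = enumerate_merges(e, e, catalog)
        assert len(rows) == 1
        assert rows[0].frequency == 4
        assert rows[0].result_index == "3.1"

    def test_symmetry_in_argument_order(self, catalog):
        e1, e2 = catalog.by_index("3.1"), catalog.by_index("4.2")
        assert enumerate_merges(e1, e2, catalog) == enumerate_merges(e2, e1, catalog)

    @pytest.mark.parametrize(
        "n1,n2",
        [(2, 2), (2, 3), (3, 3), (2, 4), (3, 4), (4, 4), (2, 5), (3, 5),
         (4, 5), (5, 5), (2, 6), (3, 6), (2, 7), (2, 8)],
    )
    def test_orbit_grouping_matches_brute_force(self, catalog, n1, n2):
        """Orbit-pair grouping == grouping all n*m labeled merges by
        brute-force automorphism orbits, for every motif pair of the orders."""
        for e1 in catalog.of_order(n1):
            for e2 in catalog.of_order(n2):
                if e1.order * e2.order > 36 or (n1, e1.z) > (n2, e2.z):
                    continue
                rows = enumerate_merges(e1, e2, catalog)
                t1, t2 = e1.tree, e2.tree
                orb1 = {v: frozenset(o) for o in brute_orbits(t1) for v in o}
                orb2 = {v: frozenset(o) for o in brute_orbits(t2) for v in o}
                self_merge = e1.index == e2.index
                groups = Counter()
                for u in range(t1.order):
                    for v in range(t2.order):
                        key = (orb1[u], orb2[v])
                        if self_merge:
                            key = frozenset(key) if orb1[u] != orb2[v] else (orb1[u],)
                        groups[key] += 1
                assert sorted(r.frequency for r in rows) == sorted(groups.values())
                # result classes agree with direct isomorphism lookup
                for r in rows:
                    assert r.result_index in {
                        catalog.entry_for(merge_at(t1, u, t2, v)).index
                        for u in range(t1.order)
                        for v in range(t2.order)
                    }


class TestAllMerges:
    def test_frequency_conservation_all_pairs(self, catalog, merge_rows):
        sums = Counter()
        for r in merge_rows:
            sums[(r.t1_index, r.t2_index)] += r.frequency
        assert len(sums) > 0
        for (i1, i2), total in sums.items():
            assert total == catalog.by_index(i1).order * catalog.by_index(i2).order

    def test_closure_every_result_in_catalog(self, catalog, merge_rows):
        for r in merge_rows:
            entry = catalog.by_index(r.result_index)
            assert entry.color == r.result_color

    def test_input_universe_and_result_orders(self, catalog, merge_rows):
        inputs = {r.t1_index for r in merge_rows} | {r.t2_index for r in merge_rows}
        assert len(inputs) == 47  # every motif of orders 2-8 occurs as an input
        for r in merge_rows:
            n1 = catalog.by_index(r.t1_index).order
            n2 = catalog.by_index(r.t2_index).order
            assert catalog.by_index(r.result_index).order == n1 + n2 - 1 <= 9

    def test_smallest_universe_is_the_k2_self_merge(self, catalog):
        rows = all_merges_upto(3, catalog)
        assert len(rows) == 1 and rows[0].result_index == "3.1"

    def test_incomplete_catalog_rejected(self, catalog):
        from ragmerge import Catalog

        partial = Catalog([e for e in catalog if e.order != 5])
        with pytest.raises(TreeError, match="missing orders \\[5\\]"):
            all_merges_upto(9, partial)


class TestDataVectors:
    def test_worked_example_tree_7_9(self, catalog, merge_rows):
        """Tree 7.9's five identification classes and their multiplicities."""
        vecs = data_vectors_for(catalog.by_index("7.9"), merge_rows, catalog)
        got = sorted((v.features, v.weight) for v in vecs)
        assert got == sorted(
            zip(
                [(1, 1, 1, 3), (1, 0, 1, 2), (1, 1, 2, 2), (1, 1, 2, 1), (1, 1, 1, 3)],
                AGGREGATION_EXAMPLE["weights"],
            )
        )
        # 7.9 is black, so every vector targets (0, 1)
        assert all(v.target == (0, 1) for v in vecs)

    def test_red_result_targets(self, catalog, merge_rows):
        vecs = data_vectors_for(catalog.by_index("8.3"), merge_rows, catalog)
        assert vecs and all(v.target == (1, 0) for v in vecs)

    def test_unknown_result_has_no_target(self, catalog, merge_rows):
        unknown = next(e for e in catalog.of_order(9) if e.color == "unknown")
        vecs = data_vectors_for(unknown, merge_rows, catalog)
        assert vecs and all(v.target is None for v in vecs)

    def test_unknown_input_color_is_an_error(self):
        # force an undecided small-tree color: c-features become ill-defined
        cat = build_catalog(5, colors={"2.1": "unknown"})
        rows = all_merges_upto(5, cat)
        with pytest.raises(TreeError, match="2.1"):
            training_vectors(cat, rows, orders=(3, 4, 5))

    def test_training_corpus_covers_26_trees(self, catalog, merge_rows):
        vecs = training_vectors(catalog, merge_rows)
        results = {v.result_index for v in vecs}
        assert len(results) == 26
        assert all(v.target is not None for v in vecs)
        degrees_ok = all(
            v.deg_v1 <= catalog.by_index(v.t1_index).order - 1
            and v.deg_v2 <= catalog.by_index(v.t2_index).order - 1
            for v in vecs
        )
        assert degrees_ok
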