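import itertools

import networkx as nx
import pytest

import dctspace as d


def neighbors_or_equal(a, b):
    return d.trees_equal(a, b) or d.as_dct(b) in d.all_neighbors(a, max(a.m, b.m))


class TestFindPath:
    def test_identical_trees_give_trivial_path(self):
        t = d.enumerate_ranked(4)[0]
        p = d.findpath(t, t)
        assert len(p) == 0 and p.trees == [t]

    def test_reversed_caterpillars_reach_the_diameter(self):
        for n in (4, 5, 6):
            labels = d.canonical_labels(n)
            t = d.caterpillar_ranked(labels)
            r = d.caterpillar_ranked(tuple(reversed(labels)))
            assert len(d.findpath(t, r)) == (n - 1) * (n - 2) // 2

    def test_matches_bfs_on_all_pairs(self, rnni4):
        graph, trees = rnni4
        dist = dict(nx.all_pairs_shortest_path_length(graph))
        for a, b in itertools.combinations(trees, 2):
            assert len(d.findpath(a.topology, b.topology)) == dist[a][b]

    def test_paths_are_valid_move_sequences(self, rnni4):
        _, trees = rnni4
        for a, b in itertools.combinations(trees[::3], 2):
            p = d.findpath(a.topology, b.topology)
            assert p.start == a.topology and p.end == b.topology
            assert len(p.moves) == len(p.trees) - 1
            for x, y in zip(p.trees, p.trees[1:]):
                assert neighbors_or_equal(d.as_dct(x), d.as_dct(y))

    def test_distance_is_symmetric(self):
        trees = d.enumerate_ranked(4)
        for a, b in itertools.combinations(trees, 2):
            assert d.rnni_distance(a, b) == d.rnni_distance(b, a)

    def test_cluster_preservation_along_findpath(self):
        """Trees sharing a cluster keep it on every tree of the path."""
        trees = d.enumerate_ranked(5)
        full = frozenset(range(5))
        checked = 0
        for a, b in itertools.combinations(trees[::5], 2):
            shared = (set(a.clusters) & set(b.clusters)) - {full}
            if not shared:
                continue
            checked += 1
            for t in d.findpath(a, b).trees:
                for c in shared:
                    assert c in t.clusters
        assert checked > 50

    def test_leaf_set_mismatch_rejected(self):
        a = d.caterpillar_ranked(["a1", "a2", "a3"])
        b = d.caterpillar_ranked(["x", "y", "z"])
        with pytest.raises(d.InvalidTreeError):
            d.findpath(a, b)


class TestExtension:
    def test_five_leaf_tree_in_dct6_extends_to_eight_leaves(self):
        t = d.DiscreteCoalescentTree.from_clusters(
            [{"a2", "a3"}, {"a1", "a5"}, {"a2", "a3", "a4"},
             {"a1", "a2", "a3", "a4", "a5"}],
            [1, 3, 4, 6],
            m=6,
        )
        ext = d.extend_to_ranked(t, 6)
        assert ext.whole.n == 8
        assert len(ext.added_labels) == 3
        assert d.trees_equal(ext.restrict(), t)

    def test_caterpillar_part_times_are_the_free_slots(self):
        topo = d.validate_ranked([{"a1", "a2"}, {"a1", "a2", "a3"}])
        t = d.validate_dct(topo, (2, 4), 4)
        ext = d.extend_to_ranked(t, 4)
        orig = frozenset(range(3))
        c_times = [
            i + 1 for i, c in enumerate(ext.whole.clusters) if not (c & orig)
        ]
        assert c_times == [1, 3]  # complement of {2, 4} in {1..4}
        # root at m + 1, every slot 1..m+1 filled
        assert ext.whole.n - 1 == t.m + 1

    def test_degenerate_extension_of_a_ranked_tree(self):
        # m = n - 1: a single added leaf directly below the new root
        for topo in d.enumerate_ranked(4):
            t = d.DiscreteCoalescentTree.from_ranked(topo)
            ext = d.extend_to_ranked(t, 3)
            assert ext.whole.n == 5
            assert ext.c_part_clusters() == []
            assert d.trees_equal(ext.restrict(), t)

    def test_roundtrip_over_enumerated_space(self):
        for t in d.enumerate_dct(3, 4):
            assert d.trees_equal(d.restrict(d.extend_to_ranked(t, 4)), t)

    def test_m_below_root_time_rejected(self):
        topo = d.validate_ranked([{"a1", "a2"}, {"a1", "a2", "a3"}])
        t = d.validate_dct(topo, (2, 5), 5)
        with pytest.raises(d.InvalidTreeError):
            d.extend_to_ranked(t, 4)


class TestFindPathPlus:
    def test_identical_trees(self, dct34):
        _, trees = dct34
        t = trees[0]
        assert len(d.findpath_plus(t, t, 4)) == 0

    def test_matches_bfs_and_extension_route(self, dct34):
        graph, trees = dct34
        dist = dict(nx.all_pairs_shortest_path_length(graph))
        for a, b in itertools.combinations(trees, 2):
            fp = len(d.findpath_plus(a, b, 4))
            assert fp == dist[a][b]
            assert fp == len(d.findpath_via_extension(a, b, 4))

    def test_path_equals_extension_route_pointwise(self, dct34):
        _, trees = dct34
        for a, b in itertools.combinations(trees[::2], 2):
            native = d.findpath_plus(a, b, 4).trees
            oracle = d.findpath_via_extension(a, b, 4).trees
            assert len(native) == len(oracle)
            for x, y in zip(native, oracle):
                assert d.trees_equal(x, y)

    def test_theorem_length_equals_extended_rnni_distance(self, dct34):
        _, trees = dct34
        for a, b in itertools.combinations(trees[::2], 2):
            fp_plus = len(d.findpath_plus(a, b, 4))
            te = d.extend_to_ranked(a, 4)
            re_ = d.extend_to_ranked(b, 4)
            assert fp_plus == len(d.findpath(te.whole, re_.whole))

    def test_distance_is_stable_in_m(self, dct34):
        _, trees = dct34
        for a, b in itertools.combinations(trees[::2], 2):
            assert d.dct_distance(a, b, 4) == d.dct_distance(a, b, 6)

    def test_distance_is_symmetric_and_bounded(self, dct34):
        _, trees = dct34
        n, m = 3, 4
        bound = (n - 1) * (n - 2) // 2 + (m - n + 1) * (n - 1)
        for a, b in itertools.combinations(trees, 2):
            dd = d.dct_distance(a, b, m)
            assert dd == d.dct_distance(b, a, m)
            assert 0 < dd <= bound

    def test_moves_are_classified(self, dct34):
        # with three leaves both internal nodes are always parent-child, so
        # rank moves cannot occur in this space
        _, trees = dct34
        kinds = set()
        for a, b in itertools.combinations(trees[::3], 2):
            p = d.findpath_plus(a, b, 4)
            for mv, (x, y) in zip(p.moves, zip(p.trees, p.trees[1:])):
                assert mv.kind in {"nni", "rank", "length"}
                kinds.add(mv.kind)
                if mv.kind == "length":
                    assert x.clusters == y.clusters and x.times != y.times
                elif mv.kind == "rank":
                    assert set(x.clusters) == set(y.clusters)
                    assert x.times == y.times
                else:
                    assert set(x.clusters) != set(y.clusters)
        assert kinds == {"nni", "length"}

    def test_rank_moves_appear_for_four_leaves(self):
        bal = d.DiscreteCoalescentTree.from_clusters(
            [{"a1", "a2"}, {"a3", "a4"}, {"a1", "a2", "a3", "a4"}], [1, 2, 3]
        )
        swapped = d.DiscreteCoalescentTree.from_clusters(
            [{"a3", "a4"}, {"a1", "a2"}, {"a1", "a2", "a3", "a4"}], [1, 2, 3]
        )
        p = d.findpath_plus(bal, swapped, 3)
        assert len(p) == 1 and p.moves[0].kind == "rank"

    def test_neighbor_pair_distance_one(self):
        a = d.as_dct(d.caterpillar_ranked(["a1", "a2", "a3"]))
        b = d.as_dct(d.caterpillar_ranked(["a2", "a3", "a1"]))
        assert d.dct_distance(a, b) == 1
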