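import itertools

import pytest

import dctspace as d


def cat3(cherry, times=(1, 2), m=None):
    third = ({"a1", "a2", "a3"} - set(cherry)).pop()
    topo = d.validate_ranked([set(cherry), {"a1", "a2", "a3"}])
    return d.validate_dct(topo, times, m if m is not None else max(times))


class TestNniMoves:
    def test_three_leaf_caterpillar_has_two_nni_neighbors(self):
        nbrs = d.nni_neighbors(cat3(("a1", "a2")))
        assert len(nbrs) == 2
        cherries = {frozenset(t.cherry()) for t in nbrs}
        assert cherries == {frozenset({"a1", "a3"}), frozenset({"a2", "a3"})}

    def test_no_unit_edge_means_no_nni(self):
        assert d.nni_neighbors(cat3(("a1", "a2"), times=(1, 3), m=4)) == []

    def test_balanced_four_leaf_tree(self):
        bal = d.as_dct(d.validate_ranked(
            [{"a1", "a2"}, {"a3", "a4"}, {"a1", "a2", "a3", "a4"}]
        ))
        # only the edge root -> rank-2 node has length one above an internal node
        assert len(d.nni_neighbors(bal)) == 2

    def test_contraction_oracle_on_all_pairs(self, rnni4):
        """T, R are NNI neighbours iff contracting unit edges (above internal
        nodes) yields identical timed trees — checked against enumeration."""
        _, trees = rnni4

        def signatures(t):
            sigs = set()
            for i in range(t.n - 2):
                j = t.topology.parent_index(i)
                if t.times[j] - t.times[i] == 1:
                    sigs.add(frozenset(
                        (c, ti) for k, (c, ti) in
                        enumerate(zip(t.clusters, t.times)) if k != i
                    ))
            return sigs

        sig = {t: signatures(t) for t in trees}
        for a, b in itertools.combinations(trees, 2):
            oracle = bool(sig[a] & sig[b])
            assert oracle == (b in d.nni_neighbors(a))


class TestRankMoves:
    def test_balanced_tree_has_one_rank_neighbor(self):
        bal = d.as_dct(d.validate_ranked(
            [{"a1", "a2"}, {"a3", "a4"}, {"a1", "a2", "a3", "a4"}]
        ))
        (nbr,) = d.rank_neighbors(bal)
        assert nbr.clusters[0] == frozenset({2, 3})

    def test_three_leaf_trees_have_no_rank_moves(self):
        for t in d.enumerate_ranked(3):
            assert d.rank_neighbors(t) == []

    def test_caterpillars_have_no_rank_moves(self):
        # all consecutive nodes of a ranked caterpillar are parent-child
        for t in d.enumerate_ranked(4):
            if t.is_caterpillar():
                assert d.rank_neighbors(t) == []


class TestLengthMoves:
    def test_stated_slots_for_stretched_three_leaf_tree(self):
        t = cat3(("a1", "a2"), times=(1, 3), m=4)
        got = {nb.times for nb in d.length_neighbors(t)}
        assert got == {(2, 3), (1, 4), (1, 2)}

    def test_fully_packed_tree_has_no_length_moves(self):
        assert d.length_neighbors(cat3(("a1", "a2"), times=(1, 2), m=2)) == []

    def test_root_capped_at_m(self):
        t = cat3(("a1", "a2"), times=(1, 4), m=4)
        assert all(nb.root_time <= 4 for nb in d.length_neighbors(t))
        assert (1, 5) not in {nb.times for nb in d.length_neighbors(t)}


class TestNeighborhoods:
    def test_three_leaf_rnni_is_a_triangle(self):
        trees = [d.as_dct(t) for t in d.enumerate_ranked(3)]
        for t in trees:
            nbrs = d.all_neighbors(t)
            assert len(nbrs) == 2
            assert t not in nbrs

    def test_every_neighbor_is_valid_and_in_space(self, dct34):
        _, trees = dct34
        space = set(trees)
        for t in trees:
            for nb in d.all_neighbors(t, 4):
                assert nb in space  # re-validated on construction

    def test_move_types_are_disjoint(self, dct34):
        _, trees = dct34
        for t in trees:
            sets = [
                set(d.nni_neighbors(t)),
                set(d.rank_neighbors(t)),
                set(d.length_neighbors(t)),
            ]
            for x, y in itertools.combinations(sets, 2):
                assert not (x & y)

    @pytest.mark.parametrize("n,m", [(3, 4), (4, 4), (4, 5)])
    def test_adjacency_is_symmetric(self, n, m):
        trees = d.enumerate_dct(n, m)
        nbrs = {t: set(d.all_neighbors(t, m)) for t in trees}
        for t in trees:
            for nb in nbrs[t]:
                assert t in nbrs[nb]

    def test_a_tree_admitting_all_three_move_types(self):
        # structural smoke test: with a gap in the times, a spare slot, and a
        # mixed topology all three neighbourhoods are non-empty
        t = d.DiscreteCoalescentTree.from_clusters(
            [{"a1", "a2"}, {"a3", "a4"}, {"a1", "a2", "a3", "a4"},
             {"a1", "a2", "a3", "a4", "a5"}],
            [2, 3, 4, 6],
            m=6,
        )
        assert d.nni_neighbors(t)
        assert d.rank_neighbors(t)
        assert d.length_neighbors(t)
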