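"""Shortest paths in ranked-tree space and discrete coalescent tree space.

``findpath`` computes a shortest RNNI path between two ranked trees: for each
target rank i (bottom-up over the second tree's clusters) the most recent
common ancestor of that cluster in the running tree is lowered one rank per
move — by the unique NNI move on the unit edge below it when the node of the
next-lower rank is its child, by a rank swap otherwise.

``findpath_plus`` is the native generalisation to discrete coalescent trees:
it sweeps the time slots k = 1..m, lowering the mrca of the target cluster at
time k by NNI, rank or length moves, or — when the running tree occupies a
slot the target leaves empty — pushing the blocking nodes up by length moves.
Its path length equals the RNNI distance between the *extended ranked
versions* of the two trees (ranked trees on m + 2 leaves obtained by adding
a root at time m + 1 and a caterpillar subtree filling the unused time
slots); that extension route is kept here as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .tree_core import (
    DiscreteCoalescentTree,
    InvalidTreeError,
    RankedTree,
    as_dct,
)


@dataclass(frozen=True)
class Move:
    """One step of a path: the move type and the times (slots) it acted on.

    ``kind`` is "nni", "rank" or "length"; ``times`` records the two time
    slots involved (for a length move: old and new time of the moved node).
    """

    kind: str
    times: tuple[int, int]


@dataclass
class TreePath:
    """A sequence of trees in which consecutive entries are one move apart."""

    trees: list
    moves: list[Move]

    def __len__(self) -> int:
        return len(self.moves)

    @property
    def start(self):
        return self.trees[0]

    @property
    def end(self):
        return self.trees[-1]


def _mrca_index(clusters: Sequence[frozenset[int]], s: frozenset[int]) -> int:
    for i, c in enumerate(clusters):
        if s <= c:
            return i
    raise AssertionError("root covers all leaves")  # pragma: no cover


def _children_blocks(clusters: Sequence[frozenset[int]], i: int):
    c = clusters[i]
    parts: list[frozenset[int]] = []
    covered: set[int] = set()
    for j in range(i - 1, -1, -1):
        cj = clusters[j]
        if cj <= c and covered.isdisjoint(cj):
            parts.append(cj)
            covered |= cj
            if len(covered) == len(c):
                break
    for e in sorted(c - covered):
        parts.append(frozenset((e,)))
    assert len(parts) == 2
    return parts


def _nni_lowering(clusters: list[frozenset[int]], r: int, target: frozenset[int]):
    """NNI move on the unit edge between ranks r and r+1 (indices r-1, r)
    that lowers the mrca of ``target`` to index r - 1; unique by construction."""
    below = clusters[r - 1]
    a, b = _children_blocks(clusters, r - 1)
    inter = target & below
    if inter <= a:
        keep = a
    else:
        assert inter <= b, "NNI lowering move is not unique"
        keep = b
    clusters[r - 1] = keep | (clusters[r] - below)


def findpath(T: RankedTree, R: RankedTree) -> TreePath:
    """Shortest RNNI path from T to R; its length is the RNNI distance."""
    if T.labels != R.labels:
        raise InvalidTreeError("trees must share a leaf set")
    n = T.n
    clusters = list(T.clusters)
    trees = [T]
    moves: list[Move] = []
    for i in range(n - 2):
        target = R.clusters[i]
        r = _mrca_index(clusters, target)
        while r > i:
            if clusters[r - 1] < clusters[r]:
                _nni_lowering(clusters, r, target)
                moves.append(Move("nni", (r + 1, r)))
            else:
                clusters[r - 1], clusters[r] = clusters[r], clusters[r - 1]
                moves.append(Move("rank", (r + 1, r)))
            r -= 1
            trees.append(RankedTree(T.labels, tuple(clusters)))
        assert clusters[i] == target
    assert tuple(clusters) == R.clusters
    return TreePath(trees, moves)


def rnni_distance(T: RankedTree, R: RankedTree) -> int:
    """RNNI distance between two ranked trees (length of the FindPath path)."""
    if isinstance(T, DiscreteCoalescentTree):
        T = T.topology if T.is_ranked() else None
    if isinstance(R, DiscreteCoalescentTree):
        R = R.topology if R.is_ranked() else None
    if T is None or R is None:
        raise InvalidTreeError("rnni_distance expects ranked trees")
    return len(findpath(T, R))


# -- extension to ranked trees ---------------------------------------


@dataclass(frozen=True)
class ExtendedRankedTree:
    """Ranked tree on m + 2 leaves encoding a DCT on n leaves.

    The original tree sits below the new root (time m + 1) as the subtree on
    the first n leaves; a caterpillar subtree on the added leaves occupies
    exactly the time slots in {1..m} unused by the original tree.
    """

    whole: RankedTree
    n_original: int
    m: int

    @property
    def added_labels(self) -> tuple[str, ...]:
        return self.whole.labels[self.n_original :]

    def d_part_clusters(self) -> list[frozenset[int]]:
        orig = frozenset(range(self.n_original))
        return [c for c in self.whole.clusters if c <= orig]

    def c_part_clusters(self) -> list[frozenset[int]]:
        orig = frozenset(range(self.n_original))
        return [c for c in self.whole.clusters if not (c & orig)]

    def restrict(self) -> DiscreteCoalescentTree:
        return restrict(self)


def _fresh_labels(existing: Sequence[str], count: int, start_index: int):
    labels = []
    taken = set(existing)
    k = start_index
    while len(labels) < count:
        cand = f"a{k}"
        if cand in taken:
            cand = f"ext{k}"
        labels.append(cand)
        taken.add(cand)
        k += 1
    return tuple(labels)


def extend_to_ranked(tree, m: int | None = None) -> ExtendedRankedTree:
    """Extended ranked version of a discrete coalescent tree.

    Adds a new root at time m + 1 whose second child is a caterpillar tree on
    m + 2 - n fresh leaves; the caterpillar's internal nodes take exactly the
    times in {1..m} not used by the original tree, so the result is a ranked
    tree on m + 2 leaves (every rank 1..m+1 occupied).
    """
    t = as_dct(tree)
    if m is None:
        m = t.m
    if m < t.root_time:
        raise InvalidTreeError(
            f"m={m} is below the root time {t.root_time}"
        )
    n = t.n
    n_added = m + 2 - n
    added = _fresh_labels(t.labels, n_added, n + 1)
    labels = t.labels + added
    free = sorted(set(range(1, m + 1)) - set(t.times))
    assert len(free) == n_added - 1
    by_time: dict[int, frozenset[int]] = {
        ti: c for c, ti in zip(t.clusters, t.times)
    }
    for j, ft in enumerate(free, start=2):
        by_time[ft] = frozenset(range(n, n + j))
    by_time[m + 1] = frozenset(range(len(labels)))
    clusters = tuple(by_time[k] for k in range(1, m + 2))
    whole = RankedTree(labels, clusters)
    whole._validate()
    return ExtendedRankedTree(whole, n, m)


def restrict(extended) -> DiscreteCoalescentTree:
    """Inverse of :func:`extend_to_ranked` on its image.

    Also applies to any ranked tree arising on a FindPath path between two
    extended ranked versions: cluster preservation guarantees every such tree
    splits into a pure-original part and the shared added caterpillar, so the
    pure-original clusters with their ranks as times form a valid DCT.
    """
    if isinstance(extended, ExtendedRankedTree):
        whole, n, m = extended.whole, extended.n_original, extended.m
    else:
        raise TypeError("restrict expects an ExtendedRankedTree")
    return restrict_tree(whole, n, m)


def restrict_tree(whole: RankedTree, n_original: int, m: int) -> DiscreteCoalescentTree:
    orig = frozenset(range(n_original))
    clusters = []
    times = []
    for i, c in enumerate(whole.clusters):
        if c <= orig:
            clusters.append(c)
            times.append(i + 1)
        elif c & orig and i + 1 <= m:
            raise InvalidTreeError(
                "tree mixes original and added leaves below the root; "
                "not the restriction of an extension-path tree"
            )
    topo = RankedTree(whole.labels[:n_original], tuple(clusters))
    topo._validate()
    return DiscreteCoalescentTree(topo, tuple(times), m)


def findpath_via_extension(T, R, m: int | None = None) -> TreePath:
    """Oracle route for FindPath+: extend, run FindPath, restrict pointwise."""
    t, r = as_dct(T), as_dct(R)
    if m is None:
        m = max(t.root_time, r.root_time)
    te = extend_to_ranked(t, m)
    re_ = extend_to_ranked(r, m)
    fp = findpath(te.whole, re_.whole)
    trees = [restrict_tree(w, t.n, m) for w in fp.trees]
    moves = [_classify(a, b) for a, b in zip(trees, trees[1:])]
    return TreePath(trees, moves)


def _classify(a: DiscreteCoalescentTree, b: DiscreteCoalescentTree) -> Move:
    """Move descriptor for two adjacent DCTs (used by the oracle route)."""
    if a.clusters != b.clusters:
        diff = [i for i, (x, y) in enumerate(zip(a.clusters, b.clusters)) if x != y]
        if set(a.clusters) == set(b.clusters):
            i = diff[0]
            return Move("rank", (a.times[i + 1], a.times[i]))
        return Move("nni", (a.times[diff[0] + 1], a.times[diff[0]]))
    if a.times != b.times:
        (i,) = [i for i, (x, y) in enumerate(zip(a.times, b.times)) if x != y]
        return Move("length", (a.times[i], b.times[i]))
    raise AssertionError("consecutive path trees are identical")


# -- FindPath+ --------------------------------------------------------


def findpath_plus(T, R, m: int | None = None) -> TreePath:
    """Shortest path between two discrete coalescent trees in DCT_m.

    If ``m`` is not given it is taken as the maximum root time of the two
    trees (the distance does not depend on m beyond that).
    """
    t, r = as_dct(T), as_dct(R)
    if t.labels != r.labels:
        raise InvalidTreeError("trees must share a leaf set")
    if m is None:
        m = max(t.root_time, r.root_time)
    if m < t.root_time or m < r.root_time:
        raise InvalidTreeError("m is below a root time of the input trees")

    labels = t.labels
    clusters = list(t.clusters)
    times = list(t.times)
    r_by_time = {ti: c for c, ti in zip(r.clusters, r.times)}

    def snapshot() -> DiscreteCoalescentTree:
        return DiscreteCoalescentTree(
            RankedTree(labels, tuple(clusters)), tuple(times), m
        )

    trees = [snapshot()]
    moves: list[Move] = []

    for k in range(1, m + 1):
        if k in r_by_time:
            target = r_by_time[k]
            while True:
                idx = _mrca_index(clusters, target)
                tcur = times[idx]
                assert tcur >= k
                if tcur == k:
                    break
                if idx > 0 and times[idx - 1] == tcur - 1:
                    if clusters[idx - 1] < clusters[idx]:
                        _nni_lowering(clusters, idx, target)
                        moves.append(Move("nni", (tcur, tcur - 1)))
                    else:
                        clusters[idx - 1], clusters[idx] = (
                            clusters[idx],
                            clusters[idx - 1],
                        )
                        moves.append(Move("rank", (tcur, tcur - 1)))
                else:
                    # slot below is free: a length move keeps the rank order
                    times[idx] = tcur - 1
                    moves.append(Move("length", (tcur, tcur - 1)))
                trees.append(snapshot())
            assert clusters[_mrca_index(clusters, target)] == target
        elif k in times:
            # The running tree blocks a slot the target leaves empty: shift
            # the contiguous block of nodes at times k..i-1 up by one, where
            # i is the lowest free slot above k.  Top-down application keeps
            # every intermediate target slot free.
            occupied = set(times)
            i = k + 1
            while i in occupied:
                i += 1
            assert i <= m, "no free slot below the bound m"
            for tt in range(i - 1, k - 1, -1):
                idx = times.index(tt)
                times[idx] = tt + 1
                moves.append(Move("length", (tt, tt + 1)))
                trees.append(snapshot())
        # else: neither tree uses slot k — nothing to do

    assert tuple(clusters) == r.clusters and tuple(times) == r.times
    return TreePath(trees, moves)


def dct_distance(T, R, m: int | None = None) -> int:
    """Distance in DCT_m (length of the FindPath+ path); symmetric."""
    return len(findpath_plus(T, R, m))
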