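"""Ranked trees and discrete coalescent trees.

A *ranked tree* on n leaves is a rooted binary tree whose internal nodes are
totally ordered by their coalescence order: the node of rank i induces the
cluster C_i (the set of leaves below it), and the rank-ordered cluster
sequence [C_1, ..., C_{n-1}] determines the tree uniquely.  A *discrete
coalescent tree* (DCT) additionally assigns strictly increasing positive
integer times t_1 < ... < t_{n-1} to the ranked nodes, with all leaves at
time 0 and the root time bounded by an integer m >= n - 1.

The cluster sequence is the canonical internal representation; leaf labels
are mapped to integer indices on input and clusters are stored as frozensets
of indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class InvalidTreeError(ValueError):
    """Raised when a cluster/time sequence does not define a valid tree."""


_NATURAL_RE = re.compile(r"(\d+)")


def _natural_key(label: str):
    return tuple(int(p) if p.isdigit() else p for p in _NATURAL_RE.split(label))


def canonical_labels(n: int) -> tuple[str, ...]:
    """Default leaf names a1..an."""
    return tuple(f"a{i}" for i in range(1, n + 1))


@dataclass(frozen=True)
class Node:
    """Reference to one internal node of a tree (rank, time and cluster)."""

    rank: int
    time: int
    cluster: frozenset[str]


@dataclass(frozen=True)
class RankedTree:
    """Ranked tree stored as leaf labels plus rank-ordered index clusters.

    ``clusters[i]`` is the frozenset of leaf *indices* below the node of rank
    i + 1.  Use :meth:`from_clusters` to build from label sets with
    validation.
    """

    labels: tuple[str, ...]
    clusters: tuple[frozenset[int], ...]

    @property
    def n(self) -> int:
        return len(self.labels)

    # -- construction -------------------------------------------------

    @classmethod
    def from_clusters(
        cls,
        clusters: Sequence[Iterable[str]],
        labels: Sequence[str] | None = None,
    ) -> "RankedTree":
        """Validate a sequence of label sets as a ranked tree.

        Leaf labels default to the (naturally sorted) union of the clusters.
        Raises :class:`InvalidTreeError` for a non-laminar family, a cluster
        that is not the union of two existing blocks, or a wrong-length
        sequence.
        """
        cluster_sets = [frozenset(c) for c in clusters]
        if labels is None:
            union: set[str] = set()
            for c in cluster_sets:
                union |= c
            labels = sorted(union, key=_natural_key)
        labels = tuple(str(lb) for lb in labels)
        if len(set(labels)) != len(labels):
            raise InvalidTreeError("leaf labels must be pairwise distinct")
        if len(labels) < 2:
            raise InvalidTreeError("a tree needs at least two leaves")
        index = {lb: i for i, lb in enumerate(labels)}
        try:
            idx_clusters = tuple(
                frozenset(index[lb] for lb in c) for c in cluster_sets
            )
        except KeyError as exc:
            raise InvalidTreeError(f"unknown leaf label {exc.args[0]!r}") from None
        tree = cls(labels, idx_clusters)
        tree._validate()
        return tree

    def _validate(self) -> None:
        n = self.n
        if len(self.clusters) != n - 1:
            raise InvalidTreeError(
                f"expected {n - 1} clusters for {n} leaves, got {len(self.clusters)}"
            )
        # Bottom-up: each cluster must be the union of exactly two current
        # blocks (earlier clusters or singletons).  This enforces laminarity
        # and binarity in one pass.
        block_of: dict[int, frozenset[int]] = {
            i: frozenset((i,)) for i in range(n)
        }
        for pos, c in enumerate(self.clusters):
            if not c:
                raise InvalidTreeError("empty cluster")
            it = iter(c)
            first = next(it)
            b1 = block_of[first]
            second = next((e for e in c if e not in b1), None)
            if second is None:
                raise InvalidTreeError(
                    f"cluster {self._format_cluster(c)} (rank {pos + 1}) is not "
                    "the union of two distinct blocks"
                )
            b2 = block_of[second]
            if len(b1) + len(b2) != len(c) or (b1 | b2) != c:
                raise InvalidTreeError(
                    f"cluster {self._format_cluster(c)} (rank {pos + 1}) is not "
                    "the union of two existing blocks (non-laminar family?)"
                )
            for e in c:
                block_of[e] = c
        if self.clusters[-1] != frozenset(range(n)):
            raise InvalidTreeError("last cluster must be the full leaf set")

    # -- queries ------------------------------------------------------

    def _format_cluster(self, c: frozenset[int]) -> str:
        return "{" + ",".join(self.labels[i] for i in sorted(c)) + "}"

    def cluster_labels(self, rank: int) -> frozenset[str]:
        """Cluster of the node with the given rank (1-based), as labels."""
        return frozenset(self.labels[i] for i in self.clusters[rank - 1])

    def parent_index(self, i: int) -> int | None:
        """Index of the parent cluster of ``clusters[i]`` (None for root)."""
        c = self.clusters[i]
        for j in range(i + 1, len(self.clusters)):
            if c < self.clusters[j]:
                return j
        return None

    def children_blocks(self, i: int) -> tuple[frozenset[int], frozenset[int]]:
        """The two blocks (earlier clusters or singletons) partitioning clusters[i]."""
        c = self.clusters[i]
        parts: list[frozenset[int]] = []
        covered: set[int] = set()
        for j in range(i - 1, -1, -1):
            cj = self.clusters[j]
            if cj <= c and covered.isdisjoint(cj):
                parts.append(cj)
                covered |= cj
                if len(covered) == len(c):
                    break
        for e in sorted(c - covered):
            parts.append(frozenset((e,)))
        assert len(parts) == 2, "binary tree invariant violated"
        return parts[0], parts[1]

    def mrca_index(self, leaf_labels: Iterable[str]) -> int:
        """Index (rank - 1) of the most recent common ancestor of a leaf set."""
        index = {lb: i for i, lb in enumerate(self.labels)}
        try:
            s = frozenset(index[lb] for lb in leaf_labels)
        except KeyError as exc:
            raise InvalidTreeError(f"unknown leaf label {exc.args[0]!r}") from None
        if not s:
            raise InvalidTreeError("mrca of an empty set is undefined")
        for i, c in enumerate(self.clusters):
            if s <= c:
                return i
        raise AssertionError("root covers all leaves")  # pragma: no cover

    def is_caterpillar(self) -> bool:
        """True if every internal node has at least one leaf child."""
        return all(
            len(self.clusters[i]) == i + 2 for i in range(len(self.clusters))
        )

    def cherries(self) -> list[frozenset[str]]:
        """All leaf pairs sharing a parent."""
        return [
            frozenset(self.labels[e] for e in c)
            for c in self.clusters
            if len(c) == 2
        ]

    def sort_key(self) -> tuple:
        return tuple(tuple(sorted(c)) for c in self.clusters)


@dataclass(frozen=True)
class DiscreteCoalescentTree:
    """A ranked tree together with integer node times bounded by m.

    Two discrete coalescent trees are equal when their leaf labels, cluster
    sequences and time sequences coincide; the bound ``m`` is metadata (the
    space the tree lives in) and does not enter identity.
    """

    topology: RankedTree
    times: tuple[int, ...]
    m: int = field(compare=False)

    def __post_init__(self) -> None:
        n = self.topology.n
        times = self.times
        if len(times) != n - 1:
            raise InvalidTreeError(
                f"expected {n - 1} node times, got {len(times)}"
            )
        if any(int(t) != t for t in times):
            raise InvalidTreeError("node times must be integers")
        if times and times[0] < 1:
            raise InvalidTreeError("node times must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidTreeError("node times must be strictly increasing")
        if self.m < n - 1:
            raise InvalidTreeError(f"bound m={self.m} below n-1={n - 1}")
        if times[-1] > self.m:
            raise InvalidTreeError(
                f"root time {times[-1]} exceeds bound m={self.m}"
            )

    # -- construction -------------------------------------------------

    @classmethod
    def from_clusters(
        cls,
        clusters: Sequence[Iterable[str]],
        times: Sequence[int],
        m: int | None = None,
        labels: Sequence[str] | None = None,
    ) -> "DiscreteCoalescentTree":
        topo = RankedTree.from_clusters(clusters, labels)
        times = tuple(int(t) for t in times)
        if m is None:
            m = max(times) if times else 1
        return cls(topo, times, m)

    @classmethod
    def from_ranked(cls, tree: RankedTree) -> "DiscreteCoalescentTree":
        """Embed a ranked tree as a DCT with times 1..n-1 and m = n-1."""
        return cls(tree, tuple(range(1, tree.n)), tree.n - 1)

    def with_m(self, m: int) -> "DiscreteCoalescentTree":
        return DiscreteCoalescentTree(self.topology, self.times, m)

    # -- delegated views ----------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return self.topology.labels

    @property
    def clusters(self) -> tuple[frozenset[int], ...]:
        return self.topology.clusters

    @property
    def n(self) -> int:
        return self.topology.n

    @property
    def root_time(self) -> int:
        return self.times[-1]

    def is_ranked(self) -> bool:
        return self.times == tuple(range(1, self.n))

    def node(self, rank: int) -> Node:
        return Node(rank, self.times[rank - 1], self.topology.cluster_labels(rank))

    def node_at_time(self, t: int) -> Node | None:
        """The internal node with time t, or None if the slot is empty."""
        for i, ti in enumerate(self.times):
            if ti == t:
                return self.node(i + 1)
        return None

    def mrca(self, leaf_labels: Iterable[str]) -> Node:
        """Most recent common ancestor of a leaf set.

        Following the standard convention, the mrca of a single leaf
        ``{a}`` is the parent of ``a``.
        """
        return self.node(self.topology.mrca_index(leaf_labels) + 1)

    def leaf_parent(self, label: str) -> Node:
        """Parent node of one leaf (the (a_i)_T query form)."""
        return self.mrca([label])

    def is_caterpillar(self) -> bool:
        return self.topology.is_caterpillar()

    def cherries(self) -> list[frozenset[str]]:
        return self.topology.cherries()

    def cherry(self) -> frozenset[str]:
        """The unique cherry of a caterpillar tree."""
        ch = self.cherries()
        if len(ch) != 1:
            raise InvalidTreeError("tree has more than one cherry")
        return ch[0]

    # -- serialization -------------------------------------------------

    def to_cluster_string(self) -> str:
        """Canonical ``[{a1,a2}:1,...]`` serialization (bit-exact dialect)."""
        items = []
        for c, t in zip(self.clusters, self.times):
            leaves = ",".join(self.labels[i] for i in sorted(c))
            items.append("{" + leaves + "}:" + str(t))
        return "[" + ",".join(items) + "]"

    def sort_key(self) -> tuple:
        return (self.times, self.topology.sort_key())


def validate_ranked(
    clusters: Sequence[Iterable[str]], leaves: Sequence[str] | None = None
) -> RankedTree:
    """Functional form of :meth:`RankedTree.from_clusters`."""
    return RankedTree.from_clusters(clusters, leaves)


def validate_dct(
    tree: RankedTree, times: Sequence[int], m: int
) -> DiscreteCoalescentTree:
    """Attach validated integer times (bounded by m) to a ranked tree."""
    return DiscreteCoalescentTree(tree, tuple(int(t) for t in times), m)


def trees_equal(t1, t2) -> bool:
    """Label-, cluster- and time-preserving identity (ignores the bound m)."""
    a = as_dct(t1)
    b = as_dct(t2)
    return a.labels == b.labels and a.clusters == b.clusters and a.times == b.times


def as_dct(tree) -> DiscreteCoalescentTree:
    """Coerce a RankedTree to its DCT embedding (times 1..n-1); pass DCTs through."""
    if isinstance(tree, DiscreteCoalescentTree):
        return tree
    if isinstance(tree, RankedTree):
        return DiscreteCoalescentTree.from_ranked(tree)
    raise TypeError(f"not a tree: {tree!r}")


def caterpillar_ranked(order: Sequence[str]) -> RankedTree:
    """Caterpillar ranked tree from a leaf order (first two entries = cherry)."""
    order = list(order)
    if len(order) < 2:
        raise InvalidTreeError("caterpillar needs at least two leaves")
    clusters = [set(order[:2])]
    for leaf in order[2:]:
        clusters.append(clusters[-1] | {leaf})
    return RankedTree.from_clusters(clusters)
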