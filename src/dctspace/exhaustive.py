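"""Brute-force ground truth for small tree spaces.

Enumerates all ranked trees on n leaves ((n-1)! n! / 2^(n-1) of them) and all
discrete coalescent trees with root time at most m (times enter as the
(n-1)-subsets of {1..m}), builds the explicit move graph, and answers
distance, diameter, radius, geodesic and cluster-property queries by BFS.
This module is the independent oracle the shortest-path algorithms are
tested against; it is deliberately capped by a vertex budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, factorial

import networkx as nx

from .moves import all_neighbors
from .tree_core import (
    DiscreteCoalescentTree,
    RankedTree,
    as_dct,
    canonical_labels,
)

DEFAULT_VERTEX_BUDGET = 5000
DEFAULT_PATH_CAP = 10**6


class BudgetExceededError(RuntimeError):
    """The requested space is larger than the configured oracle budget."""


def ranked_tree_count(n: int) -> int:
    return factorial(n - 1) * factorial(n) // 2 ** (n - 1)


def dct_count(n: int, m: int) -> int:
    return ranked_tree_count(n) * comb(m, n - 1)


def enumerate_ranked(n: int, labels=None) -> list[RankedTree]:
    """All ranked trees on n leaves, by recursive coalescent merging."""
    if labels is None:
        labels = canonical_labels(n)
    labels = tuple(labels)

    def merge(blocks: list[frozenset[int]]):
        if len(blocks) == 1:
            yield []
            return
        for i, j in combinations(range(len(blocks)), 2):
            merged = blocks[i] | blocks[j]
            rest = [b for k, b in enumerate(blocks) if k not in (i, j)]
            rest.append(merged)
            for tail in merge(rest):
                yield [merged] + tail

    singletons = [frozenset((i,)) for i in range(n)]
    trees = [
        RankedTree(labels, tuple(seq)) for seq in merge(singletons)
    ]
    assert len(trees) == ranked_tree_count(n)
    return trees


def enumerate_dct(n: int, m: int, labels=None) -> list[DiscreteCoalescentTree]:
    """All DCT_m trees on n leaves: ranked topologies x time subsets."""
    out = []
    for topo in enumerate_ranked(n, labels):
        for times in combinations(range(1, m + 1), n - 1):
            out.append(DiscreteCoalescentTree(topo, times, m))
    assert len(out) == dct_count(n, m)
    return out


def build_move_graph(
    trees,
    m: int | None = None,
    neighbor_fn=None,
    vertex_budget: int = DEFAULT_VERTEX_BUDGET,
) -> nx.Graph:
    """Explicit undirected move graph on an enumerated tree set.

    ``neighbor_fn(tree) -> iterable of trees`` defaults to the union of the
    three move types; every emitted neighbour must lie in the vertex set
    (closure check).
    """
    trees = [as_dct(t) for t in trees]
    if len(trees) > vertex_budget:
        raise BudgetExceededError(
            f"{len(trees)} vertices exceed the oracle budget {vertex_budget}"
        )
    if neighbor_fn is None:
        neighbor_fn = lambda t: all_neighbors(t, m)
    g = nx.Graph()
    g.add_nodes_from(trees)
    vertex_set = set(trees)
    for t in trees:
        for nb in neighbor_fn(t):
            assert nb in vertex_set, "neighbour outside the enumerated space"
            g.add_edge(t, nb)
    return g


def rnni_graph(n: int, **kwargs) -> nx.Graph:
    return build_move_graph(
        [as_dct(t) for t in enumerate_ranked(n)], n - 1, **kwargs
    )


def dct_graph(n: int, m: int, **kwargs) -> nx.Graph:
    return build_move_graph(enumerate_dct(n, m), m, **kwargs)


# -- BFS quantities ---------------------------------------------------


def bfs_distance(graph: nx.Graph, T, R) -> int:
    return nx.shortest_path_length(graph, as_dct(T), as_dct(R))


def eccentricity(graph: nx.Graph, T) -> int:
    return nx.eccentricity(graph, as_dct(T))


def diameter(graph: nx.Graph) -> int:
    return nx.diameter(graph)


def radius(graph: nx.Graph) -> int:
    return nx.radius(graph)


def all_shortest_paths(graph: nx.Graph, T, R, path_cap: int = DEFAULT_PATH_CAP):
    """Every geodesic between two trees (via the BFS predecessor DAG)."""
    count = 0
    for path in nx.all_shortest_paths(graph, as_dct(T), as_dct(R)):
        count += 1
        if count > path_cap:
            raise BudgetExceededError(
                f"more than {path_cap} geodesics between the given trees"
            )
        yield path


# -- theorem checkers -------------------------------------------------


@dataclass
class ClusterPropertyReport:
    n: int
    m: int
    pairs_checked: int
    geodesics_checked: int
    violations: list  # (T, R, missing cluster, offending path)

    @property
    def ok(self) -> bool:
        return not self.violations


def check_cluster_property(
    n: int,
    m: int | None = None,
    neighbor_fn=None,
    path_cap: int = DEFAULT_PATH_CAP,
    max_violations: int = 10,
) -> ClusterPropertyReport:
    """Verify that every geodesic preserves every shared non-trivial cluster.

    A corrupted ``neighbor_fn`` (e.g. NNI allowed across long edges) serves
    as a negative control: it is expected to produce violations.
    """
    if m is None:
        m = n - 1
    trees = enumerate_dct(n, m)
    graph = build_move_graph(trees, m, neighbor_fn=neighbor_fn)
    full = frozenset(range(n))
    violations = []
    pairs = 0
    geodesics = 0
    for i, a in enumerate(trees):
        a_clusters = set(a.clusters) - {full}
        for b in trees[i + 1 :]:
            shared = a_clusters & set(b.clusters)
            if not shared:
                continue
            pairs += 1
            for path in all_shortest_paths(graph, a, b, path_cap):
                geodesics += 1
                for c in shared:
                    if any(c not in t.clusters for t in path):
                        violations.append((a, b, c, path))
                        break
                if len(violations) >= max_violations:
                    return ClusterPropertyReport(
                        n, m, pairs, geodesics, violations
                    )
    return ClusterPropertyReport(n, m, pairs, geodesics, violations)


def corrupted_all_neighbors(tree, m: int | None = None):
    """Negative-control move set: additionally allows NNI across edges of
    length two, which is known to break the cluster property."""
    t = as_dct(tree)
    if m is not None:
        t = t.with_m(m)
    extra = []
    clusters = t.clusters
    times = t.times
    for i in range(len(clusters) - 1):
        j = t.topology.parent_index(i)
        if times[j] - times[i] != 2:
            continue
        a, b = t.topology.children_blocks(i)
        d = clusters[j] - clusters[i]
        for keep in (a, b):
            new_clusters = list(clusters)
            new_clusters[i] = keep | d
            try:
                topo = RankedTree(t.labels, tuple(new_clusters))
                topo._validate()
                extra.append(DiscreteCoalescentTree(topo, times, t.m))
            except Exception:
                continue  # exchange would break the rank ordering
    return all_neighbors(t) + extra


# -- diameter / radius ------------------------------------------------


def rnni_diameter_formula(n: int) -> int:
    return (n - 1) * (n - 2) // 2


def dct_diameter_formula(n: int, m: int) -> int:
    return rnni_diameter_formula(n) + (m - n + 1) * (n - 1)


@dataclass
class DiameterReport:
    n: int
    m: int
    bfs_diameter: int
    formula_diameter: int
    bfs_radius: int
    extremal_pair_distance: int | None

    @property
    def ok(self) -> bool:
        return self.bfs_diameter == self.formula_diameter


def verify_diameter_formulas(n: int, m: int | None = None) -> DiameterReport:
    """BFS diameter/radius of the enumerated space against the closed forms.

    Also measures the distance of an extremal caterpillar pair (ascending
    caterpillar occupying the top n-1 time slots vs descending caterpillar at
    times 1..n-1), which is expected — though reported, not asserted — to
    attain the diameter.
    """
    if m is None:
        m = n - 1
    graph = dct_graph(n, m)
    labels = canonical_labels(n)
    from .tree_core import caterpillar_ranked

    asc = DiscreteCoalescentTree(
        caterpillar_ranked(labels), tuple(range(m - n + 2, m + 1)), m
    )
    desc = DiscreteCoalescentTree(
        caterpillar_ranked(tuple(reversed(labels))), tuple(range(1, n)), m
    )
    from .findpath import dct_distance

    return DiameterReport(
        n,
        m,
        bfs_diameter=diameter(graph),
        formula_diameter=dct_diameter_formula(n, m),
        bfs_radius=radius(graph),
        extremal_pair_distance=dct_distance(asc, desc, m),
    )
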