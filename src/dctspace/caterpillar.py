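"""Closed-form RNNI distance between caterpillar trees.

A caterpillar tree is determined by its leaf order (parent ranks increasing;
the first two leaves form the cherry and are interchangeable).  For two
caterpillar trees T and R on the same leaves the RNNI distance is

    d(T, R) = p(T, R) - m(T, R)

where p counts *transpositions* — leaf pairs whose parent-rank order differs
strictly between the trees (pairs inside a cherry share a rank and are never
counted) — and m counts the leaves x of T such that every other leaf at or
below x's parent rank in T sits strictly above x in R, and no cherry leaf of
R sits at or below x in T.  The set of caterpillar trees is convex: some
shortest path between two caterpillar trees visits only caterpillar trees,
which is what makes the closed form (and the token-swapping view on lollipop
graphs) available.

Two implementations are provided: a quadratic reference (`direct`) that
materialises the sets P and M, and an O(n log n) one (`fast`) based on
merge-sort inversion counting plus a linear scan for m.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .tree_core import InvalidTreeError, as_dct


def caterpillar_order(tree) -> list[str]:
    """Leaf sequence by increasing parent rank; cherry first, lexicographically
    smaller cherry leaf leading (canonical resolution of the cherry ambiguity)."""
    t = as_dct(tree)
    if not t.is_caterpillar():
        raise InvalidTreeError("not a caterpillar tree")
    labels = t.labels
    order = sorted((labels[i] for i in t.clusters[0]))
    seen = set(t.clusters[0])
    for c in t.clusters[1:]:
        (new,) = c - seen
        order.append(labels[new])
        seen = c
    return order


def _parent_ranks(tree) -> dict[str, int]:
    order = caterpillar_order(tree)
    ranks = {order[0]: 1, order[1]: 1}
    for pos, leaf in enumerate(order[2:], start=2):
        ranks[leaf] = pos
    return ranks


def transposition_sets(T, R) -> tuple[set[frozenset[str]], set[str]]:
    """The sets P (as unordered leaf pairs) and M entering the distance formula.

    Pairs in P are stored orientation-free; in the ordered definition the
    first element is the one lower in T.  The "every other leaf" condition in
    M excludes the leaf itself (relevant inside T's cherry).
    """
    rt = _parent_ranks(T)
    rr = _parent_ranks(R)
    if set(rt) != set(rr):
        raise InvalidTreeError("trees must share a leaf set")
    leaves = sorted(rt)
    p_set = {
        frozenset((x, y))
        for x, y in combinations(leaves, 2)
        if (rt[x] - rt[y]) * (rr[x] - rr[y]) < 0
    }
    r_cherry_min_rank_in_t = min(
        rt[x] for x in leaves if rr[x] == 1
    )
    m_set = {
        x
        for x in leaves
        if rt[x] < r_cherry_min_rank_in_t
        and all(
            rr[l] > rr[x]
            for l in leaves
            if l != x and rt[l] <= rt[x]
        )
    }
    return p_set, m_set


def caterpillar_distance_direct(T, R) -> int:
    """Quadratic reference implementation of the closed-form distance."""
    p_set, m_set = transposition_sets(T, R)
    return len(p_set) - len(m_set)


def _merge_count(seq: list[int]) -> int:
    """Number of strict inversions, by merge sort; ties are not inversions."""
    n = len(seq)
    if n < 2:
        return 0
    mid = n // 2
    left, right = seq[:mid], seq[mid:]
    inv = _merge_count(left) + _merge_count(right)
    merged = []
    i = j = 0
    while i < len(left) and j < len(right):
        if left[i] <= right[j]:
            merged.append(left[i])
            i += 1
        else:
            inv += len(left) - i
            merged.append(right[j])
            j += 1
    merged.extend(left[i:])
    merged.extend(right[j:])
    seq[:] = merged
    return inv


def caterpillar_distance_fast(T, R) -> int:
    """O(n log n) caterpillar distance: inversion count minus the m correction.

    The transposition count p equals the number of strict inversions of R's
    parent ranks read along T's leaf order, once T's cherry pair is ordered so
    that it contributes no inversion (R's cherry pair is tied and never
    counts).  The correction m is one linear scan maintaining the running
    minimum of R-ranks.
    """
    rr = _parent_ranks(R)
    order = caterpillar_order(T)
    if set(order) != set(rr):
        raise InvalidTreeError("trees must share a leaf set")
    # order T's cherry so the (rank-tied) pair is ascending in R: no inversion
    if rr[order[0]] > rr[order[1]]:
        order[0], order[1] = order[1], order[0]
    seq = [rr[leaf] for leaf in order]

    p = _merge_count(list(seq))

    # m: leaves strictly below R's cherry (in T) whose T-predecessors all sit
    # strictly above them in R.  Positions 0 and 1 are rank-tied in T, so each
    # cherry leaf's condition includes the other one.
    r_cherry_positions = [i for i, v in enumerate(seq) if v == 1]
    cutoff_rank = min(
        1 if i <= 1 else i for i in r_cherry_positions
    )
    m = 0
    running_min = seq[0]
    for pos, leaf in enumerate(order):
        rank_t = 1 if pos <= 1 else pos
        if rank_t >= cutoff_rank:
            break
        if pos == 0:
            others_min = seq[1]  # the cherry partner is the only tied leaf
        elif pos == 1:
            others_min = seq[0]
        else:
            others_min = running_min
        if others_min > seq[pos]:
            m += 1
        running_min = min(running_min, seq[pos])
    return p - m


def caterpillar_distance(T, R, method: str = "fast") -> int:
    if method == "fast":
        return caterpillar_distance_fast(T, R)
    if method == "direct":
        return caterpillar_distance_direct(T, R)
    raise ValueError(f"unknown method {method!r}")


# -- convexity --------------------------------------------------------


@dataclass
class ConvexityReport:
    n: int
    m: int
    pairs_checked: int
    violations: list  # (T, R, restricted distance, full distance)

    @property
    def ok(self) -> bool:
        return not self.violations


def check_caterpillar_convexity(n: int, m: int | None = None) -> ConvexityReport:
    """Exhaustively verify convexity of the caterpillar set in DCT_m.

    For every pair of caterpillar trees in the enumerated space, the BFS
    distance inside the caterpillar-induced subgraph must equal the
    unrestricted BFS distance.
    """
    import networkx as nx

    from .exhaustive import build_move_graph, enumerate_dct

    if m is None:
        m = n - 1
    trees = enumerate_dct(n, m)
    graph = build_move_graph(trees, m)
    cats = [t for t in trees if t.is_caterpillar()]
    sub = graph.subgraph(cats)
    violations = []
    pairs = 0
    full = dict(nx.all_pairs_shortest_path_length(graph))
    restricted = dict(nx.all_pairs_shortest_path_length(sub))
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            pairs += 1
            d_full = full[a][b]
            d_sub = restricted[a].get(b)
            if d_sub != d_full:
                violations.append((a, b, d_sub, d_full))
    return ConvexityReport(n, m, pairs, violations)


# -- token swapping on lollipop graphs --------------------------------


@dataclass(frozen=True)
class LollipopInstance:
    """Token swapping instance equivalent to a caterpillar distance problem.

    The host graph is a lollipop: a triangle on the first three vertices
    (the cherry-side end), joined by an edge to a path through the remaining
    vertices.  ``vertex_labels[i]`` is the leaf sitting at position i in R;
    ``goals[i]`` is the vertex index the token currently on vertex i must
    reach.  The minimum number of adjacent token swaps equals the RNNI
    distance between the two caterpillar trees.
    """

    vertex_labels: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    goals: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.vertex_labels)


def to_token_swapping(T, R) -> LollipopInstance:
    """Build the lollipop token-swapping instance for two caterpillar trees.

    Vertices are labelled by R's leaf order (triangle: positions 0,1,2 with
    position 2 incident to the path).  The token placed on the vertex at
    position i carries as goal the vertex labelled by T's leaf at position i;
    if a cherry vertex of R carries a leaf that is also in T's cherry, that
    token is placed on its own vertex.
    """
    a_order = caterpillar_order(R)
    b_order = caterpillar_order(T)
    if set(a_order) != set(b_order):
        raise InvalidTreeError("trees must share a leaf set")
    n = len(a_order)
    if n < 3:
        raise InvalidTreeError("token swapping instance needs n >= 3 leaves")
    pos_a = {leaf: i for i, leaf in enumerate(a_order)}
    edges = [(0, 1), (0, 2), (1, 2)] + [(i, i + 1) for i in range(2, n - 1)]
    goals = [0] * n
    for i in range(2, n):
        goals[i] = pos_a[b_order[i]]
    # cherry placement: tokens with goals b_1, b_2 go on vertices a_1, a_2;
    # a token whose goal is itself a cherry vertex of R sits on that vertex
    t1, t2 = pos_a[b_order[0]], pos_a[b_order[1]]
    if t1 <= 1 and t2 <= 1:
        goals[t1], goals[t2] = t1, t2
    elif t1 <= 1:
        goals[t1] = t1
        goals[1 - t1] = t2
    elif t2 <= 1:
        goals[t2] = t2
        goals[1 - t2] = t1
    else:
        goals[0], goals[1] = t1, t2
    return LollipopInstance(tuple(a_order), tuple(edges), tuple(goals))


def min_token_swaps(instance: LollipopInstance) -> int:
    """Exact optimum by BFS over token configurations (small instances only).

    The goal tree, like any caterpillar, has two list representations
    differing by its cherry; both corresponding configurations (tokens with
    goals on the two cherry vertices interchanged) count as solved.
    """
    from collections import deque

    start = instance.goals
    ident = list(range(instance.n))
    targets = {tuple(ident), tuple([1, 0] + ident[2:])}
    if start in targets:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        conf, dist = queue.popleft()
        for u, v in instance.edges:
            nxt = list(conf)
            nxt[u], nxt[v] = nxt[v], nxt[u]
            nxt = tuple(nxt)
            if nxt in targets:
                return dist + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, dist + 1))
    raise AssertionError("configuration space is connected")  # pragma: no cover
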