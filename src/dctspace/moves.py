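"""The three move types generating the discrete coalescent tree graph.

Trees T and R are adjacent in DCT_m when one of the following turns T into R:

* an **NNI move** — across an edge of length one above an internal node,
  exchange one child subtree of the lower node with its sibling subtree;
  the only move that changes clusters;
* a **rank move** — exchange the times of two internal nodes with time
  difference one that are not in a parent-child relation;
* a **length move** — shift one internal node's time by one into an
  unoccupied slot, respecting the order constraints (above all children,
  below the parent, root capped at m).

For m = n - 1 (ranked trees) no length move is possible and the graph is
the RNNI graph.  A pair of adjacent trees is connected by exactly one move
type.  All functions return neighbours in canonical serialization order.
"""

from __future__ import annotations

from .tree_core import DiscreteCoalescentTree, RankedTree, as_dct


def _sorted(trees: list[DiscreteCoalescentTree]) -> list[DiscreteCoalescentTree]:
    return sorted(trees, key=lambda t: t.sort_key())


def nni_neighbors(tree) -> list[DiscreteCoalescentTree]:
    """All trees one NNI move away (times unchanged)."""
    t = as_dct(tree)
    clusters = t.clusters
    times = t.times
    out = []
    for i in range(len(clusters) - 1):
        j = t.topology.parent_index(i)
        assert j is not None
        if times[j] - times[i] != 1:
            continue
        a, b = t.topology.children_blocks(i)
        d = clusters[j] - clusters[i]
        for keep in (a, b):
            new_clusters = list(clusters)
            new_clusters[i] = keep | d
            out.append(
                DiscreteCoalescentTree(
                    RankedTree(t.labels, tuple(new_clusters)), times, t.m
                )
            )
    return _sorted(out)


def rank_neighbors(tree) -> list[DiscreteCoalescentTree]:
    """All trees one rank move away (cluster order swapped, times fixed)."""
    t = as_dct(tree)
    clusters = t.clusters
    times = t.times
    out = []
    for i in range(len(clusters) - 1):
        # only consecutive ranks can have time difference one
        if times[i + 1] - times[i] != 1:
            continue
        if clusters[i] < clusters[i + 1]:
            continue  # parent-child: swapping would break the time order
        new_clusters = list(clusters)
        new_clusters[i], new_clusters[i + 1] = new_clusters[i + 1], new_clusters[i]
        out.append(
            DiscreteCoalescentTree(
                RankedTree(t.labels, tuple(new_clusters)), times, t.m
            )
        )
    return _sorted(out)


def length_neighbors(tree, m: int | None = None) -> list[DiscreteCoalescentTree]:
    """All trees one length move away within the bound m (default: the tree's)."""
    t = as_dct(tree)
    if m is not None:
        t = t.with_m(m)
    clusters = t.clusters
    times = t.times
    occupied = set(times)
    root = len(times) - 1
    out = []
    for i in range(len(times)):
        a, b = t.topology.children_blocks(i)
        child_time = max(
            (times[clusters.index(blk)] for blk in (a, b) if len(blk) > 1),
            default=0,
        )
        if i == root:
            parent_cap = t.m
        else:
            j = t.topology.parent_index(i)
            parent_cap = times[j] - 1
        for target in (times[i] - 1, times[i] + 1):
            if target < 1 or target in occupied:
                continue
            if target <= child_time or target > parent_cap:
                continue
            new_times = list(times)
            new_times[i] = target
            out.append(
                DiscreteCoalescentTree(t.topology, tuple(new_times), t.m)
            )
    return _sorted(out)


def all_neighbors(tree, m: int | None = None) -> list[DiscreteCoalescentTree]:
    """Union of NNI, rank and length neighbourhoods, canonically ordered."""
    t = as_dct(tree)
    if m is not None:
        t = t.with_m(m)
    return _sorted(
        nni_neighbors(t) + rank_neighbors(t) + length_neighbors(t)
    )
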