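"""Reading and writing trees: Newick and the cluster-string dialect.

Newick dialect: rooted binary trees with branch lengths equal to the time
difference of the edge's endpoints.  All leaves must come out at the same
depth (time 0), internal times must be distinct positive integers.  Parsing
goes through dendropy so standard phylogenetics conventions (quoted labels,
whitespace) apply.

Cluster-string dialect (bit-exact): ``[{a1,a2}:1,{a1,a2,a5}:3,...]`` —
comma-separated ``{leaves}:time`` items in strictly increasing time order,
whitespace-insensitive.
"""

from __future__ import annotations

import re

import dendropy

from .tree_core import DiscreteCoalescentTree, InvalidTreeError, as_dct

_TIME_TOL = 1e-9


def parse_newick(text: str, m: int | None = None) -> DiscreteCoalescentTree:
    """Parse a rooted, binary, ultrametric Newick string with integer times.

    Node times are reconstructed as root_time - depth; the bound m defaults
    to the root time.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise InvalidTreeError(f"unreadable Newick: {exc}") from exc

    root = dtree.seed_node
    depths: dict = {root: 0.0}
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise InvalidTreeError("every edge needs a branch length")
        depths[node] = depths[node.parent_node] + node.edge.length

    leaves = [nd for nd in dtree.leaf_node_iter()]
    if len(leaves) < 2:
        raise InvalidTreeError("a tree needs at least two leaves")
    leaf_depths = {depths[nd] for nd in leaves}
    root_time = max(leaf_depths)
    if max(leaf_depths) - min(leaf_depths) > _TIME_TOL:
        raise InvalidTreeError("tree is not ultrametric (leaves at unequal times)")
    if abs(root_time - round(root_time)) > _TIME_TOL:
        raise InvalidTreeError("node times must be integers")
    root_time = round(root_time)

    internals = []
    for node in dtree.preorder_internal_node_iter():
        children = node.child_nodes()
        if len(children) != 2:
            raise InvalidTreeError("tree must be binary")
        t = root_time - depths[node]
        if abs(t - round(t)) > _TIME_TOL:
            raise InvalidTreeError("node times must be integers")
        t = round(t)
        if t < 1:
            raise InvalidTreeError("internal node times must be positive")
        cluster = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        internals.append((t, cluster))

    times = [t for t, _ in internals]
    if len(set(times)) != len(times):
        raise InvalidTreeError("internal node times must be distinct")
    internals.sort(key=lambda it: it[0])
    clusters = [c for _, c in internals]
    times = [t for t, _ in internals]
    tree = DiscreteCoalescentTree.from_clusters(
        clusters, times, m if m is not None else root_time
    )
    return tree


def write_newick(tree) -> str:
    """Serialize a tree in the branch-length-as-time-difference dialect."""
    t = as_dct(tree)
    labels = t.labels

    def render(block: frozenset, parent_time: int) -> str:
        if len(block) == 1:
            (i,) = block
            return f"{labels[i]}:{parent_time}"
        idx = t.clusters.index(block)
        a, b = t.topology.children_blocks(idx)
        a, b = sorted((a, b), key=min)
        own = t.times[idx]
        inner = f"({render(a, own)},{render(b, own)})"
        return inner if parent_time is None else f"{inner}:{parent_time - own}"

    root = t.clusters[-1]
    idx = len(t.clusters) - 1
    a, b = sorted(t.topology.children_blocks(idx), key=min)
    own = t.times[idx]
    return f"({render(a, own)},{render(b, own)});"


def write_clusters(tree) -> str:
    """Cluster-string serialization (deterministic, byte-identical)."""
    return as_dct(tree).to_cluster_string()


_ITEM_RE = re.compile(r"\{([^{}]*)\}\s*:\s*(\d+)")


def parse_clusters(text: str, m: int | None = None) -> DiscreteCoalescentTree:
    """Parse the ``[{a1,a2}:1,...]`` dialect; m defaults to the root time."""
    body = text.strip()
    if not (body.startswith("[") and body.endswith("]")):
        raise InvalidTreeError("cluster string must be bracketed")
    body = body[1:-1]
    items = _ITEM_RE.findall(body)
    leftover = _ITEM_RE.sub("", body).replace(",", "").strip()
    if leftover or not items:
        raise InvalidTreeError(f"malformed cluster string: {text!r}")
    clusters = []
    times = []
    for leaves, t in items:
        clusters.append({lb.strip() for lb in leaves.split(",") if lb.strip()})
        times.append(int(t))
    if any(b <= a for a, b in zip(times, times[1:])):
        raise InvalidTreeError("cluster-string times must be strictly increasing")
    return DiscreteCoalescentTree.from_clusters(
        clusters, times, m if m is not None else max(times)
    )


def parse_tree(text: str, fmt: str = "auto", m: int | None = None):
    """Dispatch between the two dialects (``auto`` sniffs the first character)."""
    text = text.strip()
    if fmt == "auto":
        fmt = "clusters" if text.startswith("[") else "newick"
    if fmt == "clusters":
        return parse_clusters(text, m)
    if fmt == "newick":
        return parse_newick(text, m)
    raise ValueError(f"unknown format {fmt!r}")
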