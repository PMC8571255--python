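"""Seeded random tree generation.

Ranked topologies are sampled by coalescent merging — repeatedly joining a
uniformly chosen pair of lineages — which is uniform over ranked trees
(labelled histories).  Times of a discrete coalescent tree are a uniformly
chosen (n-1)-subset of {1..m}.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import random
from typing import Sequence

from .tree_core import (
    DiscreteCoalescentTree,
    InvalidTreeError,
    RankedTree,
    canonical_labels,
    caterpillar_ranked,
)


def _rng(seed, rng) -> random.Random:
    if rng is not None:
        return rng
    return random.Random(seed)


def random_ranked_tree(
    n: int,
    seed: int | None = None,
    rng: random.Random | None = None,
    labels: Sequence[str] | None = None,
) -> RankedTree:
    """Uniform random ranked tree on n leaves (coalescent merging)."""
    r = _rng(seed, rng)
    if labels is None:
        labels = canonical_labels(n)
    labels = tuple(labels)
    blocks = [frozenset((i,)) for i in range(n)]
    clusters = []
    while len(blocks) > 1:
        i, j = r.sample(range(len(blocks)), 2)
        merged = blocks[i] | blocks[j]
        blocks = [b for k, b in enumerate(blocks) if k not in (i, j)]
        blocks.append(merged)
        clusters.append(merged)
    return RankedTree(labels, tuple(clusters))


def random_times(
    n: int, m: int, seed: int | None = None, rng: random.Random | None = None
) -> tuple[int, ...]:
    if m < n - 1:
        raise InvalidTreeError(f"m={m} below n-1={n - 1}")
    r = _rng(seed, rng)
    return tuple(sorted(r.sample(range(1, m + 1), n - 1)))


def random_dct(
    n: int,
    m: int,
    seed: int | None = None,
    rng: random.Random | None = None,
    labels: Sequence[str] | None = None,
) -> DiscreteCoalescentTree:
    """Random discrete coalescent tree: uniform ranked topology, uniform times."""
    r = _rng(seed, rng)
    topo = random_ranked_tree(n, rng=r, labels=labels)
    times = random_times(n, m, rng=r)
    return DiscreteCoalescentTree(topo, times, m)


def random_caterpillar(
    n: int,
    seed: int | None = None,
    rng: random.Random | None = None,
    labels: Sequence[str] | None = None,
) -> RankedTree:
    """Uniform random caterpillar ranked tree (uniform over leaf orders)."""
    r = _rng(seed, rng)
    if labels is None:
        labels = canonical_labels(n)
    order = list(labels)
    r.shuffle(order)
    return caterpillar_ranked(order)
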