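# dctspace

Tools for the space of **discrete coalescent trees** (DCT_m) and the
**ranked nearest-neighbour-interchange** (RNNI) graph.

Time trees — rooted binary trees whose internal nodes carry the times of
coalescence events — are the central object of clock-based phylogenetics
(virus evolution, cancer phylogenetics, coalescent-based population
inference). Tree-proposal and summary methods need a tree space with a
computable metric whose shortest paths respect shared evolutionary signal.
`dctspace` implements such a space for trees with *discrete* times: all n
leaves sit at time 0, the n−1 internal nodes carry distinct integer times
t_1 < … < t_{n−1} ≤ m. Two trees are neighbours when one move transforms
one into the other:

* **NNI move** — exchange subtrees across an edge of length one (the only
  move that changes clusters);
* **rank move** — swap the times of two non-adjacent nodes with time
  difference one;
* **length move** — shift one node's time by ±1 into a free slot (the root
  is capped at m).

For m = n−1 the space collapses to the RNNI graph of ranked trees. The
distance d(T, R) is the length of a shortest move path.

## What the package provides

* `tree_core` — `RankedTree` (rank-ordered cluster sequence) and
  `DiscreteCoalescentTree` (clusters + integer times), with validation,
  mrca/cherry/caterpillar queries and a bit-exact cluster-string dialect.
* `moves` — the three neighbourhoods, in canonical order.
* `findpath` — **FindPath** (shortest RNNI paths between ranked trees,
  O(n²)), **FindPath⁺** (shortest DCT_m paths, O(mn)), and the *extended
  ranked version* construction: a DCT on n leaves becomes a ranked tree on
  m+2 leaves (new root at time m+1, caterpillar subtree filling the unused
  time slots) with d_DCT(T,R) = d_RNNI(T_r,R_r); the extension route is kept
  as an independent oracle for FindPath⁺.
* `caterpillar` — the closed form d(T,R) = |P| − |M| for caterpillar trees
  (transposition set P, correction set M), both as a quadratic reference and
  as O(n log n) merge-sort inversion counting, plus the convexity checker
  and the token-swapping correspondence on lollipop graphs.
* `exhaustive` — enumeration of all ranked/DCT trees on small n
  ((n−1)!·n!/2^{n−1} and ×C(m,n−1)), the explicit move graph (networkx),
  BFS distances, diameter/radius, geodesic enumeration, and exhaustive
  checkers for the cluster property, the convexity of the caterpillar set
  and the diameter formulas (n−1)(n−2)/2 for RNNI and
  (n−1)(n−2)/2 + (m−n+1)(n−1) for DCT_m.
* `treeio` / `generate` / `cli` — Newick I/O (branch length = time
  difference), seeded uniform random ranked trees and DCTs, and the
  `dctspace` command-line tool.

## Worked example

```python
>>> import dctspace as d
>>> T = d.parse_newick("((a1:2,a2:2):2,a3:4);", m=4)   # times (2, 4)
>>> R = d.parse_newick("((a2:1,a3:1):3,a1:4);", m=4)   # times (1, 4)
>>> path = d.findpath_plus(T, R, 4)
>>> len(path)
4
>>> [mv.kind for mv in path.moves]
['length', 'nni', 'length', 'length']
>>> [t.to_cluster_string() for t in path.trees]
['[{a1,a2}:2,{a1,a2,a3}:4]', '[{a1,a2}:2,{a1,a2,a3}:3]', '[{a2,a3}:2,{a1,a2,a3}:3]', '[{a2,a3}:1,{a1,a2,a3}:3]', '[{a2,a3}:1,{a1,a2,a3}:4]']
```

The two trees are four moves apart: the root drops to time 3 (creating a
unit edge), one NNI exchange rebuilds the cherry as {a2,a3}, and two length
moves settle the times at (1, 4).

The same from the shell:

```sh
$ dctspace distance "((a1:2,a2:2):2,a3:4);" "((a2:1,a3:1):3,a1:4);" --m 4
4
$ dctspace check --property diameter --n 3 --m 4
property  n  m  bfs  formula  radius  extremal_pair  ok
diameter  3  4  5    5        3       5              True
```

For two caterpillar trees the closed form replaces path construction:

```python
>>> T = d.caterpillar_ranked(["a5", "a4", "a3", "a2", "a1"])
>>> R = d.caterpillar_ranked(["a1", "a2", "a3", "a4", "a5"])
>>> P, M = d.transposition_sets(T, R)
>>> len(P), len(M), d.caterpillar_distance_fast(T, R)
(8, 2, 6)
```

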