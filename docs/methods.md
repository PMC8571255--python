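# Methods

## The spaces

A **discrete coalescent tree** on n leaves is a rooted binary tree with all
leaves at time 0 and distinct positive integer times on the n−1 internal
nodes, the root bounded by an integer m ≥ n−1. The space DCT_m has one
vertex per such tree and an edge for every single NNI, rank or length move
(definitions in the README and module docstrings). Setting m = n−1 leaves
no room for length moves and gives the RNNI graph of ranked trees. Counting
is exact: (n−1)!·n!/2^{n−1} ranked trees, times C(m, n−1) time assignments
for DCT_m; the enumeration module asserts both formulas on construction.

The canonical representation throughout is the rank-ordered cluster
sequence [C_1..C_{n−1}] plus the time sequence — not a pointer tree —
because every algorithm here manipulates clusters directly. Leaf labels are
mapped to integer indices on input; clusters are frozensets of indices.
Validation is a single bottom-up pass: each cluster must be the union of
exactly two current blocks, which enforces laminarity, binarity and the
root condition in O(Σ|C_i|) set operations.

Assumptions, and hence hard rejections: binary topology, simultaneous
(time-0) leaves, distinct integer internal times. Heterochronous tips,
sampled ancestors and non-binary nodes are out of scope.

## Shortest paths

**FindPath** (ranked trees). For each target rank i = 1..n−2 the mrca of
the i-th cluster of the destination is lowered one rank per move: a rank
swap when the node one rank below is not its child, otherwise the unique
NNI exchange on the unit edge that carries the mrca down. The path length
is the RNNI distance; every enumerated space we can afford (all pairs at
n = 4 and n = 5) confirms optimality against BFS.

**Extension.** A DCT bounded by m becomes a ranked tree on m+2 leaves: a
new root at time m+1 takes the original root and a caterpillar subtree on
fresh leaves whose internal nodes occupy exactly the unused time slots in
{1..m}. With m = n−1 the caterpillar part degenerates to a single leaf
under the new root. Distances are preserved by this map, and restriction
(keeping the clusters made purely of original leaves, with their ranks as
times) is its inverse; cluster preservation along FindPath guarantees the
restriction is well defined for every tree on a path between two extended
trees.

**FindPath⁺** (native DCT paths). Sweeping k = 1..m: if the destination has
a node at time k inducing cluster C, the mrca of C in the running tree is
lowered to time k — length move into an empty slot, rank move past an
unrelated occupant, NNI move past a child. If instead the *running* tree
occupies slot k that the destination leaves empty, the contiguous block of
occupied slots k..i−1 (i the lowest free slot above k) shifts up by one,
applied top-down so each move lands in a free slot; if neither tree uses
slot k nothing happens. The no-op case and the top-down order are design
choices fixed by the requirement that the native path coincide pointwise
with restrict∘FindPath on the extended trees — an equality the test suite
asserts tree by tree, alongside length-equality with BFS. The distance is
independent of m beyond the maximum root time, so `m` defaults to that.

Move uniqueness in the NNI-lowering step: of the two exchanges across the
unit edge, exactly one places the mrca one step lower (the child block
containing the target's intersection is kept); the implementation asserts
this uniqueness instead of assuming it.

## Caterpillar distance

Caterpillar trees (every internal node has a leaf child) are closed under
some shortest path — the convexity checker verifies this exhaustively — so
their distance reduces to a permutation statistic on leaf orders:
d = |P| − |M|, with P the strictly discordant leaf pairs (cherry-internal
pairs are rank-tied and never counted) and M the leaves all of whose
T-predecessors sit strictly above them in R, provided no R-cherry leaf lies
at or below them in T. The "every other leaf" quantifier excludes the leaf
itself; this matters only inside T's cherry and is pinned by the worked
five-leaf example (|P| = 8, |M| = 2, d = 6).

The fast route counts strict inversions of R-ranks along T's order by merge
sort (O(n log n); the asymptotically faster counting structures in the
literature are deliberately not reproduced — same output, simpler code) and
computes M in one linear scan with a running minimum. The cherry
ambiguities are resolved by ordering T's cherry so it contributes no
inversion; R's cherry is a tie and never counts.

The same problem is an instance of token swapping on a lollipop graph
(triangle joined to a path): vertices are R's leaf positions, the token on
position i wants the vertex holding T's i-th leaf. Because a caterpillar
has two list representations, the goal tree corresponds to *two* token
configurations differing by the cherry transposition; the exact BFS solver
accepts either, and the placement rule puts a token whose goal is an
R-cherry vertex onto that vertex. With these two conventions the BFS
optimum equals the RNNI distance on every instance small enough to
enumerate (all caterpillar pairs at n = 4, plus the worked n = 5 example).

## Exhaustive oracle and theorem checkers

The move graph is materialised with networkx for spaces up to a vertex
budget (default 5,000 vertices); BFS supplies distances, eccentricities,
diameter, radius and all geodesics (geodesic enumeration capped at 10⁶
paths). The checkers verify, with zero tolerated violations:

* **cluster property** — every geodesic between trees sharing a non-trivial
  cluster contains it (RNNI n = 4; DCT n = 3, m = 4);
* **convexity** of the caterpillar set — restricted BFS distance equals
  unrestricted (RNNI n ≤ 5);
* **diameter/radius** — BFS diameter equals (n−1)(n−2)/2 in RNNI
  (n = 3,4,5, where radius = diameter) and
  (n−1)(n−2)/2 + (m−n+1)(n−1) in DCT_m ((3,4) and (4,5)); in DCT_4 on three
  leaves the radius (3 by BFS) is strictly below the diameter 5.

The extremal caterpillar pair for the DCT diameter (ascending caterpillar
occupying the top n−1 slots vs descending caterpillar at times 1..n−1) is
*reported* alongside the BFS value rather than asserted as the unique
maximiser, because the printed specification of the ascending tree's times
is ambiguous; BFS settles the diameter unambiguously and the pair attains
it in every space checked.

**Negative control.** The cluster-property checker is itself tested by
mutation: admitting NNI exchanges across edges of length two (keeping only
exchanges that still yield valid trees) must produce violations. The
corruption only bites where non-trivial clusters and spare time slots
coexist — DCT n = 4, m = 5 — and there it does; in DCT n = 3 every
cross-cherry detour stays strictly longer, and in pure RNNI at n ≤ 5 the
few valid long-edge exchanges do not shorten any within-class path, so
those spaces stay clean even under the corrupted move set.

## Random generation

`random_ranked_tree` merges a uniformly chosen pair of lineages per rank,
which is the uniform distribution over ranked topologies (labelled
histories); `random_dct` adds a uniform (n−1)-subset of {1..m} as times.
These generators exist to drive property tests (uniformity is itself
tested at n = 3 and n = 4 with 3σ bands) and the acceptance script's
extension example; they emulate only the combinatorial null model, not any
biological signal — passing tests say nothing about fit to real
posteriors.

## Numerical and tie-breaking choices

* Newick parsing tolerates floating-point branch lengths within 1e−9 of an
  integer; everything else about times is exact integer arithmetic.
* Cluster strings list leaves in index order; neighbourhoods and
  enumerations are returned in canonical serialization order, so all
  outputs are byte-reproducible.
* Equality of trees ignores the bound m (it is metadata about the ambient
  space, not the tree).
* Problem sizes in the test suite — all pairs at n ≤ 5 for ranked trees,
  (n,m) = (3,4) and (4,5) for DCT, caterpillar exhaustion at n ≤ 6 with
  1,000 seeded pairs at n = 200 — are chosen as the largest spaces where
  the brute-force oracle is exact and cheap; the algorithms themselves
  carry no such limits.

## Known limitations

* The exhaustive module is an oracle, not a production tool: spaces beyond
  the vertex budget raise instead of thrashing.
* The token-swapping converter builds instances; solving them exactly is
  BFS over configurations and only intended for small n (an optimal
  polynomial solver for lollipop instances is out of scope).
* Weighted variants of the moves and continuous-time tree spaces are not
  modelled; discretising continuous time trees before measuring distances
  is the caller's responsibility.
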