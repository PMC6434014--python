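# Methods

## Problem and model

Given a set *S* of *n* genomic intervals on one chromosome and a query
interval *q* = [x′, y′], an **interval query** asks for every *a* ∈ *S*
standing in a chosen Allen relation *r* to *q*. Allen's interval algebra
partitions ordered interval pairs into 13 mutually exclusive, jointly
exhaustive relations — overlaps (o), overlapped-by (oi), during (d),
contains (di), meets (m), met-by (mi), starts (s), started-by (si),
finishes (f), finished-by (fi), before (<), after (>), equals (=) — each an
ordering of the four endpoints. Eleven of them imply closed-interval
intersection (`a.start ≤ q.end and a.end ≥ q.start`); < and > are the two
disjoint cases.

The engine's central device is **query rewriting**: identify interval
[x, y] with the 2-D point (x, y). Every relation's endpoint ordering then
becomes membership in an axis-aligned rectangle determined by (r, q). For
example *a d q* (x′ < x < y < y′) becomes x ∈ (x′, y′), y ∈ (x′, y′);
*a si q* becomes x = x′, y ∈ (y′, ∞). An interval query is thereby a 2-D
orthogonal range-reporting query, answered by any range structure — and all
structures necessarily agree, because the rewriting is proven sound
(classify(a,q) = r ⟺ (a.start, a.end) ∈ rewrite(r, q), tested exhaustively
on all pairs with endpoints in {0..6}).

Since all coordinates are integers, strict inequalities are represented as
**open integer bounds** rather than half-integer endpoints (a d query on
[2, 10] admits the open box (2, 10)², the same lattice set as a closed
query on [2.5, 9.5]); equalities are closed degenerate bounds. This keeps
arithmetic exact. One deliberate deviation from the usual presentation:
the unconstrained start side of o/di/m/fi/< is left unbounded below rather
than "0 < x", because position 0 is a legal genomic coordinate and a strict
positive bound would silently drop start-0 intervals.

## Index structures

**RTFC (primary).** A static balanced tree over starts; leaves hold the
intervals in (start, index) order; an internal node's `x_key` is the largest
start in its left subtree (equal to the ≤-median start under the split rule
below). Each node stores its subtree's intervals as parallel arrays sorted
by (end, index), plus two fractional-cascading index arrays giving, for each
position of the node's array, the position of the smallest not-smaller end
value in each child's array (−1 when none exists). A query finds the split
node where the two x-descent paths diverge, performs **one** binary search
for the lower end bound there, and thereafter propagates the array position
in O(1) per node through the FC arrays; each canonical subtree reports a
contiguous run of its end-sorted array cut off by the upper end bound.
Cost: O(log n + k).

**2D-RT (baseline).** The same x-tree shape, but each node carries a 1-D
structure over its subtree's end values (a static balanced search tree
flattened to a sorted array — the flattening preserves the two-endpoint-
searches-plus-linear-reporting contract and simplifies serialization). Each
canonical subtree pays its own O(log m) search: O(log² n + k) per query.

**IT (baseline).** A red-black tree keyed by (start, end, index), augmented
with each subtree's maximum end so subtrees with `max_end < q.start` are
pruned. Intersection reporting is O(log n + m); a refined relation is
answered by post-filtering the m overlap candidates with the shared
classifier — by construction it cannot disagree with the range trees on
relation semantics, and by construction it inspects ≈ 2m candidates when
only k ≪ m satisfy the refined relation (the instrumentation reports
exactly 200% of m on the dense-overlap fixture). Before/after queries use
ordered traversals that report whole pruned subtrees. Insert-only; the
invariant checker verifies red-black coloring, black height, key order,
max_end freshness and size after arbitrary insertion sequences.

## Numerical and structural choices

- **Split rule.** All elements with start equal to the median start go left;
  if that empties the right side (all starts equal), fall back to a rank
  split with the first ⌈n/2⌉ on the left. Both recursive subproblems are
  always strictly smaller. Under this rule the left subtree's maximum start
  always equals the median, so the two natural keying conventions coincide.
- **Duplicate handling.** Ties everywhere — leaf order, end-sorted arrays,
  red-black keys — are broken by the interval's provenance index, fixed at
  ingest. Structures are therefore fully deterministic, duplicates of equal
  coordinates are each reported exactly once per query, and results compare
  exactly across structures as index sets.
- **Descent with duplicates.** The lower-x path turns left iff the lower
  bound admits `x_key`; the upper-x path turns right iff the upper bound
  admits `x_key`. Because duplicates of a split key may occupy the right
  subtree, a closed degenerate range [c, c] diverges at the internal node
  keyed c (not at a leaf) whenever such a node exists; both slivers are then
  walked. Degenerate-start queries (s, si, =) consequently reduce to binary
  search plus short reporting runs.
- **FC sentinel discipline.** FC entries equal to −1 mean "no successor";
  once a cascade cursor hits −1 the entire remaining subtree fails the lower
  end bound and the descent stops reporting. A lower-bound search that falls
  off the end of the split node's array terminates the query immediately.
- **Empty/invalid input.** Range-tree builders reject empty sets (callers
  represent empty chromosomes as absent indexes); the interval tree accepts
  an empty build. Intervals with start ≥ end are rejected at ingest with a
  logged drop counter — such records carry no valid point above y = x.

## BED semantics

Raw `chromStart`/`chromEnd` values are used verbatim as closed endpoints
[start, end]. An optional `--half-open` ingest flag converts conventional
0-based half-open records [s, e) to [s, e−1] for users wanting strict BED
semantics. Duplicated records across pooled files are kept by default
(each copy independently queryable); `--dedup` removes exact
(chrom, start, end) duplicates. Chromosome names are matched as exact
strings; query chromosomes absent from an index produce a warning and zero
results. Full < and > queries are supported directly (half-unbounded
boxes); the `flank` command provides the practical alternative — a d query
against the window [x′−l, x′] (upstream, floored at 0) or [y′, y′+l]
(downstream) — which is what promoter-style "within l bases" searches mean.

## Synthetic data: what it covers and what it does not

`generate_uniform(n, coord_max, seed)` draws both endpoints uniformly on
{0..coord_max−1}, redrawing equal pairs, and orders them; pooling-induced
duplication is emulated by `add_duplicates`, which re-indexes coordinate
copies. The adversarial suite covers the structural corner cases: all
intervals identical, shared starts, shared ends, a 50-deep nested chain,
an abutting chain rich in m/mi pairs, and a synthetic 8-interval
"cascade_demo8" set whose d query against [2, 10] returns exactly 4 hits
with the split node at the root. Uniform endpoint draws produce length
distributions (mean ≈ coord_max/3) unlike real chromatin features, and no
clustering along the chromosome; passing tests therefore demonstrate
*correctness* of the index structures on duplicate-heavy, degenerate and
random inputs, not performance on realistically skewed genomic length or
density profiles. Wall-clock performance claims are out of scope
throughout; complexity assertions are made on instrumented node-visit
counts, which are hardware-independent.

## Verification design

Ground truth is always the brute-force oracle (linear scan with the
classifier, or direct point-in-box membership); the two oracles are
cross-checked against each other on rewritten boxes. The randomized
acceptance sweep runs 200 seeded instances (n ∈ {16..2048}, coordinate
universes {100, 1000, 10000} to vary density, 10% duplicates) and compares
all three structures to the oracle for all 13 relations; exhaustive sweeps
at small coordinate universes cover every (S, q, r) combination. FC
correctness is checked by comparing every cascaded position in a 4096-leaf
tree against an independent binary search in the child array for 100
probes. Empty-result visit counts are bounded by 8·(log₂ n + 1) for RTFC
and 8·(log₂ n)² for 2D-RT across n = 2⁸..2¹⁴ (observed constants ≈ 1.1 and
≈ 0.14·log² respectively — the bound is generous). These problem sizes keep
the whole suite under a minute while exercising every code path; scaling
them up changes nothing structural.

## Known limitations

- Static indexes: no insertion/deletion after build (the interval tree
  supports insertion but the CLI treats all three as build-once).
- One chromosome per tree; cross-chromosome queries are a routing concern
  of the CLI layer.
- The JSON index archive stores the full node layout (O(n log n) integers
  for the range trees); for very large chromosomes rebuilding from BED can
  be cheaper than loading, and a compact format would be the first
  engineering improvement.
- Strand-aware filtering and d > 2 dimensional range trees are out of scope.
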