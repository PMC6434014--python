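# allenrange

Efficient genomic interval queries for **all 13 Allen relations**, not just
"overlaps".

Annotating variants and features means asking questions like *which
regulatory elements lie strictly inside this deletion?*, *which peaks share
this exon's start?*, *which elements abut this interval end-to-start?*
These are refined relations from Allen's interval algebra — during (`d`),
starts (`s`), meets (`m`), and ten more — and conventional interval-tree
tooling answers them by fetching all *m* overlapping intervals and
filtering, paying O(log n + m) even when only k ≪ m intervals qualify.

`allenrange` instead **rewrites each relation query as a 2-D range query**:
an interval [x, y] is the point (x, y), and "all a with *a r q*" is exactly
"all points in an axis-aligned rectangle determined by (r, q)". For
q = [x′, y′]:

| r | definition | rewritten box |
|---|------------|----------------|
| `o` | x < x′ < y < y′ | x ∈ (−∞, x′), y ∈ (x′, y′) |
| `d` | x′ < x < y < y′ | x ∈ (x′, y′), y ∈ (x′, y′) |
| `s` | x = x′ < y < y′ | x = x′, y ∈ (x′, y′) |
| `=` | x = x′, y = y′ | x = x′, y = y′ |
| … | (all 13 supported) | … |

The rectangle is answered by a **range tree with fractional cascading
(RTFC)** in O(log n + k): one binary search for the lower end-bound at the
split node, then constant-time index propagation down both descent paths.
Two interchangeable baselines ship alongside it — a basic 2-D range tree
(O(log² n + k)) and an augmented red-black interval tree (O(log n + 2m)
for refined relations) — all three verified query-by-query against a
brute-force oracle.

## Worked example

Eight annotated elements, one query variant [2, 10]:

```sh
$ cat elements.bed
chr1	0	4
chr1	3	6
chr1	4	7
chr1	5	9
chr1	6	12
chr1	7	9
chr1	8	13
chr1	10	14

$ allenrange build elements.bed --structure rtfc -o elements.idx.json
$ printf 'chr1\t2\t10\n' > variants.bed
$ allenrange query elements.idx.json variants.bed --relation d
chr1	2	10	d	chr1	3	6	1
chr1	2	10	d	chr1	4	7	2
chr1	2	10	d	chr1	5	9	3
chr1	2	10	d	chr1	7	9	5
```

Exactly the four elements strictly inside (2, 10) on both ends: [3,6],
[4,7], [5,9], [7,9]. [0,4] only overlaps from the front, [6,12] and [8,13]
hang out past 10, and the boundary-touching [10,14] is met-by, not during.
Columns are query chrom/start/end, refined relation, data chrom/start/end,
and the data interval's provenance index.

Coarse queries report every intersecting element tagged with its refined
relation:

```sh
$ allenrange query elements.idx.json variants.bed --coarse any
chr1	2	10	o	chr1	0	4	0
chr1	2	10	d	chr1	3	6	1
...
chr1	2	10	mi	chr1	10	14	7
```

`allenrange compare` runs RTFC, the 2-D range tree, the interval tree *and*
the oracle on the same inputs and verifies total agreement (exit status 3
on any discrepancy):

```sh
$ allenrange compare elements.bed variants.bed
all structures agree with the oracle on 13 (query, relation) instances
relation	hits	rtfc_visits	rt2d_visits	it_candidates
o	1	5	5	16
oi	2	5	12	16
...
```

Other commands: `allenrange flank` (before/after restricted to an
*l*-base window, the practical promoter-search form of `<`/`>`) and
`allenrange bench` (informational timings). BED records are ingested with
raw chromStart/chromEnd as closed endpoints by default; `--half-open`
converts strict BED semantics, `--dedup` collapses pooled duplicates.

## Library use

```python
from allenrange import GenomicInterval, AllenRelation, build_rtfc, query_rtfc

S = [GenomicInterval("chr1", s, e, i) for i, (s, e) in
     enumerate([(0, 4), (3, 6), (4, 7), (5, 9)])]
root = build_rtfc(S)
query_rtfc(root, GenomicInterval("chr1", 2, 10), AllenRelation.DURING)
# {1, 2, 3}
```

See `docs/methods.md` for the model, tie-breaking and duplicate-handling
rules, and the verification design.

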