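"""Range tree with fractional cascading (RTFC) for 2-D interval range reporting.

The primary index structure: a balanced binary tree over the start
coordinates of the intervals, whose leaves hold the intervals in start order.
Every internal node ``v`` stores the intervals of its subtree as an array
sorted by end coordinate, together with two *FC-index* arrays mapping each
position of that array to the position of the smallest not-smaller end value
in the left and right child arrays.  A 2-D query then needs a single binary
search for the lower end-bound at the split node; the position is propagated
in constant time down both descent paths (fractional cascading), so reporting
costs ``O(log n + k)`` instead of the ``O(log² n + k)`` of a basic
2-dimensional range tree.

The tree is static: build once, query many.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .allen_core import (
    AllenRelation,
    Bound,
    GenomicInterval,
    RangeBox,
    rewrite,
)

__all__ = [
    "FCIndex",
    "RTFCNode",
    "make_fc_index",
    "build_rtfc",
    "find_split_node",
    "query_rtfc",
    "query_rtfc_box",
    "visit_count",
]

_NO_SUCCESSOR = -1  # FC sentinel: no element in the child array is >= this one


@dataclass(frozen=True)
class FCIndex:
    """Indexing array from a sorted parent array A1 into a sorted child array A2.

    ``entries[i]`` is the position in A2 of the smallest element no less than
    ``A1[i]``, or ``-1`` when every element of A2 is smaller.
    """

    entries: tuple[int, ...]

    def __getitem__(self, i: int) -> int:
        return self.entries[i]

    def __len__(self) -> int:
        return len(self.entries)


def _fc_entries(parent_ys: Sequence[int], child_ys: Sequence[int]) -> list[int]:
    """Two-pointer merge computing the FC entries; both inputs sorted ascending."""
    entries: list[int] = []
    j = 0
    m = len(child_ys)
    for y in parent_ys:
        while j < m and child_ys[j] < y:
            j += 1
        entries.append(j if j < m else _NO_SUCCESSOR)
    return entries


def make_fc_index(A1: Sequence[int], A2: Sequence[int]) -> FCIndex:
    """Build the FC-index from sorted array ``A1`` to sorted array ``A2 ⊆ A1``.

    Raises ``ValueError`` if either input is not sorted ascending.
    """
    for name, arr in (("A1", A1), ("A2", A2)):
        if any(arr[i] > arr[i + 1] for i in range(len(arr) - 1)):
            raise ValueError(f"{name} must be sorted ascending")
    return FCIndex(tuple(_fc_entries(A1, A2)))


class RTFCNode:
    """One node of the RTFC.

    ``x_key`` is the split key — the largest start coordinate in the left
    subtree (equal to the ≤-median start used to split).  ``ys``/``idx`` hold
    the subtree's intervals sorted by ``(end, index)``: end values and
    provenance indices in parallel arrays.  ``lfc``/``rfc`` are FC entries
    (plain lists, with ``-1`` as the no-successor sentinel) into the child
    arrays.  A leaf stores its single interval in ``interval``.
    """

    __slots__ = (
        "x_key",
        "ys",
        "idx",
        "lfc",
        "rfc",
        "lchild",
        "rchild",
        "interval",
        "last_visit_count",
    )

    def __init__(
        self,
        x_key: int,
        ys: list[int],
        idx: list[int],
        lfc: Optional[list[int]] = None,
        rfc: Optional[list[int]] = None,
        lchild: Optional["RTFCNode"] = None,
        rchild: Optional["RTFCNode"] = None,
        interval: Optional[GenomicInterval] = None,
    ) -> None:
        self.x_key = x_key
        self.ys = ys
        self.idx = idx
        self.lfc = lfc
        self.rfc = rfc
        self.lchild = lchild
        self.rchild = rchild
        self.interval = interval
        self.last_visit_count = 0

    @property
    def is_leaf(self) -> bool:
        return self.interval is not None

    @property
    def size(self) -> int:
        return len(self.ys)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "node"
        return f"<RTFC {kind} x_key={self.x_key} size={self.size}>"


def _split_point(pts: Sequence[GenomicInterval]) -> int:
    """Index k so that ``pts[:k]`` / ``pts[k:]`` is the build split.

    ``pts`` is sorted by ``(start, index)``.  All elements with start equal to
    the median start go left; if that would leave the right side empty (every
    start equal), fall back to a rank split with the first ⌈n/2⌉ on the left,
    which keeps both recursive subproblems strictly smaller.
    """
    n = len(pts)
    x_mid = pts[(n - 1) // 2].start
    k = (n - 1) // 2 + 1
    while k < n and pts[k].start == x_mid:
        k += 1
    if k == n:  # all starts equal x_mid
        k = (n + 1) // 2
    return k


def _merge_by_y(
    lys: list[int], lidx: list[int], rys: list[int], ridx: list[int]
) -> tuple[list[int], list[int]]:
    """Merge two (end, index)-sorted parallel arrays."""
    ys: list[int] = []
    idx: list[int] = []
    i = j = 0
    nl, nr = len(lys), len(rys)
    while i < nl and j < nr:
        if (lys[i], lidx[i]) <= (rys[j], ridx[j]):
            ys.append(lys[i])
            idx.append(lidx[i])
            i += 1
        else:
            ys.append(rys[j])
            idx.append(ridx[j])
            j += 1
    ys.extend(lys[i:])
    idx.extend(lidx[i:])
    ys.extend(rys[j:])
    idx.extend(ridx[j:])
    return ys, idx


def _build(pts: Sequence[GenomicInterval]) -> RTFCNode:
    if len(pts) == 1:
        a = pts[0]
        return RTFCNode(x_key=a.start, ys=[a.end], idx=[a.index], interval=a)
    k = _split_point(pts)
    left = _build(pts[:k])
    right = _build(pts[k:])
    ys, idx = _merge_by_y(left.ys, left.idx, right.ys, right.idx)
    return RTFCNode(
        x_key=pts[k - 1].start,  # max start in the left subtree
        ys=ys,
        idx=idx,
        lfc=_fc_entries(ys, left.ys),
        rfc=_fc_entries(ys, right.ys),
        lchild=left,
        rchild=right,
    )


def build_rtfc(S: Sequence[GenomicInterval]) -> RTFCNode:
    """Build an RTFC over a non-empty interval set on one chromosome.

    Leaves read left to right are ``S`` sorted by ``(start, index)``; every
    internal node's data array is the ``(end, index)``-sorted merge of its
    children's arrays.  Ties are broken by provenance index throughout, so
    the structure (and therefore every query answer) is deterministic.
    """
    if not S:
        raise ValueError("cannot build an index over an empty interval set")
    chroms = {a.chrom for a in S}
    if len(chroms) > 1:
        raise ValueError(
            f"interval set spans multiple chromosomes: {sorted(chroms)}; "
            "build one index per chromosome"
        )
    pts = sorted(S, key=lambda a: (a.start, a.index))
    return _build(pts)


def _descend_dirs(node, x_low: Bound, x_high: Bound) -> tuple[bool, bool]:
    """(go-left for the lower path, go-right for the upper path) at ``node``.

    The lower-bound path goes left iff the left subtree (starts ≤ x_key) can
    still contain admitted starts; the upper-bound path goes right iff the
    right subtree (starts ≥ x_key under duplicate starts) can.
    """
    return x_low.admits_above(node.x_key), x_high.admits_below(node.x_key)


def find_split_node(root, x_low: Bound, x_high: Bound):
    """Deepest node where the descent paths for the two x-bounds diverge.

    Returns the leaf where both paths end when they never diverge (e.g. the
    degenerate ``x = x'`` queries of the s/si/= relations on duplicate-free
    starts).  Works for any node type exposing ``x_key``/``lchild``/``rchild``
    /``is_leaf``, so the basic 2-D range tree shares it.
    """
    v = root
    while not v.is_leaf:
        lo_left, hi_right = _descend_dirs(v, x_low, x_high)
        if lo_left and not hi_right:
            v = v.lchild
        elif not lo_left and hi_right:
            v = v.rchild
        else:
            break
    return v


def _lower_pos(ys: Sequence[int], y_low: Bound) -> int:
    """Position of the smallest element of ``ys`` admitted by the lower bound."""
    if y_low.unbounded:
        return 0
    if y_low.closed:
        return bisect_left(ys, y_low.value)
    return bisect_right(ys, y_low.value)


def query_rtfc_box(root: RTFCNode, box: RangeBox) -> set[int]:
    """Report the provenance indices of all points inside ``box``.

    One binary search for the lower y-bound at the split node; the resulting
    array position is cascaded through the FC-index arrays along both x-descent
    paths, and each canonical subtree reports a contiguous run of its y-sorted
    array terminated by the upper y-bound.
    """
    x_low, x_high = box.x_low, box.x_high
    y_low, y_high = box.y_low, box.y_high
    out: set[int] = set()
    visits = 1
    v = root
    while not v.is_leaf:
        lo_left, hi_right = _descend_dirs(v, x_low, x_high)
        if lo_left and not hi_right:
            v = v.lchild
        elif not lo_left and hi_right:
            v = v.rchild
        else:
            break
        visits += 1
    split = v
    if split.is_leaf:
        if box.contains_interval(split.interval):
            out.add(split.interval.index)
        root.last_visit_count = visits
        return out
    lo_left, hi_right = _descend_dirs(split, x_low, x_high)
    if not (lo_left and hi_right):
        # the admitted x-range falls between the two subtrees: nothing matches
        root.last_visit_count = visits
        return out
    i0 = _lower_pos(split.ys, y_low)
    if i0 >= len(split.ys):
        # no end value in this subtree satisfies the lower y-bound
        root.last_visit_count = visits
        return out

    # Lower x-bound path: whenever it turns left, the right sibling subtree
    # lies entirely inside the x-range; report its y-run via the cascade.
    v = split.lchild
    i = split.lfc[i0]
    visits += 1
    while not v.is_leaf and i != _NO_SUCCESSOR:
        if x_low.admits_above(v.x_key):
            j = v.rfc[i]
            rys = v.rchild.ys
            ridx = v.rchild.idx
            m = len(rys)
            while j != _NO_SUCCESSOR and j < m and y_high.admits_below(rys[j]):
                out.add(ridx[j])
                j += 1
            i = v.lfc[i]
            v = v.lchild
        else:
            i = v.rfc[i]
            v = v.rchild
        visits += 1
    if v.is_leaf and i != _NO_SUCCESSOR and box.contains_interval(v.interval):
        out.add(v.interval.index)

    # Upper x-bound path, mirrored: left siblings of right turns are reported.
    v = split.rchild
    i = split.rfc[i0]
    visits += 1
    while not v.is_leaf and i != _NO_SUCCESSOR:
        if x_high.admits_below(v.x_key):
            j = v.lfc[i]
            lys = v.lchild.ys
            lidx = v.lchild.idx
            m = len(lys)
            while j != _NO_SUCCESSOR and j < m and y_high.admits_below(lys[j]):
                out.add(lidx[j])
                j += 1
            i = v.rfc[i]
            v = v.rchild
        else:
            i = v.lfc[i]
            v = v.lchild
        visits += 1
    if v.is_leaf and i != _NO_SUCCESSOR and box.contains_interval(v.interval):
        out.add(v.interval.index)

    root.last_visit_count = visits
    return out


def query_rtfc(root: RTFCNode, q: GenomicInterval, r: AllenRelation) -> set[int]:
    """All indices of data intervals ``a`` in the tree with ``a r q``."""
    return query_rtfc_box(root, rewrite(r, q))


def visit_count(root: RTFCNode) -> int:
    """Tree nodes touched by the most recent query, excluding reporting steps."""
    return root.last_visit_count
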