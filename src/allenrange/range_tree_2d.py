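"""Basic 2-dimensional range tree (2D-RT) baseline.

Same x-tree shape as the fractionally cascaded variant, but instead of FC
arrays every node carries a one-dimensional search structure over the end
coordinates of its subtree.  Each canonical subtree of the x-decomposition
then answers the y-constraint with its own binary searches, giving
``O(log² n + k)`` per query.  The y-structures are static balanced search
trees flattened to sorted arrays; the query contract (two O(log m) endpoint
searches plus linear reporting) is unchanged by the flattening.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Optional, Sequence

from .allen_core import AllenRelation, Bound, GenomicInterval, RangeBox, rewrite
from .rtfc import _descend_dirs, _split_point, _merge_by_y

__all__ = [
    "YTree",
    "RT2DNode",
    "build_2d_rt",
    "query_1d",
    "query_2d_rt",
    "query_2d_rt_box",
    "visit_count",
]


class YTree:
    """1-D range structure over end values: parallel (end, index)-sorted arrays."""

    __slots__ = ("ys", "idx")

    def __init__(self, ys: list[int], idx: list[int]) -> None:
        self.ys = ys
        self.idx = idx

    def __len__(self) -> int:
        return len(self.ys)


def query_1d(ytree: YTree, y_low: Bound, y_high: Bound) -> set[int]:
    """All indices whose end value lies between the two bounds."""
    lo, hi = _range_positions(ytree.ys, y_low, y_high)
    return set(ytree.idx[lo:hi])


def _range_positions(ys: Sequence[int], y_low: Bound, y_high: Bound) -> tuple[int, int]:
    if y_low.unbounded:
        lo = 0
    elif y_low.closed:
        lo = bisect_left(ys, y_low.value)
    else:
        lo = bisect_right(ys, y_low.value)
    if y_high.unbounded:
        hi = len(ys)
    elif y_high.closed:
        hi = bisect_right(ys, y_high.value)
    else:
        hi = bisect_left(ys, y_high.value)
    return lo, max(lo, hi)


class RT2DNode:
    """x-tree node of the basic 2-D range tree.

    ``x_key`` is the largest start in the left subtree; ``ytree`` indexes the
    end values of every interval below this node; leaves store their interval.
    """

    __slots__ = ("x_key", "ytree", "lchild", "rchild", "interval", "last_visit_count")

    def __init__(
        self,
        x_key: int,
        ytree: YTree,
        lchild: Optional["RT2DNode"] = None,
        rchild: Optional["RT2DNode"] = None,
        interval: Optional[GenomicInterval] = None,
    ) -> None:
        self.x_key = x_key
        self.ytree = ytree
        self.lchild = lchild
        self.rchild = rchild
        self.interval = interval
        self.last_visit_count = 0

    @property
    def is_leaf(self) -> bool:
        return self.interval is not None

    @property
    def size(self) -> int:
        return len(self.ytree)


def _build(pts: Sequence[GenomicInterval]) -> RT2DNode:
    if len(pts) == 1:
        a = pts[0]
        return RT2DNode(x_key=a.start, ytree=YTree([a.end], [a.index]), interval=a)
    k = _split_point(pts)
    left = _build(pts[:k])
    right = _build(pts[k:])
    ys, idx = _merge_by_y(left.ytree.ys, left.ytree.idx, right.ytree.ys, right.ytree.idx)
    return RT2DNode(
        x_key=pts[k - 1].start, ytree=YTree(ys, idx), lchild=left, rchild=right
    )


def build_2d_rt(S: Sequence[GenomicInterval]) -> RT2DNode:
    """Build the 2D-RT; same split rule and tie-breaks as the RTFC builder."""
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


def _search_cost(m: int) -> int:
    """Nodes a balanced 1-D search over m elements would touch (binary-search depth)."""
    return max(1, m.bit_length())


def query_2d_rt_box(root: RT2DNode, box: RangeBox) -> set[int]:
    """Canonical-subtree decomposition on x, then a 1-D y-query per canonical node."""
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
        root.last_visit_count = visits
        return out

    v = split.lchild
    visits += 1
    while not v.is_leaf:
        if x_low.admits_above(v.x_key):
            visits += _search_cost(len(v.rchild.ytree))
            out |= query_1d(v.rchild.ytree, y_low, y_high)
            v = v.lchild
        else:
            v = v.rchild
        visits += 1
    if box.contains_interval(v.interval):
        out.add(v.interval.index)

    v = split.rchild
    visits += 1
    while not v.is_leaf:
        if x_high.admits_below(v.x_key):
            visits += _search_cost(len(v.lchild.ytree))
            out |= query_1d(v.lchild.ytree, y_low, y_high)
            v = v.rchild
        else:
            v = v.lchild
        visits += 1
    if box.contains_interval(v.interval):
        out.add(v.interval.index)

    root.last_visit_count = visits
    return out


def query_2d_rt(root: RT2DNode, q: GenomicInterval, r: AllenRelation) -> set[int]:
    """All indices of data intervals ``a`` in the tree with ``a r q``."""
    return query_2d_rt_box(root, rewrite(r, q))


def visit_count(root: RT2DNode) -> int:
    """Nodes touched by the last query, counting 1-D search depth, excluding reporting."""
    return root.last_visit_count
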