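"""Brute-force reference implementations defining ground truth for every query.

These linear scans are deliberately naive — O(n) per query — and serve as the
oracles against which the tree structures are verified.  They return *index
sets*, not interval copies, so duplicated coordinates (common when pooling
many BED files) compare exactly across structures.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .allen_core import AllenRelation, GenomicInterval, RangeBox, classify

__all__ = ["brute_interval_query", "brute_range_report", "brute_overlap_query"]


def brute_interval_query(
    S: Sequence[GenomicInterval], q: GenomicInterval, r: AllenRelation
) -> set[int]:
    """Indices of all intervals ``a`` in ``S`` with ``a r q``, by linear scan."""
    return {a.index for a in S if classify(a, q) is r}


def brute_range_report(S: Sequence[GenomicInterval], box: RangeBox) -> set[int]:
    """Indices of intervals whose point ``(start, end)`` lies in ``box``."""
    return {a.index for a in S if box.contains(a.start, a.end)}


def brute_overlap_query(S: Sequence[GenomicInterval], q: GenomicInterval) -> set[int]:
    """Indices of intervals intersecting ``q`` under the closed-interval test."""
    return {a.index for a in S if a.start <= q.end and a.end >= q.start}
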