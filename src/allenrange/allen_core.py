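"""Allen's interval algebra over genomic intervals, and its range-query rewriting.

A genomic interval ``[x, y]`` (closed, integer endpoints, ``x < y``) can be
identified with the 2-D point ``(x, y)``.  Each of Allen's 13 qualitative
relations between a data interval ``a = [x, y]`` and a query interval
``q = [x', y']`` is an ordering of the four endpoints, and therefore the set
of data intervals standing in relation ``r`` to ``q`` is exactly the set of
points inside an axis-aligned rectangle determined by ``(r, q)``.  This module
defines the interval and relation types, the pairwise classifier, and the
rewriting of ``(r, q)`` into a :class:`RangeBox`.

Strict inequalities become *open* bounds and equalities become *closed*
degenerate bounds, so that on integer coordinates the admitted point set is
exact without resorting to half-integer endpoints such as 2.5/9.5.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "GenomicInterval",
    "AllenRelation",
    "Bound",
    "RangeBox",
    "INTERSECTING",
    "COARSE_TYPES",
    "ChromosomeMismatchError",
    "classify",
    "rewrite",
    "relation_holds",
    "coarse_relation_set",
]


class ChromosomeMismatchError(ValueError):
    """Raised when two intervals on different chromosomes are compared."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A closed integer interval ``[start, end]`` on a chromosome.

    ``index`` is a stable provenance id within its data set; it is what the
    index structures report, so duplicated coordinates remain distinguishable.
    """

    chrom: str
    start: int
    end: int
    index: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}]: start must be < end"
            )
        if self.index < 0:
            raise ValueError("provenance index must be non-negative")

    @property
    def point(self) -> tuple[int, int]:
        """The associated 2-D point ``(start, end)``; always above ``y = x``."""
        return (self.start, self.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:[{self.start},{self.end}]#{self.index}"


class AllenRelation(enum.Enum):
    """The 13 Allen relations, spelled with the conventional ASCII symbols."""

    OVERLAPS = "o"
    OVERLAPPED_BY = "oi"
    DURING = "d"
    CONTAINS = "di"
    MEETS = "m"
    MET_BY = "mi"
    STARTS = "s"
    STARTED_BY = "si"
    FINISHES = "f"
    FINISHED_BY = "fi"
    BEFORE = "<"
    AFTER = ">"
    EQUALS = "="

    @property
    def symbol(self) -> str:
        return self.value

    @classmethod
    def from_symbol(cls, symbol: str) -> "AllenRelation":
        """Parse a relation symbol; ``lt``/``gt``/``eq`` alias ``<``/``>``/``=``."""
        s = symbol.strip()
        s = _SYMBOL_ALIASES.get(s, s)
        try:
            return cls(s)
        except ValueError:
            raise ValueError(f"unknown Allen relation symbol: {symbol!r}") from None

    @property
    def converse(self) -> "AllenRelation":
        """The relation r⁻¹ with ``a r q  ⟺  q r⁻¹ a``."""
        return _CONVERSE[self]

    def __str__(self) -> str:
        return self.value


_SYMBOL_ALIASES = {"lt": "<", "gt": ">", "eq": "=", "e": "="}

_CONVERSE = {
    AllenRelation.OVERLAPS: AllenRelation.OVERLAPPED_BY,
    AllenRelation.OVERLAPPED_BY: AllenRelation.OVERLAPS,
    AllenRelation.DURING: AllenRelation.CONTAINS,
    AllenRelation.CONTAINS: AllenRelation.DURING,
    AllenRelation.MEETS: AllenRelation.MET_BY,
    AllenRelation.MET_BY: AllenRelation.MEETS,
    AllenRelation.STARTS: AllenRelation.STARTED_BY,
    AllenRelation.STARTED_BY: AllenRelation.STARTS,
    AllenRelation.FINISHES: AllenRelation.FINISHED_BY,
    AllenRelation.FINISHED_BY: AllenRelation.FINISHES,
    AllenRelation.BEFORE: AllenRelation.AFTER,
    AllenRelation.AFTER: AllenRelation.BEFORE,
    AllenRelation.EQUALS: AllenRelation.EQUALS,
}

#: The 11 relations implying a (closed-interval) intersection with the query.
INTERSECTING: frozenset[AllenRelation] = frozenset(
    {
        AllenRelation.OVERLAPS,
        AllenRelation.OVERLAPPED_BY,
        AllenRelation.DURING,
        AllenRelation.CONTAINS,
        AllenRelation.MEETS,
        AllenRelation.MET_BY,
        AllenRelation.STARTS,
        AllenRelation.STARTED_BY,
        AllenRelation.FINISHES,
        AllenRelation.FINISHED_BY,
        AllenRelation.EQUALS,
    }
)

#: Coarse query types (the findOverlaps vocabulary) and their refined relations.
COARSE_TYPES: dict[str, frozenset[AllenRelation]] = {
    "any": INTERSECTING,
    "within": frozenset(
        {
            AllenRelation.DURING,
            AllenRelation.STARTS,
            AllenRelation.FINISHES,
            AllenRelation.EQUALS,
        }
    ),
    "start": frozenset(
        {AllenRelation.STARTS, AllenRelation.STARTED_BY, AllenRelation.EQUALS}
    ),
    "end": frozenset(
        {AllenRelation.FINISHES, AllenRelation.FINISHED_BY, AllenRelation.EQUALS}
    ),
    "equal": frozenset({AllenRelation.EQUALS}),
}


def coarse_relation_set(coarse_type: str) -> frozenset[AllenRelation]:
    """Return the set of refined Allen relations making up a coarse query type.

    ``coarse_type`` must be one of ``any``, ``within``, ``start``, ``end``,
    ``equal``.
    """
    try:
        return COARSE_TYPES[coarse_type]
    except KeyError:
        raise ValueError(
            f"unknown coarse query type {coarse_type!r}; "
            f"expected one of {sorted(COARSE_TYPES)}"
        ) from None


def classify(a: GenomicInterval, q: GenomicInterval) -> AllenRelation:
    """Return the unique Allen relation ``r`` with ``a r q``.

    The 13 relations partition the space of ordered interval pairs, so exactly
    one symbol is returned for every valid pair on a common chromosome.
    """
    if a.chrom != q.chrom:
        raise ChromosomeMismatchError(
            f"cannot relate intervals on different chromosomes: "
            f"{a.chrom!r} vs {q.chrom!r}"
        )
    x, y = a.start, a.end
    xp, yp = q.start, q.end
    # Disjoint / touching cases first, then the overlap diamond.
    if y < xp:
        return AllenRelation.BEFORE
    if y == xp:
        return AllenRelation.MEETS
    if x > yp:
        return AllenRelation.AFTER
    if x == yp:
        return AllenRelation.MET_BY
    if x == xp:
        if y == yp:
            return AllenRelation.EQUALS
        return AllenRelation.STARTS if y < yp else AllenRelation.STARTED_BY
    if y == yp:
        return AllenRelation.FINISHES if x > xp else AllenRelation.FINISHED_BY
    if x < xp:
        return AllenRelation.OVERLAPS if y < yp else AllenRelation.CONTAINS
    return AllenRelation.DURING if y < yp else AllenRelation.OVERLAPPED_BY


_NEG_INF = -math.inf
_POS_INF = math.inf


@dataclass(frozen=True, slots=True)
class Bound:
    """One side of a range constraint: an extended-integer value plus openness.

    ``closed`` says whether the endpoint value itself is admitted.  Infinite
    values are always open.  Open integer bounds realize strict inequalities
    exactly: a d-query against ``[2, 10]`` admits integer coordinates in
    ``(2, 10)``, the same set a half-integer query ``[2.5, 9.5]`` would admit.
    """

    value: float  # an int, -inf, or +inf
    closed: bool = False

    def __post_init__(self) -> None:
        if math.isinf(self.value) and self.closed:
            raise ValueError("infinite bounds must be open")

    @classmethod
    def open_at(cls, value: int) -> "Bound":
        return cls(value, closed=False)

    @classmethod
    def closed_at(cls, value: int) -> "Bound":
        return cls(value, closed=True)

    @classmethod
    def neg_inf(cls) -> "Bound":
        return cls(_NEG_INF, closed=False)

    @classmethod
    def pos_inf(cls) -> "Bound":
        return cls(_POS_INF, closed=False)

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.value)

    def admits_above(self, t: float) -> bool:
        """True if ``t`` satisfies this bound used as a *lower* limit."""
        return t > self.value or (self.closed and t == self.value)

    def admits_below(self, t: float) -> bool:
        """True if ``t`` satisfies this bound used as an *upper* limit."""
        return t < self.value or (self.closed and t == self.value)


@dataclass(frozen=True, slots=True)
class RangeBox:
    """A 2-D axis-aligned query rectangle with independently open/closed sides.

    This is the rewritten form of an Allen query: interval ``a`` satisfies
    ``a r q`` iff the point ``(a.start, a.end)`` lies in ``rewrite(r, q)``.
    """

    x_low: Bound
    x_high: Bound
    y_low: Bound
    y_high: Bound

    def __post_init__(self) -> None:
        if self.x_low.value > self.x_high.value or self.y_low.value > self.y_high.value:
            raise ValueError("degenerate RangeBox: low bound exceeds high bound")

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_low.admits_above(x)
            and self.x_high.admits_below(x)
            and self.y_low.admits_above(y)
            and self.y_high.admits_below(y)
        )

    def contains_interval(self, a: GenomicInterval) -> bool:
        return self.contains(a.start, a.end)


def rewrite(r: AllenRelation, q: GenomicInterval) -> RangeBox:
    """Rewrite the interval query ``(r, q)`` as a 2-D range query.

    For ``q = [x', y']`` the returned box admits exactly the points
    ``(a.start, a.end)`` of intervals with ``a r q``.  Examples: an ``oi``
    query against ``[3, 7]`` becomes ``x ∈ (3, 7), y ∈ (7, +∞)``; an ``=``
    query becomes the closed degenerate box at ``(x', y')``.

    Textbook presentations write the unconstrained start side of o/di/m/fi/<
    as ``0 < x``; genomic coordinates may legitimately be 0, so the start side
    is left unbounded below instead (the set of *valid* intervals admitted is
    otherwise unchanged for positive coordinates).
    """
    xp, yp = q.start, q.end
    op, cl = Bound.open_at, Bound.closed_at
    lo, hi = Bound.neg_inf(), Bound.pos_inf()
    R = AllenRelation
    if r is R.OVERLAPS:  # x < x' < y < y'
        return RangeBox(lo, op(xp), op(xp), op(yp))
    if r is R.OVERLAPPED_BY:  # x' < x < y' < y
        return RangeBox(op(xp), op(yp), op(yp), hi)
    if r is R.DURING:  # x' < x < y < y'
        return RangeBox(op(xp), op(yp), op(xp), op(yp))
    if r is R.CONTAINS:  # x < x' < y' < y
        return RangeBox(lo, op(xp), op(yp), hi)
    if r is R.MEETS:  # x < y = x' < y'
        return RangeBox(lo, op(xp), cl(xp), cl(xp))
    if r is R.MET_BY:  # x' < y' = x < y
        return RangeBox(cl(yp), cl(yp), op(yp), hi)
    if r is R.STARTS:  # x = x' < y < y'
        return RangeBox(cl(xp), cl(xp), op(xp), op(yp))
    if r is R.STARTED_BY:  # x = x' < y' < y
        return RangeBox(cl(xp), cl(xp), op(yp), hi)
    if r is R.FINISHES:  # x' < x < y = y'
        return RangeBox(op(xp), op(yp), cl(yp), cl(yp))
    if r is R.FINISHED_BY:  # x < x' < y' = y
        return RangeBox(lo, op(xp), cl(yp), cl(yp))
    if r is R.BEFORE:  # x < y < x'
        return RangeBox(lo, op(xp), lo, op(xp))
    if r is R.AFTER:  # y' < x < y
        return RangeBox(op(yp), hi, op(yp), hi)
    if r is R.EQUALS:  # x = x', y = y'
        return RangeBox(cl(xp), cl(xp), cl(yp), cl(yp))
    raise ValueError(f"unknown relation: {r!r}")  # pragma: no cover


def relation_holds(a: GenomicInterval, q: GenomicInterval, r: AllenRelation) -> bool:
    """True iff ``a r q`` holds, i.e. ``classify(a, q) is r``."""
    return classify(a, q) is r


def intervals_intersect(a: GenomicInterval, q: GenomicInterval) -> bool:
    """Closed-interval intersection test: ``a.start <= q.end and a.end >= q.start``."""
    return a.start <= q.end and a.end >= q.start
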