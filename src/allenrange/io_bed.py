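"""BED dialect input/output and result emission.

BED intervals are read with their raw ``chromStart``/``chromEnd`` values as
closed endpoints ``[start, end]`` — the same convention the index structures
use — unless ``half_open=True`` converts the conventional 0-based half-open
records ``[s, e)`` to ``[s, e-1]``.  Records whose start is not strictly
below their (possibly converted) end are dropped and counted, since such
records carry no valid point above the ``y = x`` line.

Reading is gzip-transparent (sniffed from the magic bytes, not the filename)
and locale-independent: coordinates are parsed as exact integers.
"""

from __future__ import annotations

import gzip
import io
import logging
import sys
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence, TextIO, Union

from .allen_core import AllenRelation, GenomicInterval

__all__ = ["BedData", "BedParseError", "read_bed", "write_bed", "write_results"]

logger = logging.getLogger(__name__)

_SKIP_PREFIXES = ("#", "track", "browser")


class BedParseError(ValueError):
    """A malformed BED record; carries the 1-based line number."""

    def __init__(self, path: str, lineno: int, message: str) -> None:
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass
class BedData(Mapping):
    """Mapping chromosome → list of intervals, plus ingest bookkeeping.

    ``n_dropped`` counts records rejected for ``start >= end`` (after any
    half-open conversion); ``n_duplicates_removed`` counts records removed by
    deduplication.  Provenance indices run 0,1,... in file order within each
    chromosome, before deduplication, so surviving duplicates keep their ids.
    """

    by_chrom: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    n_dropped: int = 0
    n_duplicates_removed: int = 0

    def __getitem__(self, chrom: str) -> list[GenomicInterval]:
        return self.by_chrom[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.by_chrom)

    def __len__(self) -> int:
        return len(self.by_chrom)

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())


def _open_text(path: str) -> TextIO:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="utf-8")
    return io.TextIOWrapper(fh, encoding="utf-8")


def read_bed(path: str, half_open: bool = False, dedup: bool = False) -> BedData:
    """Read a BED file into per-chromosome interval lists.

    The first three tab-separated columns are chrom, chromStart, chromEnd;
    extra columns are ignored, header/track/browser lines are skipped.
    Malformed coordinate fields raise :class:`BedParseError` with the line
    number.  Chromosome names are kept verbatim (no "chr" normalization).
    """
    data = BedData()
    counters: dict[str, int] = {}
    seen: set[tuple[str, int, int]] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(path, lineno, "fewer than 3 columns")
            chrom, s_raw, e_raw = fields[0], fields[1], fields[2]
            try:
                start = int(s_raw)
                end = int(e_raw)
            except ValueError:
                raise BedParseError(
                    path, lineno, f"non-integer coordinates {s_raw!r}/{e_raw!r}"
                ) from None
            if half_open:
                end -= 1
            if start >= end:
                data.n_dropped += 1
                continue
            if dedup:
                key = (chrom, start, end)
                if key in seen:
                    data.n_duplicates_removed += 1
                    continue
                seen.add(key)
            i = counters.get(chrom, 0)
            counters[chrom] = i + 1
            data.by_chrom.setdefault(chrom, []).append(
                GenomicInterval(chrom, start, end, i)
            )
    if data.n_dropped:
        logger.warning(
            "%s: dropped %d record(s) with start >= end", path, data.n_dropped
        )
    if data.n_duplicates_removed:
        logger.info(
            "%s: removed %d duplicate record(s)", path, data.n_duplicates_removed
        )
    return data


def write_bed(stream: Union[TextIO, str], intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as 3-column BED (raw closed endpoints, as ingested)."""
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8") as fh:
            write_bed(fh, intervals)
        return
    for a in intervals:
        stream.write(f"{a.chrom}\t{a.start}\t{a.end}\n")


def write_results(
    stream: Union[TextIO, str],
    records: Iterable[tuple[GenomicInterval, GenomicInterval, AllenRelation]],
) -> int:
    """Emit query hits as 8-column TSV, one line per (query, hit, relation).

    Columns: query chrom/start/end, relation symbol, data chrom/start/end,
    data provenance index.  Records are written in the order given; callers
    order them by query position in the query file, then data index.
    Returns the number of lines written.
    """
    if isinstance(stream, str):
        with open(stream, "w", encoding="utf-8") as fh:
            return write_results(fh, records)
    n = 0
    for q, a, r in records:
        stream.write(
            f"{q.chrom}\t{q.start}\t{q.end}\t{r.symbol}\t"
            f"{a.chrom}\t{a.start}\t{a.end}\t{a.index}\n"
        )
        n += 1
    return n
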