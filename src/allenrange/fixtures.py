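"""Deterministic synthetic interval sets for testing and benchmarking.

Everything here is reproducible from a single master seed: random generators
derive a per-fixture stream via :func:`fixture_seed`, and the adversarial
fixtures are fully deterministic constructions covering the structural corner
cases of the index trees (duplicate coordinates, shared starts or ends,
deep nesting, touching chains).

The ``cascade_demo8`` fixture is a synthetic 8-interval set constructed so
that a ``d`` query against ``[2, 10]`` returns exactly 4 intervals with the
split node at the root, exercising reporting on both descent paths of the
cascaded query.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np

from .allen_core import GenomicInterval

__all__ = [
    "fixture_seed",
    "generate_uniform",
    "add_duplicates",
    "adversarial_suite",
]

_SEED_MOD = 2**31 - 1


def fixture_seed(master_seed: int, name: str) -> int:
    """Derive a per-fixture seed from one master seed and a fixture name."""
    return (int(master_seed) + zlib.crc32(name.encode("utf-8"))) % _SEED_MOD


def generate_uniform(
    n: int, coord_max: int, seed: int, chrom: str = "chr1"
) -> list[GenomicInterval]:
    """``n`` intervals with endpoints uniform on ``{0, ..., coord_max - 1}``.

    Pairs drawing equal endpoints are redrawn (start must be strictly below
    end); the smaller draw becomes the start.  Output is deterministic for a
    fixed seed, with provenance indices 0..n-1 in generation order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if coord_max < 2:
        raise ValueError("coord_max must be >= 2 to admit a valid interval")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, coord_max, size=n)
    b = rng.integers(0, coord_max, size=n)
    while True:
        equal = a == b
        k = int(equal.sum())
        if k == 0:
            break
        a[equal] = rng.integers(0, coord_max, size=k)
        b[equal] = rng.integers(0, coord_max, size=k)
    starts = np.minimum(a, b)
    ends = np.maximum(a, b)
    return [
        GenomicInterval(chrom, int(s), int(e), i)
        for i, (s, e) in enumerate(zip(starts, ends))
    ]


def add_duplicates(
    S: Sequence[GenomicInterval], n_duplicates: int, seed: int
) -> list[GenomicInterval]:
    """Append ``n_duplicates`` coordinate-duplicates with fresh provenance indices.

    Emulates pooling overlapping BED files, where identical intervals recur;
    the duplicates share (start, end) with randomly chosen originals but keep
    distinct indices so every copy is individually reportable.
    """
    rng = np.random.default_rng(seed)
    out = list(S)
    base = len(out)
    picks = rng.integers(0, len(S), size=n_duplicates)
    for j, p in enumerate(picks):
        src = S[int(p)]
        out.append(GenomicInterval(src.chrom, src.start, src.end, base + j))
    return out


def _seq(chrom: str, pairs: Sequence[tuple[int, int]]) -> list[GenomicInterval]:
    return [GenomicInterval(chrom, s, e, i) for i, (s, e) in enumerate(pairs)]


def adversarial_suite(chrom: str = "chr1") -> dict[str, list[GenomicInterval]]:
    """Named deterministic fixtures covering structural corner cases.

    - ``identical``: 16 copies of one interval (duplicate faithfulness).
    - ``identical_starts``: 32 intervals sharing a start (degenerate x-splits).
    - ``identical_ends``: 32 intervals sharing an end (y-sort ties).
    - ``nested_chain``: 50 strictly nested intervals (every interior one is
      ``d`` of the outermost; dense-overlap stress).
    - ``touching_chain``: 10 abutting intervals (9 consecutive ``m`` pairs).
    - ``cascade_demo8``: synthetic 8-interval set whose ``d`` query against
      ``[2, 10]`` has exactly 4 hits with the split at the root.
    """
    return {
        "identical": _seq(chrom, [(10, 20)] * 16),
        "identical_starts": _seq(chrom, [(5, 6 + i) for i in range(32)]),
        "identical_ends": _seq(chrom, [(i, 100) for i in range(32)]),
        "nested_chain": _seq(chrom, [(i, 200 - i) for i in range(50)]),
        "touching_chain": _seq(chrom, [(10 * i, 10 * (i + 1)) for i in range(10)]),
        "cascade_demo8": _seq(
            chrom,
            [(0, 4), (3, 6), (4, 7), (5, 9), (6, 12), (7, 9), (8, 13), (10, 14)],
        ),
    }
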