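import pytest
from hypothesis import HealthCheck, settings

from allenrange.allen_core import GenomicInterval

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_interval(start, end, index=0, chrom="chr1"):
    return GenomicInterval(chrom, start, end, index)


def all_valid_intervals(coord_max, chrom="chr1"):
    """Every valid interval with endpoints in {0..coord_max}, indexed in order."""
    out = []
    for s in range(coord_max + 1):
        for e in range(s + 1, coord_max + 1):
            out.append(GenomicInterval(chrom, s, e, len(out)))
    return out


@pytest.fixture
def iv():
    return make_interval


@pytest.fixture(scope="session")
def small_universe():
    """All 21 valid intervals with endpoints in {0..6}."""
    return all_valid_intervals(6)
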