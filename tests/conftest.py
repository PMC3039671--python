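import numpy as np
import pytest

from broadcall import GenomicInterval, TagSet


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture()
def random_tagset(rng):
    """500 tags of mixed strand on two small chromosomes."""
    def make(n=500, extent=50_000, chroms=("chr1", "chr2")):
        tags = {}
        for chrom in chroms:
            pos = rng.integers(0, extent, size=n)
            strand = rng.choice(np.array([1, -1], dtype=np.int8), size=n)
            tags[chrom] = (pos, strand)
        return TagSet(tags, read_length=36, chrom_sizes={c: extent for c in chroms})
    return make


def random_intervals(rng, n, extent=100_000, chrom="chr1", max_len=2_000):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, extent - max_len))
        out.append(GenomicInterval(chrom, start, start + int(rng.integers(1, max_len))))
    return out
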