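import numpy as np
import pytest

from archscape.core import AlignedRead, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_read(chrom, start, end, strand="+", name=None, adapter=True):
    return AlignedRead(
        interval=GenomicInterval(chrom, start, end, strand=strand, name=name),
        reached_adapter=adapter,
    )


def random_reads(rng, n, genome=5000, chrom="chr1", min_len=100, max_len=240):
    reads = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        s = int(rng.integers(0, genome - length))
        reads.append(make_read(chrom, s, s + length, name=f"r{i}"))
    return reads


def reference_greedy(pileup):
    """Brute-force reference peak caller: explicit sort of all candidates,
    sequential acceptance with an all-pairs overlap scan against accepted
    peaks. Independent of the production implementation."""
    peaks = []
    for chrom in sorted(pileup.counts):
        counts = pileup.counts[chrom]
        longest = pileup.longest[chrom]
        candidates = sorted(counts, key=lambda p: (-counts[p], p))
        accepted = []
        for pos in candidates:
            b = longest[pos]
            if any(b.start < b2.end and b2.start < b.end for b2 in accepted):
                continue
            accepted.append(b)
            peaks.append((chrom, pos, b.start, b.end, counts[pos]))
    peaks.sort(key=lambda t: (t[0], t[1]))
    return peaks
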