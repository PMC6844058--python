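import numpy as np
import pytest

from methdissect.io_segments import ReadCalls, SegmentProfile, SegmentKey


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_reads(rng, n_reads=1000, chroms=("chr1", "chr2"), max_cpgs=8,
                 unit_prefix="read", units=None):
    """Random read-call sets over a small shared CpG landscape so that
    windows from different reads actually collide."""
    # a fixed CpG grid per chromosome; reads pick a contiguous slice
    grid = {c: np.sort(rng.choice(np.arange(100, 5000, 7), size=80, replace=False))
            for c in chroms}
    reads = []
    for i in range(n_reads):
        chrom = chroms[rng.integers(len(chroms))]
        g = grid[chrom]
        n = int(rng.integers(1, max_cpgs + 1))
        start = int(rng.integers(0, len(g) - n))
        pos = tuple(int(p) for p in g[start:start + n])
        calls = tuple(int(c) for c in rng.integers(0, 2, size=n))
        unit = (f"{unit_prefix}{i}" if units is None
                else str(units[rng.integers(len(units))]))
        reads.append(ReadCalls(unit, chrom, pos, calls))
    return reads


def profile_from_counts(counts: dict[str, int], chrom="chr1",
                        pos=(100, 110, 120, 130), mode="single_cell"):
    """SegmentProfile with the given pattern -> count multiset."""
    obs = {}
    i = 0
    for pat, n in counts.items():
        for _ in range(n):
            obs[f"u{i:03d}"] = pat
            i += 1
    return SegmentProfile(key=SegmentKey(chrom, pos), observations=obs, mode=mode)
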