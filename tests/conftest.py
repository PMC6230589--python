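import numpy as np
import pytest

from nascentlnc.genomic_io import CoverageTrack, GenomicInterval


@pytest.fixture
def small_genome():
    return {"chr1": 100_000, "chr2": 50_000}


def random_blocks(rng, chrom_len, n_blocks, max_width=500, max_value=20.0):
    """Non-overlapping random (start, end, value) blocks on one chromosome."""
    edges = np.sort(rng.choice(chrom_len, size=2 * n_blocks, replace=False))
    blocks = []
    for i in range(0, len(edges) - 1, 2):
        start, end = int(edges[i]), int(edges[i + 1])
        if end > start:
            blocks.append((start, min(end, start + max_width), float(rng.uniform(0, max_value))))
    return blocks


def brute_force_array(chrom_len, blocks):
    """Independent per-base signal array oracle."""
    arr = np.zeros(chrom_len)
    for start, end, value in blocks:
        arr[start:end] = value
    return arr


@pytest.fixture
def random_track(small_genome):
    rng = np.random.default_rng(42)
    blocks = {c: random_blocks(rng, L, 50) for c, L in small_genome.items()}
    track = CoverageTrack.from_blocks(small_genome, blocks)
    arrays = {c: brute_force_array(L, blocks[c]) for c, L in small_genome.items()}
    return track, arrays


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)
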