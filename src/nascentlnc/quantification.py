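"""Counting nascent signal over regions, RPKM, and expression filtering."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CountMatrix, CoverageTrack, GenomicInterval, StrandedCoverage, TranscriptUnit


def count_region(
    coverage: CoverageTrack | StrandedCoverage,
    interval: GenomicInterval,
    stranded: bool = True,
) -> int:
    """Integer tag count over an interval (round-half-even).

    With ``stranded=True`` only the matching strand of a stranded coverage is
    summed; otherwise both strands are summed (divergent eRNA transcription).
    A plain unstranded track is summed as-is.
    """
    if isinstance(coverage, StrandedCoverage):
        if stranded:
            total = coverage.get(interval.strand).sum(interval)
        else:
            total = coverage.plus.sum(interval) + coverage.minus.sum(interval)
    else:
        total = coverage.sum(interval)
    return int(np.rint(total))


def rpkm(count: float, length_bp: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count / (length_bp / 1000.0) / (library_size / 1e6)


def build_count_matrix(
    units: Sequence[TranscriptUnit],
    coverage_by_sample: Mapping[str, CoverageTrack | StrandedCoverage],
    condition: Mapping[str, str],
    library_size: Mapping[str, int],
    stranded: bool = True,
) -> CountMatrix:
    """Count every unit in every sample's coverage."""
    samples = list(coverage_by_sample)
    data = {
        s: [count_region(coverage_by_sample[s], u.interval, stranded=stranded) for u in units]
        for s in samples
    }
    df = pd.DataFrame(data, index=[u.id for u in units], dtype=np.int64)
    return CountMatrix(df, dict(condition), dict(library_size))


@dataclass
class ExpressionTable:
    """RPKM per (row, sample), tied to the count matrix it derives from."""

    counts: CountMatrix
    lengths: pd.Series  # bp per row id

    def __post_init__(self) -> None:
        self.lengths = self.lengths.loc[self.counts.counts.index].astype(int)
        if (self.lengths <= 0).any():
            raise ValueError("all region lengths must be positive")

    @property
    def rpkm(self) -> pd.DataFrame:
        lib = np.array([self.counts.library_size[s] for s in self.counts.sample_ids], dtype=float)
        mat = self.counts.counts.values * 1e9 / (self.lengths.values[:, None] * lib[None, :])
        return pd.DataFrame(mat, index=self.counts.counts.index, columns=self.counts.sample_ids)


def expression_filter(
    rpkm_table: pd.DataFrame, min_rpkm: float = 0.5, min_samples: int = 3
) -> list[str]:
    """Rows with RPKM strictly above ``min_rpkm`` in at least ``min_samples``
    samples, pooled over all samples. Order-preserving."""
    n_pass = (rpkm_table.values > min_rpkm).sum(axis=1)
    keep = n_pass >= min_samples
    return [rid for rid, k in zip(rpkm_table.index, keep) if k]
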