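"""De novo transcript-unit calling from strand-specific nascent coverage.

Pipeline order is fixed: call -> remove_gene_overlap -> remove_small_rna ->
assign_known; each stage returns a subset (or relabeling) of its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genomic_io import CoverageTrack, GenomicInterval, StrandedCoverage, TranscriptUnit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallParams:
    bin_bp: int = 100
    fold_over_background: float = 4.0
    max_gap_bins: int = 5
    min_length_bp: int = 500
    background_trim: float = 0.1

    def __post_init__(self) -> None:
        if self.bin_bp <= 0 or self.min_length_bp <= 0:
            raise ValueError("bin_bp and min_length_bp must be positive")
        if self.fold_over_background <= 0:
            raise ValueError("fold_over_background must be positive")
        if self.max_gap_bins < 0:
            raise ValueError("max_gap_bins must be >= 0")
        if not 0 <= self.background_trim < 0.5:
            raise ValueError("background_trim must be in [0, 0.5)")


def trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Mean after dropping the lowest and highest ``trim`` fraction of values."""
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        return 0.0
    k = int(np.floor(n * trim))
    core = values[k : n - k] if n - 2 * k > 0 else values
    return float(core.mean())


def _estimate_background(binned: dict[str, np.ndarray], trim: float) -> float:
    # Background over ALL bins (zeros included). With zeros excluded, the
    # noiseless limit (background truly 0) would put the threshold above the
    # transcripts themselves and nothing could ever be called.
    allbins = np.concatenate([b for b in binned.values()]) if binned else np.empty(0)
    return trimmed_mean(allbins, trim)


def _merge_candidate_runs(candidate: np.ndarray, max_gap_bins: int) -> list[tuple[int, int]]:
    """Merge candidate bins separated by <= max_gap_bins non-candidate bins.

    Returns (first_bin, last_bin_exclusive) index pairs.
    """
    idx = np.nonzero(candidate)[0]
    if idx.size == 0:
        return []
    runs = []
    run_start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap_bins:
            prev = i
        else:
            runs.append((int(run_start), int(prev) + 1))
            run_start = prev = i
    runs.append((int(run_start), int(prev) + 1))
    return runs


def call_transcripts_one_strand(
    track: CoverageTrack, strand: str, params: CallParams = CallParams()
) -> list[GenomicInterval]:
    """Call units on a single strand; boundaries snap to bin edges."""
    binned = {c: track.binned(c, params.bin_bp) for c in sorted(track.genome)}
    background = _estimate_background(binned, params.background_trim)
    threshold = params.fold_over_background * background
    intervals: list[GenomicInterval] = []
    for chrom in sorted(track.genome):
        sig = binned[chrom]
        candidate = sig > threshold
        for first, last in _merge_candidate_runs(candidate, params.max_gap_bins):
            start = first * params.bin_bp
            end = min(last * params.bin_bp, track.genome[chrom])
            if end - start < params.min_length_bp:
                continue
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def call_transcripts(
    coverage: StrandedCoverage, params: CallParams = CallParams(), id_prefix: str = "tu"
) -> list[TranscriptUnit]:
    """Call transcript units independently per strand from pooled coverage.

    Output is deterministic, ordered by (chrom, start, strand).
    """
    intervals = call_transcripts_one_strand(coverage.plus, "+", params)
    intervals += call_transcripts_one_strand(coverage.minus, "-", params)
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return [
        TranscriptUnit(iv, f"{id_prefix}_{i:05d}", origin="called")
        for i, iv in enumerate(intervals)
    ]


def remove_gene_overlap(
    units: Sequence[TranscriptUnit],
    coding_annotation: Sequence[TranscriptUnit],
    max_same_strand_overlap: float = 0.2,
) -> list[TranscriptUnit]:
    """Discard units running through same-strand coding genes.

    A unit is discarded when its overlap fraction with any single same-strand
    coding gene body is strictly greater than ``max_same_strand_overlap``, or
    when its TSS lies inside a same-strand coding gene. Opposite-strand
    overlap never discards (antisense transcripts are retained).
    """
    kept = []
    for u in units:
        discard = False
        for g in coding_annotation:
            if g.interval.strand != u.interval.strand:
                continue
            ov = u.interval.overlap_bp(g.interval)
            if ov == 0:
                continue
            if ov / u.interval.length > max_same_strand_overlap:
                discard = True
            elif g.interval.chrom == u.interval.chrom and g.interval.start <= u.tss < g.interval.end:
                discard = True
            if discard:
                logger.debug("dropping %s: same-strand overlap with %s", u.id, g.id)
                break
        if not discard:
            kept.append(u)
    return kept


def remove_small_rna(
    units: Sequence[TranscriptUnit],
    small_rna_annotation: Sequence[tuple[GenomicInterval, str]],
    max_small_length_bp: int = 300,
) -> list[TranscriptUnit]:
    """Drop short units coincident with annotated small RNAs.

    Units overlapping a same-strand small-RNA record by >= 1 bp are discarded
    when <= ``max_small_length_bp`` long; longer units are retained with a
    logged warning.
    """
    kept = []
    for u in units:
        hit = None
        for iv, name in small_rna_annotation:
            if iv.strand == u.interval.strand and u.interval.overlap_bp(iv) >= 1:
                hit = name
                break
        if hit is not None and u.interval.length <= max_small_length_bp:
            logger.debug("dropping %s: small RNA %s", u.id, hit)
            continue
        if hit is not None:
            logger.warning("unit %s overlaps small RNA %s but exceeds %d bp; retained",
                           u.id, hit, max_small_length_bp)
        kept.append(u)
    return kept


def assign_known(
    units: Sequence[TranscriptUnit],
    lnc_catalog: Sequence[tuple[GenomicInterval, str]],
    min_overlap_fraction: float = 0.7,
) -> list[TranscriptUnit]:
    """Label units as known vs novel lncRNA by same-strand catalog overlap.

    Overlap fraction is relative to the unit's length; assignment requires a
    fraction strictly greater than ``min_overlap_fraction``. The best-overlap
    record wins; exact ties break to the lexicographically smallest db id.
    """
    out = []
    for u in units:
        best_frac = -1.0
        best_id: str | None = None
        for iv, db_id in lnc_catalog:
            if iv.strand != u.interval.strand:
                continue
            frac = u.interval.overlap_bp(iv) / u.interval.length
            if frac > best_frac or (frac == best_frac and best_id is not None and db_id < best_id):
                best_frac, best_id = frac, db_id
        if best_frac > min_overlap_fraction:
            out.append(replace(u, unit_class="known_lncRNA", db_id=best_id))
        else:
            out.append(replace(u, unit_class="novel_lncRNA", db_id=None))
    return out
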