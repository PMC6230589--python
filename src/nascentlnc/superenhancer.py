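"""Super-enhancer calling: H3K27ac peaks, stitching, rank-signal cutoff,
GRO-based differential activity, and condition comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential_expression import run_de
from .genomic_io import CountMatrix, CoverageTrack, GenomicInterval, StrandedCoverage, TranscriptUnit
from .quantification import count_region
from .transcript_discovery import trimmed_mean


@dataclass
class EnhancerCluster:
    """A stitched H3K27ac region with aggregate signal, rank and SE flag."""

    interval: GenomicInterval
    member_peaks: list[GenomicInterval] = field(default_factory=list)
    aggregate_signal: float = 0.0
    rank: int = 0  # 1 = highest aggregate signal
    is_super: bool = False
    condition: str = ""

    @property
    def id(self) -> str:
        return f"se_{self.interval.chrom}_{self.interval.start}_{self.interval.end}"


def _merge_intervals(
    intervals: list[tuple[str, int, int]], gap: int
) -> list[tuple[str, int, int]]:
    """Merge sorted (chrom, start, end) triples whose gaps are <= ``gap``."""
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start - merged[-1][2] <= gap:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            merged.append((chrom, start, end))
    return merged


def call_enhancer_peaks(
    k27ac: CoverageTrack,
    window_bp: int = 1000,
    step_bp: int = 100,
    fold_over_background: float = 4.0,
    merge_gap_bp: int = 1000,
    background_trim: float = 0.1,
    min_signal: float = 1e-6,
    rel_floor: float = 0.02,
) -> list[GenomicInterval]:
    """Sliding-window peak calling on an unstranded mark track.

    Windows with mean signal strictly above fold x trimmed-mean background
    (trimmed over all windows genome-wide, zeros included) become candidates;
    overlapping or near-adjacent candidates merge into peaks.
    """
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_means = []
    for chrom in sorted(k27ac.genome):
        starts, sums = k27ac.window_sums(chrom, window_bp, step_bp)
        means = sums / window_bp
        per_chrom[chrom] = (starts, means)
        all_means.append(means)
    if not all_means or sum(m.size for m in all_means) == 0:
        return []
    background = trimmed_mean(np.concatenate(all_means), background_trim)
    # the absolute and relative floors keep faint signal tails out of the
    # candidate set when the trimmed background is zero (sparse tracks)
    peak_mean = max(float(m.max()) if m.size else 0.0 for m in all_means)
    threshold = max(fold_over_background * background, min_signal, rel_floor * peak_mean)
    # a candidate window is represented by its central step-sized tile so that
    # merged peaks hug the signal instead of being padded by the window width
    candidates: list[tuple[str, int, int]] = []
    half = (window_bp - step_bp) // 2
    for chrom, (starts, means) in per_chrom.items():
        for s in starts[means > threshold]:
            candidates.append((chrom, int(s) + half, int(s) + half + step_bp))
    peaks = _merge_intervals(candidates, merge_gap_bp)
    return [
        GenomicInterval(c, s, min(e, k27ac.genome[c]), ".") for c, s, e in peaks
    ]


def stitch_peaks(
    peaks: Sequence[GenomicInterval],
    stitch_bp: int = 12500,
    tss_exclusion: Sequence[tuple[str, int]] | None = None,
    tss_excl_halfwidth: int = 2500,
) -> list[EnhancerCluster]:
    """Stitch peaks whose gaps are <= ``stitch_bp`` into clusters.

    When ``tss_exclusion`` (a list of (chrom, tss) positions) is given, any
    peak lying fully inside +-``tss_excl_halfwidth`` of a TSS is removed
    before stitching.
    """
    usable = list(peaks)
    if tss_exclusion:
        kept = []
        for p in usable:
            inside = any(
                chrom == p.chrom and tss - tss_excl_halfwidth <= p.start and p.end <= tss + tss_excl_halfwidth
                for chrom, tss in tss_exclusion
            )
            if not inside:
                kept.append(p)
        usable = kept
    usable.sort(key=lambda p: (p.chrom, p.start, p.end))
    clusters: list[EnhancerCluster] = []
    for p in usable:
        if (
            clusters
            and clusters[-1].interval.chrom == p.chrom
            and p.start - clusters[-1].interval.end <= stitch_bp
        ):
            last = clusters[-1]
            last.member_peaks.append(p)
            last.interval = GenomicInterval(
                p.chrom, last.interval.start, max(last.interval.end, p.end), "."
            )
        else:
            clusters.append(EnhancerCluster(GenomicInterval(p.chrom, p.start, p.end, "."), [p]))
    return clusters


def score_clusters(clusters: Sequence[EnhancerCluster], k27ac: CoverageTrack) -> None:
    """Aggregate signal = sum of member-peak signal; ranks 1 = highest."""
    for c in clusters:
        c.aggregate_signal = float(sum(k27ac.sum(p) for p in c.member_peaks))
    order = np.argsort([-c.aggregate_signal for c in clusters], kind="stable")
    for rank, idx in enumerate(order, start=1):
        clusters[idx].rank = rank


def se_cutoff(signals: Sequence[float]) -> np.ndarray:
    """Super-enhancer flags from the rank-signal inflection rule.

    Signals are sorted ascending; rank and signal are each scaled to [0, 1];
    the cut point is the rightmost interior index where the central-difference
    slope crosses from <= 1 to > 1. Clusters with signal strictly above the
    cut point's signal are super-enhancers. If the slope never exceeds 1
    (e.g. all-equal signals), no cluster is flagged.
    """
    sig = np.asarray(signals, dtype=float)
    n = sig.size
    if n < 2:
        raise ValueError("se_cutoff requires >= 2 clusters")
    y_sorted = np.sort(sig)
    if y_sorted[-1] == y_sorted[0]:
        return np.zeros(n, dtype=bool)
    x = np.arange(n) / (n - 1)
    y = (y_sorted - y_sorted[0]) / (y_sorted[-1] - y_sorted[0])
    if n == 2:
        # two points define the identity line; slope never strictly exceeds 1
        return np.zeros(n, dtype=bool)
    slopes = (y[2:] - y[:-2]) / (x[2:] - x[:-2])  # interior points 1..n-2
    exceeded = slopes > 1.0
    cut_idx = None
    for j in range(slopes.size):
        prev = exceeded[j - 1] if j > 0 else False
        if exceeded[j] and not prev:
            cut_idx = j + 1  # interior index j corresponds to sorted index j+1
    if cut_idx is None:
        return np.zeros(n, dtype=bool)
    cut_signal = y_sorted[cut_idx]
    return sig > cut_signal


def flag_superenhancers(clusters: Sequence[EnhancerCluster]) -> None:
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to separate super-enhancers")
    flags = se_cutoff([c.aggregate_signal for c in clusters])
    for c, f in zip(clusters, flags):
        c.is_super = bool(f)


def union_clusters(
    clusters_a: Sequence[EnhancerCluster], clusters_b: Sequence[EnhancerCluster]
) -> list[GenomicInterval]:
    """Union of two cluster sets, merging regions that overlap by >= 1 bp."""
    triples = [
        (c.interval.chrom, c.interval.start, c.interval.end)
        for c in list(clusters_a) + list(clusters_b)
    ]
    return [GenomicInterval(c, s, e, ".") for c, s, e in _merge_intervals(triples, 0)]


def se_activity(
    regions: Sequence[GenomicInterval],
    coverage_by_sample: Mapping[str, StrandedCoverage],
    condition: Mapping[str, str],
    library_size: Mapping[str, int],
) -> CountMatrix:
    """Both-strand GRO counts per region per sample (eRNA transcription is divergent)."""
    samples = list(coverage_by_sample)
    ids = [f"se_{r.chrom}_{r.start}_{r.end}" for r in regions]
    data = {
        s: [count_region(coverage_by_sample[s], r, stranded=False) for r in regions]
        for s in samples
    }
    df = pd.DataFrame(data, index=ids, dtype=np.int64)
    return CountMatrix(df, dict(condition), dict(library_size))


def differential_se(se_counts: CountMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """FDR-only differential activity of enhancer clusters from nascent counts."""
    return run_de(se_counts, mode="fdr_only", alpha=alpha)


def gained_lost(
    se_a: Sequence[EnhancerCluster], se_b: Sequence[EnhancerCluster]
) -> dict[str, list[EnhancerCluster]]:
    """Partition SEs by >= 1 bp overlap between conditions.

    B-clusters with no overlap in A are gained, A-clusters with no overlap in
    B are lost; everything else is shared.
    """
    def overlaps_any(c: EnhancerCluster, others: Sequence[EnhancerCluster]) -> bool:
        return any(c.interval.overlap_bp(o.interval) >= 1 for o in others)

    gained = [c for c in se_b if not overlaps_any(c, se_a)]
    lost = [c for c in se_a if not overlaps_any(c, se_b)]
    shared = [c for c in se_a if overlaps_any(c, se_b)] + [
        c for c in se_b if overlaps_any(c, se_a)
    ]
    return {"gained": gained, "lost": lost, "shared": shared}


def nearest_feature_tally(
    clusters: Sequence[EnhancerCluster],
    annotation: Sequence[TranscriptUnit],
    lnc_classes: frozenset[str] = frozenset({"known_lncRNA", "novel_lncRNA", "p_lnc", "eRNA"}),
) -> tuple[pd.DataFrame, float]:
    """Nearest annotated feature per cluster (edge distance, ties -> smaller id)
    and the fraction of clusters whose nearest feature is a lncRNA."""
    if not annotation:
        raise ValueError("empty annotation")
    rows = []
    n_lnc = 0
    for c in clusters:
        best: tuple[int, str, str] | None = None
        for u in annotation:
            d = c.interval.edge_distance(u.interval)
            if d is None:
                continue
            key = (d, u.id, u.unit_class)
            if best is None or key < best:
                best = key
        if best is None:
            rows.append({"cluster": c.id, "nearest_id": "", "nearest_class": "", "distance": -1})
            continue
        d, uid, klass = best
        if klass in lnc_classes:
            n_lnc += 1
        rows.append({"cluster": c.id, "nearest_id": uid, "nearest_class": klass, "distance": d})
    frac = n_lnc / len(clusters) if clusters else float("nan")
    return pd.DataFrame(rows).set_index("cluster"), frac
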