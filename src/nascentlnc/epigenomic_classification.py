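"""Promoter vs enhancer labeling of lncRNAs from H3K4me3/H3K4me1 TSS signal.

A positive log2 ratio of mean H3K4me3 to mean H3K4me1 over the TSS window is
labeled promoter, a negative ratio enhancer, an exact zero ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GenomicInterval, TranscriptUnit


@dataclass(frozen=True)
class EpiClassification:
    unit_id: str
    me3_mean: float
    me1_mean: float
    log_ratio: float
    label: str  # promoter | enhancer | ambiguous


def tss_window(
    unit: TranscriptUnit, genome: Mapping[str, int], halfwidth: int = 1000
) -> GenomicInterval:
    """TSS-centered window, clipped to chromosome bounds, strand-agnostic output."""
    tss = unit.tss
    chrom = unit.interval.chrom
    start = max(0, tss - halfwidth)
    end = min(genome[chrom], tss + halfwidth)
    return GenomicInterval(chrom, start, end, ".")


def classify_lncrna(
    me3: CoverageTrack,
    me1: CoverageTrack,
    units: Sequence[TranscriptUnit],
    pseudocount: float = 0.1,
    halfwidth: int = 1000,
) -> list[EpiClassification]:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out = []
    for u in units:
        win = tss_window(u, me3.genome, halfwidth)
        me3_mean = me3.mean(win)
        me1_mean = me1.mean(win)
        log_ratio = float(np.log2((me3_mean + pseudocount) / (me1_mean + pseudocount)))
        if log_ratio > 0:
            label = "promoter"
        elif log_ratio < 0:
            label = "enhancer"
        else:
            label = "ambiguous"
        out.append(EpiClassification(u.id, me3_mean, me1_mean, log_ratio, label))
    return out


def classification_table(classes: Sequence[EpiClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.unit_id for c in classes],
            "me3_mean": [c.me3_mean for c in classes],
            "me1_mean": [c.me1_mean for c in classes],
            "log_ratio": [c.log_ratio for c in classes],
            "label": [c.label for c in classes],
        }
    ).set_index("id")
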