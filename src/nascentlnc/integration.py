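"""Linking lncRNAs to proximal coding genes, fold-change concordance, and
stability classification from steady-state detection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import TranscriptUnit


class ConstantInputError(ValueError):
    """Correlation of a constant vector is undefined."""


@dataclass(frozen=True)
class ProximalPair:
    lnc_id: str
    gene_id: str
    distance_bp: int
    lnc_log2fc: float = float("nan")
    gene_log2fc: float = float("nan")


@dataclass(frozen=True)
class StabilityCall:
    lnc_id: str
    label: str  # epigenomic label
    rnaseq_rpkm: float  # max over the condition's samples
    detected: bool
    stable: bool

    def __post_init__(self) -> None:
        if self.stable and not self.detected:
            raise ValueError("stable implies detected")


def proximal_pairs(
    lncs: Sequence[TranscriptUnit],
    coding_genes: Sequence[TranscriptUnit],
    max_distance: int = 100_000,
    gene_de: pd.DataFrame | None = None,
    lnc_de: pd.DataFrame | None = None,
    require_gene_de: bool = False,
    gene_fdr: float = 0.05,
    gene_fc: float = 1.5,
) -> list[ProximalPair]:
    """Nearest coding gene per lncRNA by edge distance, strand-agnostic.

    Ties break to smaller distance then lexicographic gene id. When
    ``require_gene_de``, pairs are kept only if the gene has fdr < ``gene_fdr``
    and |fold change| >= ``gene_fc`` in ``gene_de``. Fold-change columns are
    filled from the DE frames when provided.
    """
    lfc_min = np.log2(gene_fc)
    pairs: list[ProximalPair] = []
    for lnc in lncs:
        best: tuple[int, str] | None = None
        for g in coding_genes:
            d = lnc.interval.edge_distance(g.interval)
            if d is None or d > max_distance:
                continue
            if best is None or (d, g.id) < best:
                best = (d, g.id)
        if best is None:
            continue
        d, gid = best
        if require_gene_de:
            if gene_de is None:
                raise ValueError("require_gene_de needs a gene DE table")
            if gid not in gene_de.index:
                continue
            row = gene_de.loc[gid]
            if not (row["fdr"] < gene_fdr and abs(row["log2fc"]) >= lfc_min):
                continue
        lnc_lfc = float(lnc_de.loc[lnc.id, "log2fc"]) if lnc_de is not None and lnc.id in lnc_de.index else float("nan")
        gene_lfc = float(gene_de.loc[gid, "log2fc"]) if gene_de is not None and gid in gene_de.index else float("nan")
        pairs.append(ProximalPair(lnc.id, gid, d, lnc_lfc, gene_lfc))
    return pairs


def spearman_correlation(x, y) -> float:
    """Spearman rho: Pearson correlation of average-ranked data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def stability_classify(
    lnc_labels: Mapping[str, str],
    rnaseq_rpkm: pd.DataFrame,
    samples: Sequence[str],
    detect_threshold: float = 0.5,
    stable_threshold: float = 2.0,
    min_samples: int = 2,
) -> tuple[list[StabilityCall], dict]:
    """Detection/stability calls for one condition's RNA-Seq samples.

    A lncRNA absent from the RPKM table counts as zero everywhere. Detected
    means RPKM strictly above ``detect_threshold`` in at least ``min_samples``
    of the condition's samples; stable means max RPKM strictly above
    ``stable_threshold``. Stable implies detected by threshold ordering.
    """
    if stable_threshold <= detect_threshold:
        raise ValueError("stable_threshold must exceed detect_threshold")
    calls = []
    per_label_n: dict[str, int] = {}
    per_label_det: dict[str, int] = {}
    for lnc_id, label in lnc_labels.items():
        if lnc_id in rnaseq_rpkm.index:
            vals = rnaseq_rpkm.loc[lnc_id, list(samples)].to_numpy(dtype=float)
        else:
            vals = np.zeros(len(samples))
        detected = bool((vals > detect_threshold).sum() >= min_samples)
        stable = bool(detected and vals.max(initial=0.0) > stable_threshold)
        calls.append(StabilityCall(lnc_id, label, float(vals.max(initial=0.0)), detected, stable))
        per_label_n[label] = per_label_n.get(label, 0) + 1
        per_label_det[label] = per_label_det.get(label, 0) + int(detected)
    n = len(calls)
    n_det = sum(c.detected for c in calls)
    summary = {
        "n": n,
        "n_detected": n_det,
        "n_stable": sum(c.stable for c in calls),
        "detection_fraction": (n_det / n) if n else float("nan"),
        "per_label": {
            lab: {
                "n": per_label_n[lab],
                "n_detected": per_label_det[lab],
                "detection_fraction": per_label_det[lab] / per_label_n[lab],
            }
            for lab in sorted(per_label_n)
        },
    }
    return calls, summary


def fc_concordance(
    gro_log2fc: pd.Series,
    rnaseq_log2fc: pd.Series,
    labels: Mapping[str, str],
) -> dict[str, float | None]:
    """Spearman rho between nascent and steady-state log2 fold changes,
    computed separately per epigenomic label over shared row ids.

    Labels with fewer than 3 shared rows (or constant input) map to None.
    """
    shared = [i for i in gro_log2fc.index if i in rnaseq_log2fc.index and i in labels]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared rows")
    out: dict[str, float | None] = {}
    for lab in sorted(set(labels[i] for i in shared)):
        ids = [i for i in shared if labels[i] == lab]
        if len(ids) < 3:
            out[lab] = None
            continue
        try:
            out[lab] = spearman_correlation(
                gro_log2fc.loc[ids].to_numpy(), rnaseq_log2fc.loc[ids].to_numpy()
            )
        except ConstantInputError:
            out[lab] = None
    return out
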