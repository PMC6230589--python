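"""Synthetic miniature genome with planted ground truth.

Generates annotations, histone-mark tracks, and nascent / steady-state count
matrices whose statistical structure matches what the analysis modules
assume: NB counts over two conditions, direction-biased induction of
promoter-class lncRNAs, class-dependent steady-state retention, histone-mark
separation between promoter and enhancer TSSs, and clustered high-H3K27ac
regions forming super-enhancers.

Everything is deterministic under a fixed seed; each operation draws from its
own child stream of the configured seed, so operations can be re-run in any
order with identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .genomic_io import (
    CountMatrix,
    CoverageTrack,
    GenomicInterval,
    StrandedCoverage,
    TranscriptUnit,
)

CLASSES = ("coding", "p_lnc", "eRNA")


class SimulationError(ValueError):
    """Raised when a configuration cannot be realized (e.g. packing overflow)."""


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    n_coding: int = 20
    n_p_lnc: int = 30
    n_erna: int = 40
    n_superenhancer_clusters: int = 3
    se_cluster_members: int = 4
    frac_de: float = 0.2
    lfc_magnitude: float = 2.0
    lfc_jitter: float = 0.0  # fractional spread: |lfc| = magnitude * U(1-j, 1+j)
    p_lnc_up_bias: float = 0.9
    dispersion: float = 0.1  # NB phi, variance = mu + phi mu^2
    mean_expression: float = 150.0
    mean_sdlog: float = 0.3  # lognormal spread of per-transcript means
    stability: dict[str, float] = field(
        default_factory=lambda: {"coding": 1.0, "p_lnc": 0.6, "eRNA": 0.05}
    )
    replicates: int = 4
    coregulated_frac: float = 0.5
    known_frac: float = 0.5
    coding_length: tuple[int, int] = (5_000, 20_000)
    p_lnc_length: tuple[int, int] = (1_000, 8_000)
    erna_length: tuple[int, int] = (500, 2_000)
    spacing_bp: int = 5_000
    # histone-mark simulation
    chip_noise_cv: float = 0.2
    chip_resolution_bp: int = 10
    bump_sigma_bp: int = 300
    me_high_amp: float = 8.0
    me_low_amp: float = 2.0
    k27ac_amp: float = 4.0
    se_amp_fold: float = 5.0
    # members of a planted SE cluster are damped in the inactive condition so
    # the stitched cluster ranks with typical enhancers there (gained/lost truth)
    se_inactive_fold: float = 0.25
    # GRO coverage rasterization
    gro_background: float = 0.0  # per-base expected rate per sample per strand
    gro_noise: bool = False  # Poisson-resample coverage bins
    gro_resolution_bp: int = 100
    # steady-state layer
    post_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"coding": 0.1, "p_lnc": 0.8, "eRNA": 0.1}
    )
    library_size_mean: float = 1e7
    library_size_sigma: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_coding, self.n_p_lnc, self.n_erna, self.n_superenhancer_clusters) < 0:
            raise ValueError("counts must be >= 0")
        for name in ("frac_de", "p_lnc_up_bias", "coregulated_frac", "known_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for klass, r in self.stability.items():
            if not 0 <= r <= 1:
                raise ValueError(f"stability[{klass}] must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.se_cluster_members < 3:
            raise ValueError("SE clusters need >= 3 member loci")
        if self.n_superenhancer_clusters * self.se_cluster_members > self.n_erna:
            raise ValueError("n_erna too small for the requested SE clusters")
        if self.lfc_jitter < 0 or self.lfc_jitter >= 1:
            raise ValueError("lfc_jitter must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coding_length"] = list(self.coding_length)
        d["p_lnc_length"] = list(self.p_lnc_length)
        d["erna_length"] = list(self.erna_length)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        for key in ("coding_length", "p_lnc_length", "erna_length"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground truth: one row per transcript, one row per SE cluster."""

    transcripts: pd.DataFrame  # indexed by transcript id
    clusters: pd.DataFrame  # indexed by cluster id

    def sample_names(self, replicates: int) -> dict[str, str]:
        names = {}
        for cond in ("A", "B"):
            for i in range(1, replicates + 1):
                names[f"{cond}{i}"] = cond
        return names


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

# inter-item gaps keep separate items from stitching into one enhancer
# cluster even after k27ac bump tails (~1.7 kb reach each side) widen the
# called peaks, and guarantee a co-regulated lncRNA is nearest to its own
# partner gene
_INTER_GAP = (16_000, 20_000)
_COMPANION_GAP = (5_000, 12_000)
_CLUSTER_MEMBER_GAP = (1_500, 2_500)


def generate_annotation(config: SimulationConfig) -> tuple[list[TranscriptUnit], TruthTable]:
    """Lay out coding genes, p-lncRNAs and eRNA loci with planted effects.

    Raises :class:`SimulationError` if the requested transcripts cannot be
    packed into the genome with the required spacing.
    """
    rng = _rng(config, 11)

    n_cluster_erna = config.n_superenhancer_clusters * config.se_cluster_members
    n_single_erna = config.n_erna - n_cluster_erna

    # --- per-transcript attributes ---------------------------------------
    records: list[dict] = []

    def new_record(klass: str, length: int) -> dict:
        i = len(records)
        rec = {
            "id": f"{klass}_{i:04d}",
            "class": klass,
            "length": length,
            "strand": "+" if rng.random() < 0.5 else "-",
            "is_de": False,
            "log2fc": 0.0,
            "coregulated_with": "",
            "db_id": "",
            "cluster_id": "",
        }
        records.append(rec)
        return rec

    def sample_length(lo_hi: tuple[int, int]) -> int:
        return int(rng.integers(lo_hi[0], lo_hi[1] + 1))

    def planted_lfc(up_prob: float) -> float:
        mag = config.lfc_magnitude
        if config.lfc_jitter > 0:
            mag *= rng.uniform(1 - config.lfc_jitter, 1 + config.lfc_jitter)
        return mag if rng.random() < up_prob else -mag

    genes = [new_record("coding", sample_length(config.coding_length)) for _ in range(config.n_coding)]
    for g in genes:
        if rng.random() < config.frac_de:
            g["is_de"] = True
            g["log2fc"] = planted_lfc(0.5)

    p_lncs = [new_record("p_lnc", sample_length(config.p_lnc_length)) for _ in range(config.n_p_lnc)]
    singles = [new_record("eRNA", sample_length(config.erna_length)) for _ in range(n_single_erna)]

    clusters_meta: list[dict] = []
    cluster_members: list[list[dict]] = []
    # with no planted effects anywhere, clusters are active in both conditions
    # so that truth log2FC stays identically zero
    activity_cycle = ["B", "A", "both"] if config.frac_de > 0 else ["both"]
    for ci in range(config.n_superenhancer_clusters):
        members = [new_record("eRNA", sample_length(config.erna_length)) for _ in range(config.se_cluster_members)]
        active_in = activity_cycle[ci % len(activity_cycle)]
        cid = f"cluster_{ci:03d}"
        for m in members:
            m["cluster_id"] = cid
            # tie member transcription to cluster activity so differential SE
            # activity in GRO mirrors the planted k27ac gain/loss
            if active_in == "B":
                m["is_de"], m["log2fc"] = True, abs(planted_lfc(1.0))
            elif active_in == "A":
                m["is_de"], m["log2fc"] = True, -abs(planted_lfc(1.0))
        clusters_meta.append({"id": cid, "active_in": active_in})
        cluster_members.append(members)

    # co-regulation: a fraction of non-cluster lncRNAs is planted next to a
    # distinct coding gene and inherits that gene's DE status and fold change
    standalone_lncs = p_lncs + singles
    coreg_mask = rng.random(len(standalone_lncs)) < config.coregulated_frac
    coreg_pool = [lnc for lnc, m in zip(standalone_lncs, coreg_mask) if m]
    rng.shuffle(genes)
    companions: dict[str, dict] = {}
    for lnc, gene in zip(coreg_pool, genes):
        lnc["coregulated_with"] = gene["id"]
        lnc["is_de"] = gene["is_de"]
        lnc["log2fc"] = gene["log2fc"]
        companions[gene["id"]] = lnc

    # independent DE for the remaining lncRNAs
    for lnc in standalone_lncs:
        if lnc["coregulated_with"]:
            continue
        if rng.random() < config.frac_de:
            lnc["is_de"] = True
            up = config.p_lnc_up_bias if lnc["class"] == "p_lnc" else 0.5
            lnc["log2fc"] = planted_lfc(up)

    # known-catalog membership for lncRNAs
    for k, lnc in enumerate(p_lncs + singles + [m for ms in cluster_members for m in ms]):
        if rng.random() < config.known_frac:
            lnc["db_id"] = f"NONC{k:06d}"

    # --- placement --------------------------------------------------------
    # items: [gene (+companion)], [standalone lnc], [SE cluster members...]
    items: list[list[tuple[dict, int]]] = []  # (record, gap before record within item)
    for g in genes:
        item = [(g, 0)]
        if g["id"] in companions:
            item.append((companions[g["id"]], int(rng.integers(*_COMPANION_GAP))))
        items.append(item)
    placed = {r["id"] for item in items for r, _ in item}
    for lnc in standalone_lncs:
        if lnc["id"] not in placed:
            items.append([(lnc, 0)])
    for members in cluster_members:
        item = [(members[0], 0)]
        for m in members[1:]:
            item.append((m, int(rng.integers(*_CLUSTER_MEMBER_GAP))))
        items.append(item)

    order = rng.permutation(len(items))
    items = [items[i] for i in order]

    chroms = sorted(config.genome)
    chrom_i = 0
    cursor = int(rng.integers(*_INTER_GAP))
    for item in items:
        span = sum(gap + rec["length"] for rec, gap in item)
        gap_before = int(rng.integers(*_INTER_GAP))
        while chrom_i < len(chroms) and cursor + span > config.genome[chroms[chrom_i]]:
            chrom_i += 1
            cursor = int(rng.integers(*_INTER_GAP))
        if chrom_i >= len(chroms):
            raise SimulationError(
                "transcripts do not fit in the genome with the required spacing; "
                "reduce counts/lengths or enlarge the genome"
            )
        pos = cursor
        for rec, gap in item:
            pos += gap
            rec["chrom"] = chroms[chrom_i]
            rec["start"] = pos
            rec["end"] = pos + rec["length"]
            pos = rec["end"]
        cursor = pos + gap_before

    for rec in records:
        rec["tss"] = rec["start"] if rec["strand"] == "+" else rec["end"] - 1

    truth_df = pd.DataFrame.from_records(records).set_index("id")
    truth_df = truth_df.sort_values(["chrom", "start"])

    cl_rows = []
    for meta, members in zip(clusters_meta, cluster_members):
        start = min(m["start"] for m in members)
        end = max(m["end"] for m in members)
        cl_rows.append(
            {
                "id": meta["id"],
                "chrom": members[0]["chrom"],
                "start": start,
                "end": end,
                "members": ",".join(m["id"] for m in members),
                "active_in": meta["active_in"],
            }
        )
    clusters_df = (
        pd.DataFrame.from_records(cl_rows).set_index("id")
        if cl_rows
        else pd.DataFrame(columns=["chrom", "start", "end", "members", "active_in"]).rename_axis("id")
    )

    units = []
    for rid, rec in truth_df.iterrows():
        if rec["class"] == "coding":
            klass, db = "coding", None
        elif rec["db_id"]:
            klass, db = "known_lncRNA", rec["db_id"]
        else:
            klass, db = "novel_lncRNA", None
        units.append(
            TranscriptUnit(
                GenomicInterval(rec["chrom"], int(rec["start"]), int(rec["end"]), rec["strand"]),
                str(rid),
                origin="annotated",
                unit_class=klass,
                db_id=db,
            )
        )
    return units, TruthTable(truth_df, clusters_df)


# ---------------------------------------------------------------------------
# histone marks
# ---------------------------------------------------------------------------

@dataclass
class ChipTracks:
    me3: CoverageTrack
    me1: CoverageTrack
    k27ac_a: CoverageTrack
    k27ac_b: CoverageTrack


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    s = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * s * s, s, size=size)


def _add_bump(arr: np.ndarray, center_bp: int, amp: float, sigma_bp: float, res: int) -> None:
    half = int(np.ceil(4 * sigma_bp / res))
    c_bin = center_bp / res
    lo = max(0, int(np.floor(c_bin)) - half)
    hi = min(arr.size, int(np.ceil(c_bin)) + half + 1)
    if hi <= lo:
        return
    centers = np.arange(lo, hi) + 0.5
    arr[lo:hi] += amp * np.exp(-((centers - c_bin) * res) ** 2 / (2 * sigma_bp**2))


def simulate_chip_tracks(truth: TruthTable, config: SimulationConfig) -> ChipTracks:
    """Gaussian histone-mark bumps at planted TSSs, rasterized to 10-bp bins.

    Promoter-class TSSs (coding, p_lnc) get the high amplitude in H3K4me3 and
    the low one in H3K4me1; eRNA TSSs the reverse. H3K27ac bumps mark eRNA
    loci and coding promoters; planted SE members are boosted ``se_amp_fold``x
    in their active condition. Noise is multiplicative lognormal per locus.
    """
    rng = _rng(config, 12)
    res = config.chip_resolution_bp
    arrays = {
        name: {c: np.zeros(int(np.ceil(L / res))) for c, L in config.genome.items()}
        for name in ("me3", "me1", "k27ac_a", "k27ac_b")
    }
    member_active: dict[str, str] = {}
    for cid, crow in truth.clusters.iterrows():
        for mid in crow["members"].split(","):
            member_active[mid] = crow["active_in"]

    for tid, rec in truth.transcripts.iterrows():
        chrom, tss, klass = rec["chrom"], int(rec["tss"]), rec["class"]
        if klass in ("coding", "p_lnc"):
            me3_amp, me1_amp = config.me_high_amp, config.me_low_amp
        else:
            me3_amp, me1_amp = config.me_low_amp, config.me_high_amp
        _add_bump(arrays["me3"][chrom], tss,
                  me3_amp * _lognormal_factor(rng, config.chip_noise_cv), config.bump_sigma_bp, res)
        _add_bump(arrays["me1"][chrom], tss,
                  me1_amp * _lognormal_factor(rng, config.chip_noise_cv), config.bump_sigma_bp, res)
        if klass in ("coding", "eRNA"):
            active = member_active.get(tid, "")
            for cond, name in (("A", "k27ac_a"), ("B", "k27ac_b")):
                amp = config.k27ac_amp
                if active in (cond, "both"):
                    amp *= config.se_amp_fold
                elif active:  # cluster member, but inactive in this condition
                    amp *= config.se_inactive_fold
                _add_bump(arrays[name][chrom], tss,
                          amp * _lognormal_factor(rng, config.chip_noise_cv), config.bump_sigma_bp, res)

    tracks = {
        name: CoverageTrack.from_bin_values(config.genome, res, arrs)
        for name, arrs in arrays.items()
    }
    return ChipTracks(tracks["me3"], tracks["me1"], tracks["k27ac_a"], tracks["k27ac_b"])


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB draw with variance = mean + phi * mean^2 (Poisson at phi = 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if phi < 1e-12:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / phi
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(truth: TruthTable, config: SimulationConfig) -> tuple[CountMatrix, CountMatrix]:
    """Nascent (GRO-like) and steady-state (RNA-Seq-like) count matrices.

    GRO means are mu_i * 2^(-lfc/2) in condition A and mu_i * 2^(+lfc/2) in B,
    scaled by each sample's relative depth. Steady-state means multiply in the
    class retention factor and a per-transcript post-transcriptional
    perturbation of the fold change (noisier for p-lncRNAs by default).
    """
    rng = _rng(config, 13)
    tdf = truth.transcripts
    n = len(tdf)
    conditions = truth.sample_names(config.replicates)
    samples = list(conditions)

    mu = config.mean_expression * (
        rng.lognormal(-0.5 * config.mean_sdlog**2, config.mean_sdlog, size=n)
        if config.mean_sdlog > 0
        else np.ones(n)
    )
    lfc = tdf["log2fc"].to_numpy(dtype=float)
    retention = tdf["class"].map(config.stability).to_numpy(dtype=float)
    post_sd = tdf["class"].map(config.post_noise_sd).to_numpy(dtype=float)
    rna_lfc = lfc + rng.normal(0.0, 1.0, size=n) * post_sd

    def libs() -> np.ndarray:
        return np.maximum(
            1,
            np.rint(
                rng.lognormal(
                    np.log(config.library_size_mean) - 0.5 * config.library_size_sigma**2,
                    config.library_size_sigma,
                    size=len(samples),
                )
            ).astype(np.int64),
        )

    gro_libs, rna_libs = libs(), libs()

    def build(base_mu: np.ndarray, eff_lfc: np.ndarray, lib: np.ndarray) -> pd.DataFrame:
        cols = {}
        for j, s in enumerate(samples):
            sign = -0.5 if conditions[s] == "A" else +0.5
            mean = base_mu * np.exp2(sign * eff_lfc) * (lib[j] / config.library_size_mean)
            cols[s] = _nb_draw(rng, mean, config.dispersion)
        return pd.DataFrame(cols, index=tdf.index)

    gro = CountMatrix(
        build(mu, lfc, gro_libs),
        dict(conditions),
        {s: int(v) for s, v in zip(samples, gro_libs)},
    )
    rna = CountMatrix(
        build(mu * retention, rna_lfc, rna_libs),
        dict(conditions),
        {s: int(v) for s, v in zip(samples, rna_libs)},
    )
    return gro, rna


# ---------------------------------------------------------------------------
# GRO coverage rasterization
# ---------------------------------------------------------------------------

def simulate_gro_coverage(
    truth: TruthTable, gro: CountMatrix, config: SimulationConfig
) -> dict[str, StrandedCoverage]:
    """Per-sample strand-specific coverage consistent with the count matrix.

    Noiseless mode spreads each transcript's count uniformly over its span;
    noise mode Poisson-resamples per-bin signal and adds a uniform background
    rate on both strands.
    """
    rng = _rng(config, 14)
    tdf = truth.transcripts
    res = config.gro_resolution_bp
    out: dict[str, StrandedCoverage] = {}
    for s in gro.sample_ids:
        counts = gro.counts[s]
        if not config.gro_noise and config.gro_background == 0:
            blocks: dict[str, dict[str, list[tuple[int, int, float]]]] = {
                "+": {c: [] for c in config.genome},
                "-": {c: [] for c in config.genome},
            }
            for tid, rec in tdf.iterrows():
                cnt = int(counts.loc[tid])
                if cnt == 0:
                    continue
                rate = cnt / (rec["end"] - rec["start"])
                blocks[rec["strand"]][rec["chrom"]].append((int(rec["start"]), int(rec["end"]), rate))
            plus = CoverageTrack.from_blocks(config.genome, blocks["+"])
            minus = CoverageTrack.from_blocks(config.genome, blocks["-"])
        else:
            arrays = {
                "+": {c: np.zeros(int(np.ceil(L / res))) for c, L in config.genome.items()},
                "-": {c: np.zeros(int(np.ceil(L / res))) for c, L in config.genome.items()},
            }
            for strand in ("+", "-"):
                for chrom in config.genome:
                    arrays[strand][chrom] += config.gro_background * res
            for tid, rec in tdf.iterrows():
                cnt = int(counts.loc[tid])
                if cnt == 0:
                    continue
                arr = arrays[rec["strand"]][rec["chrom"]]
                b0 = int(rec["start"]) // res
                b1 = int(np.ceil(int(rec["end"]) / res))
                arr[b0:b1] += cnt / (b1 - b0)
            for strand in ("+", "-"):
                for chrom in config.genome:
                    lam = arrays[strand][chrom]
                    drawn = rng.poisson(lam) if config.gro_noise else lam
                    arrays[strand][chrom] = drawn / res  # per-base rate
            plus = CoverageTrack.from_bin_values(config.genome, res, arrays["+"])
            minus = CoverageTrack.from_bin_values(config.genome, res, arrays["-"])
        out[s] = StrandedCoverage(plus, minus)
    return out
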