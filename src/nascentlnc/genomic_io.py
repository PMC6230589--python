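"""Genomic data structures and file I/O.

All coordinates are 0-based, half-open (BED convention) throughout.
Strand-specific coverage is carried as two non-negative tracks; minus-strand
signal is never negated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise ValueError("coordinates must be integers")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bases, ignoring strand. 0 if on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def edge_distance(self, other: "GenomicInterval") -> int | None:
        """Edge-to-edge distance in bp; 0 when overlapping; None across chroms."""
        if self.chrom != other.chrom:
            return None
        if self.overlap_bp(other) > 0:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass
class TranscriptUnit:
    """A called or annotated transcript unit with class and catalog labels."""

    interval: GenomicInterval
    id: str
    origin: str = "called"  # called | annotated
    unit_class: str = "unassigned"  # coding|known_lncRNA|novel_lncRNA|small_rna|unassigned
    db_id: str | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("called", "annotated"):
            raise ValueError(f"invalid origin {self.origin!r}")
        if self.unit_class in ("known_lncRNA", "novel_lncRNA") and self.interval.length <= 200:
            raise ValueError(f"lncRNA unit {self.id} must be > 200 bp")
        if (self.unit_class == "known_lncRNA") != (self.db_id is not None):
            raise ValueError("db_id must be set iff class is known_lncRNA")

    @property
    def tss(self) -> int:
        """Transcription start: ``start`` on '+', ``end - 1`` on '-'."""
        return self.interval.start if self.interval.strand != "-" else self.interval.end - 1


class CoverageTrack:
    """Piecewise-constant non-negative signal over a genome (one strand).

    Internally stores sorted non-overlapping blocks per chromosome plus a
    cumulative integral, so range sums are O(log n) rather than per-base.
    """

    def __init__(self, genome: Mapping[str, int]):
        for chrom, length in genome.items():
            if length <= 0:
                raise ValueError(f"chrom {chrom} has non-positive length")
        self.genome = dict(genome)
        # chrom -> (starts, ends, values, cum) where cum[i] = integral of blocks < i
        self._blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        empty = (np.empty(0), np.empty(0), np.empty(0), np.zeros(1))
        for chrom in genome:
            self._blocks[chrom] = empty

    # ----- construction -----------------------------------------------------

    @classmethod
    def from_blocks(
        cls,
        genome: Mapping[str, int],
        blocks: Mapping[str, Sequence[tuple[int, int, float]]],
    ) -> "CoverageTrack":
        """Build from per-chrom ``(start, end, value)`` blocks.

        Blocks may be unsorted but must not overlap; zero-valued blocks are
        dropped; negative values or out-of-genome blocks are errors.
        """
        track = cls(genome)
        for chrom, blk in blocks.items():
            if chrom not in track.genome:
                raise ValueError(f"unknown chrom {chrom!r}")
            if not blk:
                continue
            arr = np.asarray(blk, dtype=float)
            starts, ends, values = arr[:, 0], arr[:, 1], arr[:, 2]
            if np.any(values < 0):
                raise ValueError(f"negative signal on {chrom}")
            if np.any(starts < 0) or np.any(ends > track.genome[chrom]) or np.any(starts >= ends):
                raise ValueError(f"block outside chrom bounds on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping blocks on {chrom}")
            keep = values > 0
            starts, ends, values = starts[keep], ends[keep], values[keep]
            cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
            track._blocks[chrom] = (starts, ends, values, cum)
        return track

    @classmethod
    def from_bin_values(
        cls, genome: Mapping[str, int], resolution_bp: int, arrays: Mapping[str, np.ndarray]
    ) -> "CoverageTrack":
        """Build from dense per-bin values (value applies to each base of the bin)."""
        blocks: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, vals in arrays.items():
            length = genome[chrom]
            vals = np.asarray(vals, dtype=float)
            nz = np.nonzero(vals)[0]
            blk = []
            for i in nz:
                start = int(i) * resolution_bp
                end = min(start + resolution_bp, length)
                if start < length:
                    blk.append((start, end, float(vals[i])))
            blocks[chrom] = blk
        return cls.from_blocks(genome, blocks)

    # ----- queries ----------------------------------------------------------

    def _check(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.genome:
            raise ValueError(f"chrom {interval.chrom!r} not in genome")
        if interval.end > self.genome[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:[{interval.start},{interval.end}) beyond "
                f"chrom length {self.genome[interval.chrom]}"
            )

    def _integral_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """F(pos): total signal in [0, pos) per position; vectorized."""
        starts, ends, values, cum = self._blocks[chrom]
        pos = np.asarray(pos, dtype=float)
        if starts.size == 0:
            return np.zeros(pos.shape)
        j = np.searchsorted(starts, pos, side="right") - 1
        jc = np.clip(j, 0, starts.size - 1)
        inside = np.clip(np.minimum(pos, ends[jc]) - starts[jc], 0, None) * values[jc]
        out = cum[jc] + inside
        out[j < 0] = 0.0
        return out

    def sum(self, interval: GenomicInterval) -> float:
        """Total signal over the interval."""
        self._check(interval)
        f = self._integral_at(interval.chrom, np.array([interval.start, interval.end]))
        return float(f[1] - f[0])

    def mean(self, interval: GenomicInterval) -> float:
        """Mean per-base signal over the interval."""
        return self.sum(interval) / interval.length

    def total(self) -> float:
        return float(sum(blk[3][-1] for blk in self._blocks.values()))

    def binned(self, chrom: str, bin_bp: int) -> np.ndarray:
        """Per-bin signal sums over the whole chromosome (last bin may be short)."""
        length = self.genome[chrom]
        edges = np.arange(0, length + bin_bp, bin_bp, dtype=float)
        edges[-1] = min(edges[-1], length)
        f = self._integral_at(chrom, edges)
        return np.diff(f)

    def window_sums(self, chrom: str, window_bp: int, step_bp: int) -> tuple[np.ndarray, np.ndarray]:
        """Sliding-window sums; returns (window_starts, sums)."""
        length = self.genome[chrom]
        if length < window_bp:
            return np.empty(0, dtype=int), np.empty(0)
        starts = np.arange(0, length - window_bp + 1, step_bp)
        sums = self._integral_at(chrom, starts + window_bp) - self._integral_at(chrom, starts)
        return starts, sums

    def iter_blocks(self, chrom: str) -> Iterable[tuple[int, int, float]]:
        starts, ends, values, _ = self._blocks[chrom]
        for s, e, v in zip(starts, ends, values):
            yield int(s), int(e), float(v)

    @staticmethod
    def sum_of(tracks: Sequence["CoverageTrack"]) -> "CoverageTrack":
        """Pointwise sum of tracks sharing a genome."""
        if not tracks:
            raise ValueError("no tracks to sum")
        genome = tracks[0].genome
        for t in tracks[1:]:
            if t.genome != genome:
                raise ValueError("tracks have different genomes")
        blocks: dict[str, list[tuple[int, int, float]]] = {}
        for chrom in genome:
            edges = set()
            for t in tracks:
                starts, ends, _, _ = t._blocks[chrom]
                edges.update(starts.tolist())
                edges.update(ends.tolist())
            if not edges:
                blocks[chrom] = []
                continue
            pts = np.array(sorted(edges))
            left, right = pts[:-1], pts[1:]
            vals = np.zeros(left.shape)
            for t in tracks:
                f = t._integral_at(chrom, pts)
                vals += (f[1:] - f[:-1]) / (right - left)
            blk = [
                (int(s), int(e), float(v))
                for s, e, v in zip(left, right, vals)
                if v > 0
            ]
            blocks[chrom] = blk
        return CoverageTrack.from_blocks(genome, blocks)


@dataclass
class StrandedCoverage:
    """Plus/minus pair of coverage tracks over the same genome."""

    plus: CoverageTrack
    minus: CoverageTrack

    def __post_init__(self) -> None:
        if self.plus.genome != self.minus.genome:
            raise ValueError("plus/minus tracks must share a genome")

    @property
    def genome(self) -> dict[str, int]:
        return self.plus.genome

    def get(self, strand: str) -> CoverageTrack:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"stranded query requires '+' or '-', got {strand!r}")


@dataclass
class CountMatrix:
    """Feature-by-sample integer counts with condition labels and library sizes."""

    counts: pd.DataFrame
    condition: dict[str, str]
    library_size: dict[str, int]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate row ids: {dups[:5]}")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            if not np.allclose(self.counts.values, np.round(self.counts.values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for s in self.counts.columns:
            if s not in self.condition:
                raise ValueError(f"sample {s!r} missing condition label")
            if s not in self.library_size or self.library_size[s] <= 0:
                raise ValueError(f"sample {s!r} missing positive library size")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_of(self, cond: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition[s] == cond]

    def subset_rows(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(ids)].copy(), dict(self.condition), dict(self.library_size))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED3+ records as ``(interval, name, score)`` in file order.

    Missing name/score/strand columns default to ".", 0.0 and strand ".".
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                interval = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((interval, name, score))
    return records


def write_bed(records: Iterable[tuple[GenomicInterval, str, float]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for interval, name, score in records:
            fh.write(
                f"{interval.chrom}\t{interval.start}\t{interval.end}\t{name}\t{score:g}\t{interval.strand}\n"
            )


def units_to_bed(units: Sequence[TranscriptUnit], path: str | os.PathLike) -> None:
    """Write transcript units as BED6 with ``id|class|db_id`` packed in the name."""
    recs = []
    for u in units:
        name = f"{u.id}|{u.unit_class}|{u.db_id if u.db_id is not None else '.'}"
        recs.append((u.interval, name, 0.0))
    write_bed(recs, path)


def units_from_bed(path: str | os.PathLike, origin: str = "annotated") -> list[TranscriptUnit]:
    """Read transcript units written by :func:`units_to_bed`."""
    units = []
    for interval, name, _ in read_bed(path):
        parts = name.split("|")
        if len(parts) == 3:
            uid, klass, db = parts
            db_id = None if db == "." else db
        else:
            uid, klass, db_id = name, "unassigned", None
        units.append(TranscriptUnit(interval, uid, origin=origin, unit_class=klass, db_id=db_id))
    return units


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | os.PathLike, genome: Mapping[str, int]) -> CoverageTrack:
    """Read one bedGraph file into a coverage track.

    Uncovered bases have signal 0. Overlapping lines and intervals beyond the
    declared chromosome length are errors.
    """
    blocks: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: need 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed fields") from exc
            if chrom not in genome:
                raise ParseError(f"{path}:{lineno}: unknown chrom {chrom!r}")
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid interval [{start},{end})")
            if end > genome[chrom]:
                raise ParseError(
                    f"{path}:{lineno}: interval end {end} beyond chrom length {genome[chrom]}"
                )
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative signal {value}")
            blocks[chrom].append((start, end, value))
    try:
        return CoverageTrack.from_blocks(genome, blocks)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_strand_pair(
    path_plus: str | os.PathLike, path_minus: str | os.PathLike, genome: Mapping[str, int]
) -> StrandedCoverage:
    return StrandedCoverage(read_bedgraph(path_plus, genome), read_bedgraph(path_minus, genome))


def write_bedgraph(track: CoverageTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.genome):
            for start, end, value in track.iter_blocks(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def read_genome(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column chrom-sizes TSV."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: need chrom and length")
            genome[fields[0]] = int(fields[1])
    return genome


def write_genome(genome: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f"{chrom}\t{genome[chrom]}\n")


# ---------------------------------------------------------------------------
# count matrix TSV (+ sidecar metadata)
# ---------------------------------------------------------------------------

def _meta_path(path: str | os.PathLike) -> str:
    base = str(path)
    if base.endswith(".tsv"):
        base = base[: -len(".tsv")]
    return base + ".meta.tsv"


def write_matrix(matrix: CountMatrix, path: str | os.PathLike, meta_path: str | None = None) -> None:
    """Write counts as TSV (row ids in first column) plus a metadata sidecar."""
    matrix.counts.rename_axis("id").to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {
            "sample": matrix.sample_ids,
            "condition": [matrix.condition[s] for s in matrix.sample_ids],
            "library_size": [matrix.library_size[s] for s in matrix.sample_ids],
        }
    )
    meta.to_csv(meta_path or _meta_path(path), sep="\t", index=False)


def read_matrix(path: str | os.PathLike, meta_path: str | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df = df.rename_axis(None)
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate row ids")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    meta = pd.read_csv(meta_path or _meta_path(path), sep="\t")
    condition = dict(zip(meta["sample"].astype(str), meta["condition"].astype(str)))
    library_size = dict(zip(meta["sample"].astype(str), meta["library_size"].astype(int)))
    return CountMatrix(df.astype(np.int64), condition, library_size)
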