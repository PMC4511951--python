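"""Genomic-context classification of aligned reads and GC-content diagnostics.

FFPE RNA-seq libraries are usually built from rRNA-depleted total RNA and so
capture unspliced pre-mRNA: a large share of reads lands in introns, whose GC
content in human peaks near 53% and distorts the per-read GC histogram. FF
libraries built with oligo-dT mRNA selection do not show this. This module
classifies reads as mRNA / intronic / intergenic against a merged exon model,
applies the mRNA-region filter that removes the artifact, and quantifies GC
distributions before and after filtering.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError, ValidationError

logger = logging.getLogger(__name__)

#: Column order of a read table (BED6 + GC fraction).
READ_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "gc"]


class RegionLabel(str, Enum):
    """Exhaustive, mutually exclusive genomic context of a read."""

    MRNA = "MRNA"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"


@dataclass(frozen=True)
class Transcript:
    """One transcript model: sorted, non-overlapping exons on a chromosome."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"{self.transcript_id}: exon ({start},{end}) has start >= end"
                )
            if start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (first exon start, last exon end)."""
        return self.exons[0][0], self.exons[-1][-1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        )


@dataclass(frozen=True)
class GenomeAnnotation:
    """A collection of transcript models over a toy or real coordinate space."""

    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_chrom(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            out.setdefault(tx.chrom, []).append(tx)
        return out


class _ChromIndex(NamedTuple):
    """Merged, sorted intervals on one chromosome with length prefix sums."""

    starts: np.ndarray
    ends: np.ndarray
    cum: np.ndarray  # cum[i] = total bp of intervals [0, i)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> _ChromIndex:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in ivs:
        if merged and start <= merged[-1][1]:  # overlapping or adjacent
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    starts = np.array([m[0] for m in merged], dtype=np.int64)
    ends = np.array([m[1] for m in merged], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(ends - starts)])
    return _ChromIndex(starts, ends, cum)


@dataclass(frozen=True)
class RegionIndex:
    """Per-chromosome merged mRNA (exon union) and gene-span interval sets."""

    mrna: Mapping[str, _ChromIndex]
    genes: Mapping[str, _ChromIndex]

    @property
    def chroms(self) -> set[str]:
        return set(self.mrna) | set(self.genes)


def build_mrna_regions(annotation: GenomeAnnotation) -> RegionIndex:
    """Union of all exons per chromosome, merged and sorted, plus gene spans.

    The mRNA set is the merged union of every transcript's exons; the gene-span
    set is the merged union of transcript extents. Intronic territory is the
    latter minus the former; the complement of both is intergenic. An empty
    annotation yields an empty (valid) region set.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for tx in annotation.transcripts:
        exons.setdefault(tx.chrom, []).extend(tx.exons)
        spans.setdefault(tx.chrom, []).append(tx.span)
    return RegionIndex(
        mrna={c: _merge_intervals(v) for c, v in exons.items()},
        genes={c: _merge_intervals(v) for c, v in spans.items()},
    )


def _overlap_bp(idx: _ChromIndex, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Total bp of [start, end) covered by the merged interval set (vectorized)."""
    if len(idx.starts) == 0:
        return np.zeros(np.shape(start), dtype=np.int64)
    s = np.asarray(start, dtype=np.int64)
    e = np.asarray(end, dtype=np.int64)
    i0 = np.searchsorted(idx.ends, s, side="right")
    i1 = np.searchsorted(idx.starts, e, side="left")
    has = i1 > i0
    i0c = np.minimum(i0, len(idx.starts) - 1)
    i1c = np.maximum(i1 - 1, 0)
    total = idx.cum[i1] - idx.cum[i0c]
    left = np.maximum(0, s - idx.starts[i0c])
    right = np.maximum(0, idx.ends[i1c] - e)
    return np.where(has, total - left - right, 0)


class ReadRecord(NamedTuple):
    """One aligned read's interval, strand, and GC fraction (may be NaN)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    gc: float = float("nan")


def reads_to_frame(reads: Iterable[ReadRecord]) -> pd.DataFrame:
    """Build the canonical read table from individual records."""
    return pd.DataFrame(list(reads), columns=READ_COLUMNS)


def _validate_reads(reads: pd.DataFrame) -> None:
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValidationError(f"read table lacks columns: {missing}")
    bad = reads["start"] >= reads["end"]
    if bad.any():
        rid = reads.loc[bad, "read_id"].iloc[0]
        raise ValidationError(f"read {rid}: start >= end")


def classify_reads(
    reads: pd.DataFrame,
    regions: RegionIndex,
    min_overlap_bp: int = 1,
    min_overlap_fraction: float | None = None,
) -> pd.Series:
    """Region label per read.

    A read is MRNA when its overlap with the merged exon set reaches
    ``min_overlap_bp`` (and, when given, ``min_overlap_fraction`` of the read
    length); otherwise INTRONIC when it touches any gene span; otherwise
    INTERGENIC. Reads on chromosomes absent from the coordinate space raise
    :class:`ClassificationError` naming the offending read.
    """
    _validate_reads(reads)
    labels = pd.Series(RegionLabel.INTERGENIC.value, index=reads.index, dtype=object)
    known = regions.chroms
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in known:
            rid = grp["read_id"].iloc[0]
            raise ClassificationError(f"read {rid}: unknown chromosome {chrom!r}")
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        need = np.full(len(grp), max(int(min_overlap_bp), 1), dtype=np.int64)
        if min_overlap_fraction is not None:
            need = np.maximum(need, np.ceil(min_overlap_fraction * (e - s)).astype(np.int64))
        mrna_ov = (
            _overlap_bp(regions.mrna[chrom], s, e) if chrom in regions.mrna else np.zeros(len(grp))
        )
        gene_ov = (
            _overlap_bp(regions.genes[chrom], s, e) if chrom in regions.genes else np.zeros(len(grp))
        )
        lab = np.where(
            mrna_ov >= need,
            RegionLabel.MRNA.value,
            np.where(gene_ov >= 1, RegionLabel.INTRONIC.value, RegionLabel.INTERGENIC.value),
        )
        labels.loc[grp.index] = lab
    return labels


def classify_read(
    read: ReadRecord,
    regions: RegionIndex,
    min_overlap_bp: int = 1,
    min_overlap_fraction: float | None = None,
) -> RegionLabel:
    """Classify a single read (thin wrapper over :func:`classify_reads`)."""
    frame = reads_to_frame([read])
    label = classify_reads(frame, regions, min_overlap_bp, min_overlap_fraction).iloc[0]
    return RegionLabel(label)


def filter_mrna(
    reads: pd.DataFrame,
    regions: RegionIndex,
    min_overlap_bp: int = 1,
    min_overlap_fraction: float | None = None,
) -> pd.DataFrame:
    """Retain exactly the MRNA-classified reads, preserving input order."""
    labels = classify_reads(reads, regions, min_overlap_bp, min_overlap_fraction)
    kept = reads.loc[labels == RegionLabel.MRNA.value].copy()
    logger.info("filter_mrna: %d of %d reads retained", len(kept), len(reads))
    return kept


@dataclass(frozen=True)
class GCHistogram:
    """Per-read GC content binned at integer percent 0..100.

    ``density`` sums to 1 when ``n_reads`` > 0; reads with undefined GC are
    excluded and counted in ``n_skipped``.
    """

    density: np.ndarray
    n_reads: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.density.shape != (101,):
            raise ValidationError("GC histogram requires exactly 101 bins")

    @property
    def mode_bin(self) -> int:
        """Highest-density bin (ties broken toward the lowest bin)."""
        return int(np.argmax(self.density))


def gc_histogram(reads: pd.DataFrame) -> GCHistogram:
    """Histogram of per-read GC fractions, bin = round(100·gc) half-up."""
    gc = pd.to_numeric(reads["gc"], errors="coerce")
    valid = gc.notna()
    g = gc[valid].to_numpy(dtype=float)
    if ((g < 0) | (g > 1)).any():
        raise ValidationError("gc_fraction outside [0, 1]")
    n = int(valid.sum())
    counts = np.bincount(np.floor(g * 100 + 0.5).astype(int), minlength=101)
    density = counts / n if n > 0 else np.zeros(101)
    return GCHistogram(density=density.astype(float), n_reads=n, n_skipped=int((~valid).sum()))


class HistogramMaxDiff(NamedTuple):
    value: float
    bin: int


def histogram_max_diff(h1: GCHistogram, h2: GCHistogram) -> HistogramMaxDiff:
    """Largest absolute per-bin density difference and its bin (lowest on ties)."""
    if h1.n_reads == 0 or h2.n_reads == 0:
        raise ValidationError("histogram_max_diff requires non-empty histograms")
    diff = np.abs(h1.density - h2.density)
    return HistogramMaxDiff(value=float(diff.max()), bin=int(np.argmax(diff)))


@dataclass(frozen=True)
class RegionSummary:
    """Counts and fractions of reads per genomic context."""

    counts: dict[str, int]
    fractions: dict[str, float] | None
    total: int
    #: True when fractions are defined (total > 0).
    defined: bool = field(default=True)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "fractions": self.fractions,
            "total": self.total,
            "defined": self.defined,
        }


def region_fractions(
    reads: pd.DataFrame,
    regions: RegionIndex,
    labels: pd.Series | None = None,
    min_overlap_bp: int = 1,
) -> RegionSummary:
    """Per-label read counts and fractions; fractions sum to 1 when defined."""
    if labels is None:
        labels = classify_reads(reads, regions, min_overlap_bp=min_overlap_bp)
    counts = {lab.value: int((labels == lab.value).sum()) for lab in RegionLabel}
    total = len(labels)
    if total == 0:
        return RegionSummary(counts=counts, fractions=None, total=0, defined=False)
    fractions = {k: v / total for k, v in counts.items()}
    return RegionSummary(counts=counts, fractions=fractions, total=total)
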