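"""File dialects: BED12/GTF annotation, BED6+GC reads, counts TSV, VCF.

Internal coordinates are 0-based half-open (BED native); GTF records are
converted on read and VCF positions are converted 1-based↔0-based at the
boundary only where interval arithmetic needs them — variant tables keep the
1-based VCF positions. Format violations raise with file/line context rather
than being skipped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .errors import ValidationError
from .expression_concordance import Platform, Preservation, SampleMeta
from .region_gc import GCHistogram, GenomeAnnotation, Transcript

# ---------------------------------------------------------------------------
# annotation


def write_annotation_bed12(annotation: GenomeAnnotation, path: str | Path) -> None:
    """BED12; the name field carries ``transcript_id;gene_id``."""
    with open(path, "w") as fh:
        for tx in annotation.transcripts:
            start, end = tx.span
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            starts = ",".join(str(s - start) for s, _ in tx.exons)
            fh.write(
                "\t".join(
                    [
                        tx.chrom,
                        str(start),
                        str(end),
                        f"{tx.transcript_id};{tx.gene_id}",
                        "0",
                        tx.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(tx.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_annotation_bed12(path: str | Path) -> GenomeAnnotation:
    transcripts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValidationError(f"{path}:{lineno}: BED12 needs 12 columns")
            try:
                chrom, start = fields[0], int(fields[1])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValidationError(f"{path}:{lineno}: block count mismatch")
            tid, _, gid = name.partition(";")
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            transcripts.append(
                Transcript(tid, chrom, strand, exons, gid or tid)
            )
    return GenomeAnnotation(transcripts=tuple(transcripts))


def write_annotation_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Exon-level GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for tx in annotation.transcripts:
            for start, end in tx.exons:
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            tx.chrom,
                            "ffpeqc",
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_annotation_gtf(path: str | Path) -> GenomeAnnotation:
    """Assemble transcripts from GTF exon records (converted to 0-based)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValidationError(f"{path}:{lineno}: GTF needs 9 columns")
            if fields[2] != "exon":
                continue
            try:
                start, end = int(fields[3]) - 1, int(fields[4])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            attrs = dict(
                (part.split(" ", 1)[0], part.split(" ", 1)[1].strip('"'))
                for part in (p.strip() for p in fields[8].split(";"))
                if " " in part
            )
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValidationError(f"{path}:{lineno}: exon without transcript_id")
            exons.setdefault(tid, []).append((start, end))
            info[tid] = (fields[0], fields[6], attrs.get("gene_id", tid))
    transcripts = []
    for tid in exons:
        chrom, strand, gid = info[tid]
        transcripts.append(
            Transcript(tid, chrom, strand, tuple(sorted(exons[tid])), gid)
        )
    transcripts.sort(key=lambda t: t.transcript_id)
    return GenomeAnnotation(transcripts=tuple(transcripts))


# ---------------------------------------------------------------------------
# reads (BED6 + GC column)

_READ_HEADER = ["chrom", "start", "end", "read_id", "score", "strand", "gc"]


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["end"],
            "read_id": reads["read_id"],
            "score": 0,
            "strand": reads["strand"],
            "gc": reads["gc"].map(lambda g: f"{g:.6f}"),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, names=_READ_HEADER)
    if frame[["start", "end"]].isna().any().any():
        raise ValidationError(f"{path}: malformed read intervals")
    return frame[["read_id", "chrom", "start", "end", "strand", "gc"]]


# ---------------------------------------------------------------------------
# counts and sample metadata


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene or sample ids")
    if (counts.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative count entry")
    return counts


def write_sample_meta_tsv(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "subject_id": s.subject_id,
            "preservation": s.preservation.value,
            "platform": s.platform.value,
            "rin": "" if s.rin is None else f"{s.rin:.2f}",
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sample_meta_tsv(path: str | Path) -> list[SampleMeta]:
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    out = []
    for _, row in frame.iterrows():
        rin = row.get("rin")
        out.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                preservation=Preservation(row["preservation"]),
                platform=Platform(row.get("platform", "RNASEQ")),
                rin=None if pd.isna(rin) else float(rin),
            )
        )
    return out


# ---------------------------------------------------------------------------
# variants (minimal VCF with DP/AD depths in INFO)

def write_vcf(variants: pd.DataFrame, path: str | Path) -> None:
    """Minimal single-contig-set VCF; positions are written 1-based as given."""
    contigs = variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alternate allele depth">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in variants.iterrows():
            vid = row.get("variant_id", ".") or "."
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\tDP={int(row['total_depth'])};AD={int(row['alt_depth'])}\n"
            )


def read_vcf(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a minimal VCF (via pysam) into the canonical variant table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValidationError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}; split upstream"
                )
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,  # pysam reports the 1-based VCF position
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "alt_depth": int(rec.info.get("AD", 0)),
                    "total_depth": int(rec.info.get("DP", 0)),
                    "variant_id": rec.id or "",
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "alt_depth", "total_depth", "variant_id"],
    )
    if sample_id is not None:
        frame.insert(0, "sample_id", sample_id)
    return frame


# ---------------------------------------------------------------------------
# coverage, histograms and small JSON artifacts


def write_coverage_tsv(coverage: Mapping[str, "pd.Series | list | tuple"], path: str | Path) -> None:
    """(transcript_id, comma-separated per-base coverage) table."""
    with open(path, "w") as fh:
        for tid, cov in coverage.items():
            fh.write(tid + "\t" + ",".join(str(int(c)) for c in cov) + "\n")


def read_coverage_tsv(path: str | Path) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                tid, values = line.split("\t")
                out[tid] = [float(v) for v in values.split(",")]
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gc_histogram_tsv(hist: GCHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {"bin": range(101), "density": hist.density}
    ).to_csv(path, sep="\t", index=False)


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)
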