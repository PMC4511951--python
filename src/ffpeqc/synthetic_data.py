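"""Synthetic FF/FFPE data with ground-truth labels for every stage.

The generator emulates the contrasts between fresh-frozen (FF, poly-A
selected) and formalin-fixed (FFPE, rRNA-depleted) RNA-seq that the analysis
modules diagnose:

* intronic read contamination in FFPE libraries with a GC mode near 53%,
  absent from FF libraries;
* a 3' coverage bias in FF samples growing with transcript length and with
  RNA degradation (lower RIN), while FFPE profiles stay flat;
* paired FF/FFPE tumor count matrices sharing true tumor-vs-normal fold
  changes, with FFPE attenuation of low-abundance genes and per-subject
  tumor heterogeneity shared by the matched columns;
* variant tables with true somatic SNVs plus FFPE-specific C>T/G>A
  deamination artifacts at allele fractions below 0.5 and zero DNA support.

All randomness flows from one integer seed through per-stage
``numpy.random.default_rng`` streams, so identical configurations reproduce
bit-identical outputs. Generation order is fixed: annotation → reads →
coverage → counts → variants.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, GenerationError
from .expression_concordance import Platform, Preservation, SampleMeta
from .region_gc import GenomeAnnotation, RegionLabel, Transcript

# fixed per-stage stream indices (generation order)
_STAGE_ANNOTATION = 0
_STAGE_READS = 1
_STAGE_COVERAGE = 2
_STAGE_COUNTS = 3
_STAGE_VARIANTS = 4
_STAGE_SEQUENCES = 5

CHROM = "chr1"


@dataclass(frozen=True)
class SimulationConfig:
    """All generative knobs, with defaults set to the study conditions.

    Proportions live in [0, 1]; ``artifact_af_range`` must stay strictly
    below 0.5 (the deamination artifacts are sub-clonal by construction).
    """

    seed: int = 0
    # annotation
    n_transcripts: int = 300
    length_range_bp: tuple[int, int] = (500, 30_000)
    # reads / GC
    n_reads_per_sample: int = 100_000
    read_length_bp: int = 100
    intronic_fraction_ffpe: float = 0.4
    intronic_fraction_ff: float = 0.0
    gc_mrna_mean: float = 0.45
    gc_mrna_sd: float = 0.08
    gc_intron_mean: float = 0.53
    gc_intron_sd: float = 0.02
    # coverage
    bias_coeff: float = 0.2  # per unit (10 - RIN) per log2-kbp
    coverage_depth: float = 50.0
    # counts
    n_genes: int = 5000
    n_tumor_pairs: int = 6
    n_normals: int = 7
    dispersion: float = 0.05
    lowexpr_attenuation: float = 0.7
    lowexpr_log2_cutoff: float = 10.0
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.5
    fc_nonnull_fraction: float = 0.1
    fc_log2_sd: float = 2.0
    subject_effect_sd: float = 0.3
    library_size_sd: float = 0.15
    n_nanostring_genes: int = 0
    nanostring_noise_sd: float = 0.3
    # variants
    n_true_variants: int = 100
    n_artifact_variants: int = 150
    artifact_af_range: tuple[float, float] = (0.12, 0.45)
    clonal_fraction: float = 0.5
    dna_depth_mean: float = 60.0
    low_dna_depth_fraction: float = 0.10
    rna_variant_depth_mean: float = 50.0

    def __post_init__(self) -> None:
        props = {
            "intronic_fraction_ffpe": self.intronic_fraction_ffpe,
            "intronic_fraction_ff": self.intronic_fraction_ff,
            "gc_mrna_mean": self.gc_mrna_mean,
            "gc_intron_mean": self.gc_intron_mean,
            "lowexpr_attenuation": self.lowexpr_attenuation,
            "fc_nonnull_fraction": self.fc_nonnull_fraction,
            "low_dna_depth_fraction": self.low_dna_depth_fraction,
            "clonal_fraction": self.clonal_fraction,
        }
        for name, value in props.items():
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.length_range_bp
        if lo < 1 or lo > hi:
            raise ConfigurationError(f"invalid length range {self.length_range_bp}")
        alo, ahi = self.artifact_af_range
        if not (0 <= alo <= ahi < 0.5):
            raise ConfigurationError(
                f"artifact_af_range must satisfy 0 <= lo <= hi < 0.5, got {self.artifact_af_range}"
            )
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.bias_coeff < 0:
            raise ConfigurationError("bias_coeff must be non-negative")
        for name in ("n_transcripts", "n_genes", "n_reads_per_sample", "read_length_bp"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")


@dataclass
class TruthLabels:
    """Ground-truth labels keyed by generated entity ids."""

    read_region_truth: dict[str, str] = field(default_factory=dict)
    gene_log2fc_truth: dict[str, float] = field(default_factory=dict)
    variant_is_artifact: dict[str, bool] = field(default_factory=dict)
    variant_true_dna_af: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "read_region_truth": self.read_region_truth,
            "gene_log2fc_truth": self.gene_log2fc_truth,
            "variant_is_artifact": self.variant_is_artifact,
            "variant_true_dna_af": self.variant_true_dna_af,
        }


def _rng(config: SimulationConfig, stage: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage, *extra])


def _storage_code(storage: str) -> int:
    if storage not in (Preservation.FF.value, Preservation.FFPE.value):
        raise ConfigurationError(f"storage must be FF or FFPE, got {storage!r}")
    return 0 if storage == Preservation.FF.value else 1


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Toy transcript models with alternating exon/intron structure.

    Spliced lengths are drawn log-uniformly over ``length_range_bp``; each
    transcript gets 1–8 exons (few for very short transcripts) separated by
    200–2000 bp introns, and transcripts are laid head-to-tail along one toy
    chromosome with 2–10 kbp intergenic gaps. One gene per transcript.
    """
    rng = _rng(config, _STAGE_ANNOTATION)
    lo, hi = config.length_range_bp
    n = config.n_transcripts
    if lo == hi:
        lengths = np.full(n, lo, dtype=int)
    else:
        lengths = np.round(
            np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        ).astype(int)
        lengths = np.clip(lengths, lo, hi)
    transcripts = []
    cursor = 1000
    for i, length in enumerate(lengths):
        length = int(length)
        if length < 300:
            n_exons = 1
        else:
            n_exons = int(rng.integers(2, min(8, length // 150) + 1))
        if n_exons > 1:
            cuts = np.sort(rng.choice(length - 1, size=n_exons - 1, replace=False) + 1)
            exon_lens = np.diff(np.concatenate([[0], cuts, [length]]))
            intron_lens = rng.integers(200, 2001, size=n_exons - 1)
        else:
            exon_lens = np.array([length])
            intron_lens = np.array([], dtype=int)
        exons = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            Transcript(
                transcript_id=f"tx{i:04d}",
                chrom=CHROM,
                strand=strand,
                exons=tuple(exons),
                gene_id=f"g{i:05d}",
            )
        )
        cursor = pos + int(rng.integers(2000, 10_001))
    return GenomeAnnotation(transcripts=tuple(transcripts))


# ---------------------------------------------------------------------------
# reads


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _place_reads(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    n: int,
    read_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly place n reads fully inside the given intervals, weighted by
    interval length; reads are clipped to fit short intervals."""
    starts = np.array([s for s, _ in intervals], dtype=np.int64)
    lens = np.array([e - s for s, e in intervals], dtype=np.int64)
    probs = lens / lens.sum()
    pick = rng.choice(len(intervals), size=n, p=probs)
    rl = np.minimum(read_length, lens[pick])
    offset = rng.integers(0, lens[pick] - rl + 1)
    s = starts[pick] + offset
    return s, s + rl


def simulate_reads(
    annotation: GenomeAnnotation, storage: str, config: SimulationConfig
) -> tuple[pd.DataFrame, TruthLabels]:
    """Reads placed inside exons or introns with storage-dependent mixing.

    The intronic proportion is ``intronic_fraction_ffpe`` for FFPE samples and
    ``intronic_fraction_ff`` for FF; GC per read is truncated-normal with the
    exonic (mRNA) or intronic parameters. Every read is labeled in the truth.
    """
    code = _storage_code(storage)
    frac = config.intronic_fraction_ffpe if code else config.intronic_fraction_ff
    rng = _rng(config, _STAGE_READS, code)
    exons = [iv for tx in annotation.transcripts for iv in tx.exons]
    introns = [iv for tx in annotation.transcripts for iv in tx.introns]
    if frac > 0 and not introns:
        raise GenerationError(
            "annotation has no introns but an intronic fraction > 0 was requested"
        )
    n = config.n_reads_per_sample
    is_intron = rng.random(n) < frac
    n_in = int(is_intron.sum())
    start = np.empty(n, dtype=np.int64)
    end = np.empty(n, dtype=np.int64)
    gc = np.empty(n, dtype=float)
    if n - n_in:
        s, e = _place_reads(rng, exons, n - n_in, config.read_length_bp)
        start[~is_intron], end[~is_intron] = s, e
        gc[~is_intron] = _truncnorm(rng, config.gc_mrna_mean, config.gc_mrna_sd, n - n_in)
    if n_in:
        s, e = _place_reads(rng, introns, n_in, config.read_length_bp)
        start[is_intron], end[is_intron] = s, e
        gc[is_intron] = _truncnorm(rng, config.gc_intron_mean, config.gc_intron_sd, n_in)
    read_ids = np.array([f"{storage}_r{i:06d}" for i in range(n)])
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    reads = pd.DataFrame(
        {
            "read_id": read_ids,
            "chrom": CHROM,
            "start": start,
            "end": end,
            "strand": strands,
            "gc": gc,
        }
    )
    truth = TruthLabels(
        read_region_truth={
            rid: (RegionLabel.INTRONIC.value if flag else RegionLabel.MRNA.value)
            for rid, flag in zip(read_ids, is_intron)
        }
    )
    return reads, truth


# ---------------------------------------------------------------------------
# coverage


def bias_exponent(storage: str, rin: float, spliced_length: int, bias_coeff: float) -> float:
    """3'-bias exponent β for one transcript.

    Expected coverage at normalized position x is proportional to exp(β·x)
    with β = bias_coeff · max(0, 10 − RIN) · log2(length / 1 kbp) for FF and
    β = 0 for FFPE; β is clipped at 0 (no 5' bias for sub-kbp transcripts) so
    it is non-decreasing in length and non-increasing in RIN.
    """
    if _storage_code(storage) == 1:
        return 0.0
    return bias_coeff * max(0.0, 10.0 - rin) * max(0.0, np.log2(spliced_length / 1000.0))


def simulate_coverage(
    annotation: GenomeAnnotation,
    storage: str,
    rin: float,
    config: SimulationConfig,
) -> dict[str, np.ndarray]:
    """Per-transcript base-level coverage arrays in genomic orientation.

    Observed coverage is Poisson around ``coverage_depth`` scaled by the
    exp(β·x) positional trend (x runs 5'→3'; the array is returned in genomic
    orientation, i.e. reversed for minus-strand transcripts).
    """
    if not 1 <= rin <= 10:
        raise ConfigurationError(f"RIN must be in [1, 10], got {rin}")
    code = _storage_code(storage)
    rng = _rng(config, _STAGE_COVERAGE, code)
    out: dict[str, np.ndarray] = {}
    for tx in annotation.transcripts:
        length = tx.spliced_length
        beta = bias_exponent(storage, rin, length, config.bias_coeff)
        x = (np.arange(length) + 0.5) / length
        weight = np.exp(beta * x)
        lam = config.coverage_depth * weight / weight.mean()
        cov = rng.poisson(lam).astype(float)
        if tx.strand == "-":
            cov = cov[::-1]
        out[tx.transcript_id] = cov
    return out


# ---------------------------------------------------------------------------
# counts


class ExpressionData(NamedTuple):
    """Count matrix, sample annotations and truth; NanoString columns are a
    separate matrix over a gene subset (None unless requested)."""

    counts: pd.DataFrame
    samples: list[SampleMeta]
    truth: TruthLabels
    nanostring: pd.DataFrame | None
    nanostring_samples: list[SampleMeta]


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimulationConfig) -> ExpressionData:
    """Paired FF/FFPE tumor count matrices plus a normal reference panel.

    Per-gene baselines are log-normal; a ``fc_nonnull_fraction`` of genes
    carries a shared tumor log2 fold change φ ~ N(0, fc_log2_sd). Each tumor
    subject adds a per-gene heterogeneity effect shared by its FF and FFPE
    columns. FFPE tumor means are multiplied by ``lowexpr_attenuation`` for
    genes whose baseline log2 mean sits below ``lowexpr_log2_cutoff``. Counts
    are negative-binomial with the configured dispersion, and every sample
    gets a log-normal library-size factor. When ``n_nanostring_genes`` > 0,
    NanoString-style columns for the tumor samples are resampled on a random
    gene subset with per-gene probe-efficiency noise.
    """
    if config.n_genes < 2 or config.n_normals < 2 or config.n_tumor_pairs < 1:
        raise ConfigurationError(
            "need n_genes >= 2, n_normals >= 2 and n_tumor_pairs >= 1"
        )
    rng = _rng(config, _STAGE_COUNTS)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    log2_mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    mu = 2.0**log2_mu
    nonnull = rng.random(config.n_genes) < config.fc_nonnull_fraction
    phi = np.where(nonnull, rng.normal(0.0, config.fc_log2_sd, config.n_genes), 0.0)
    attenuated = log2_mu < config.lowexpr_log2_cutoff
    atten = np.where(attenuated, config.lowexpr_attenuation, 1.0)

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    true_means: dict[str, np.ndarray] = {}

    def _lib() -> float:
        return float(2.0 ** rng.normal(0.0, config.library_size_sd))

    for k in range(config.n_normals):
        sid = f"N{k + 1}"
        mean = mu * _lib()
        columns[sid] = _nb(rng, mean, config.dispersion)
        samples.append(SampleMeta(sid, f"norm{k + 1}", Preservation.NORMAL))
    for j in range(config.n_tumor_pairs):
        subject = f"subj{j + 1}"
        u = rng.normal(0.0, config.subject_effect_sd, config.n_genes)
        tumor_mu = mu * 2.0 ** (phi + u)
        rin_ff = float(rng.uniform(5.0, 9.0))
        rin_ffpe = float(rng.uniform(1.5, 3.0))
        for storage, extra, rin in (
            (Preservation.FF, 1.0, rin_ff),
            (Preservation.FFPE, atten, rin_ffpe),
        ):
            sid = f"{storage.value}_{subject}"
            mean = tumor_mu * extra * _lib()
            columns[sid] = _nb(rng, mean, config.dispersion)
            true_means[sid] = tumor_mu * extra
            samples.append(SampleMeta(sid, subject, storage, rin=rin))

    counts = pd.DataFrame(columns, index=genes)
    truth = TruthLabels(gene_log2fc_truth=dict(zip(genes, phi.astype(float))))

    nanostring = None
    ns_samples: list[SampleMeta] = []
    if config.n_nanostring_genes > 0:
        subset_idx = np.sort(
            rng.choice(config.n_genes, size=min(config.n_nanostring_genes, config.n_genes), replace=False)
        )
        probe = 2.0 ** rng.normal(0.0, config.nanostring_noise_sd, len(subset_idx))
        ns_cols = {}
        for meta in samples:
            if meta.preservation is Preservation.NORMAL:
                continue
            mean = true_means[meta.sample_id][subset_idx] * probe * _lib()
            ns_cols[f"NS_{meta.sample_id}"] = _nb(rng, mean, config.dispersion)
            ns_samples.append(
                SampleMeta(
                    f"NS_{meta.sample_id}",
                    meta.subject_id,
                    meta.preservation,
                    Platform.NANOSTRING,
                )
            )
        nanostring = pd.DataFrame(ns_cols, index=[genes[i] for i in subset_idx])
    return ExpressionData(counts, samples, truth, nanostring, ns_samples)


# ---------------------------------------------------------------------------
# variants

_NON_DEAMINATION = tuple(
    f"{r}>{a}"
    for r in "ACGT"
    for a in "ACGT"
    if r != a and f"{r}>{a}" not in ("C>T", "G>A")
)


class VariantData(NamedTuple):
    rna_calls: pd.DataFrame
    dna_evidence: pd.DataFrame
    truth: TruthLabels


def simulate_variants(
    config: SimulationConfig, storage: str, sample_id: str | None = None
) -> VariantData:
    """True somatic SNVs plus (for FFPE) deamination artifacts.

    True variants draw DNA allele fractions from a clonal/subclonal mixture
    (AF 0.5 with probability ``clonal_fraction``, else Uniform(0.1, 0.4));
    DNA depth is Poisson(``dna_depth_mean``) with a ``low_dna_depth_fraction``
    of loci forced below 10X, and RNA evidence is a binomial resample of the
    true AF. True variants use non-deamination substitution classes so that
    artifact truth coincides with the deamination-filter action. For FFPE
    storage, ``n_artifact_variants`` extra loci carry C>T or G>A substitutions
    with RNA AF uniform in ``artifact_af_range`` and zero DNA alt depth; FF
    samples get no artifacts.
    """
    code = _storage_code(storage)
    sample_id = sample_id or f"{storage}_sample"
    rng = _rng(config, _STAGE_VARIANTS, code, zlib.crc32(sample_id.encode()) % 2**31)
    n_true = config.n_true_variants
    n_art = config.n_artifact_variants if code == 1 else 0

    records = []
    truth = TruthLabels()
    pos = 1000
    for i in range(n_true):
        vid = f"v{i:05d}"
        sub = _NON_DEAMINATION[rng.integers(len(_NON_DEAMINATION))]
        ref, alt = sub.split(">")
        true_af = 0.5 if rng.random() < config.clonal_fraction else float(rng.uniform(0.1, 0.4))
        dna_depth = int(rng.poisson(config.dna_depth_mean))
        if rng.random() < config.low_dna_depth_fraction:
            dna_depth = int(rng.integers(0, 10))
        dna_alt = int(rng.binomial(dna_depth, true_af)) if dna_depth else 0
        rna_depth = max(1, int(rng.poisson(config.rna_variant_depth_mean)))
        rna_alt = max(1, int(rng.binomial(rna_depth, true_af)))
        records.append((vid, pos, ref, alt, rna_alt, rna_depth, dna_alt, dna_depth))
        truth.variant_is_artifact[vid] = False
        truth.variant_true_dna_af[vid] = true_af
        pos += 500
    for i in range(n_art):
        vid = f"a{i:05d}"
        sub = "C>T" if rng.random() < 0.5 else "G>A"
        ref, alt = sub.split(">")
        af = float(rng.uniform(*config.artifact_af_range))
        rna_depth = max(5, int(rng.poisson(config.rna_variant_depth_mean)))
        rna_alt = int(np.clip(round(af * rna_depth), 1, (rna_depth - 1) // 2))
        dna_depth = int(rng.poisson(config.dna_depth_mean))
        if rng.random() < config.low_dna_depth_fraction:
            dna_depth = int(rng.integers(0, 10))
        records.append((vid, pos, ref, alt, rna_alt, rna_depth, 0, dna_depth))
        truth.variant_is_artifact[vid] = True
        truth.variant_true_dna_af[vid] = 0.0
        pos += 500

    frame = pd.DataFrame(
        records,
        columns=["variant_id", "pos", "ref", "alt", "rna_alt", "rna_depth", "dna_alt", "dna_depth"],
    )
    rna_calls = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": CHROM,
            "pos": frame["pos"],
            "ref": frame["ref"],
            "alt": frame["alt"],
            "alt_depth": frame["rna_alt"],
            "total_depth": frame["rna_depth"],
            "variant_id": frame["variant_id"],
        }
    )
    dna_evidence = pd.DataFrame(
        {
            "chrom": CHROM,
            "pos": frame["pos"],
            "ref": frame["ref"],
            "alt": frame["alt"],
            "alt_depth": frame["dna_alt"],
            "total_depth": frame["dna_depth"],
        }
    )
    return VariantData(rna_calls, dna_evidence, truth)


# ---------------------------------------------------------------------------
# optional sequence emission (FASTA/SAM round-trip support only)


def emit_read_sequences(reads: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    """ACGT sequences whose GC content matches each read's gc fraction.

    Only needed for FASTA/SAM round-trip tests; GC itself is simulated
    directly because nothing downstream consumes nucleotides.
    """
    rng = _rng(config, _STAGE_SEQUENCES)
    seqs = []
    for _, row in reads.iterrows():
        length = int(row["end"] - row["start"])
        n_gc = int(round(float(row["gc"]) * length))
        letters = np.concatenate(
            [
                rng.choice(list("GC"), size=n_gc),
                rng.choice(list("AT"), size=length - n_gc),
            ]
        )
        rng.shuffle(letters)
        seqs.append("".join(letters))
    return pd.Series(seqs, index=reads.index, name="sequence")
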