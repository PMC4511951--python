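"""End-to-end orchestration: config validation, stage execution, reporting.

A run config is a flat YAML mapping (documented keys below). Stages execute
in dependency order — simulate → gcfilter → coverage → expression → variants
— each writing its artifacts under the output directory and contributing one
section to the consolidated report. A fixed config + seed reproduces every
stage output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as fio
from . import __version__
from .errors import StageError
from .expression_concordance import (
    Preservation,
    cluster_samples,
    correlation_matrix,
    fold_change_correlation,
    log_fold_changes,
    lowess_curve,
    quantile_normalize,
)
from .region_gc import (
    RegionLabel,
    build_mrna_regions,
    classify_reads,
    gc_histogram,
    histogram_max_diff,
    region_fractions,
)
from .synthetic_data import SimulationConfig, simulate_annotation, simulate_counts, simulate_coverage, simulate_reads, simulate_variants
from .transcript_coverage import bias_report, build_profiles
from .variant_concordance import (
    apply_ffpe_filter,
    classify_pairs,
    pair_variants,
    spectrum,
    summarize_concordance,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "gcfilter", "coverage", "expression", "variants")

#: Threshold keys with their valid ranges (inclusive).
_THRESHOLD_RANGES = {
    "min_overlap_bp": (1, 10_000),
    "n_bins": (10, 1000),
    "lowess_span": (1e-6, 1.0),
    "rna_af_min": (0.0, 1.0),
    "dna_af_min": (0.0, 1.0),
    "dna_cov_min": (0, 10_000),
    "ffpe_af_threshold": (0.0, 1.0),
    "rin_ff": (1.0, 10.0),
    "rin_ffpe": (1.0, 10.0),
}


@dataclass
class RunConfig:
    """Validated run configuration (flat key-value dialect)."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # optional input paths; the simulate stage fills the gaps
    annotation: Path | None = None
    reads_ff: Path | None = None
    reads_ffpe: Path | None = None
    counts: Path | None = None
    meta: Path | None = None
    rna_vcf: Path | None = None
    dna_vcf: Path | None = None
    # analysis thresholds (defaults are the published values)
    min_overlap_bp: int = 1
    n_bins: int = 100
    lowess_span: float = 0.3
    rna_af_min: float = 0.10
    dna_af_min: float = 0.10
    dna_cov_min: int = 10
    ffpe_af_threshold: float = 0.50
    rin_ff: float = 5.0
    rin_ffpe: float = 2.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def validate_config(raw: dict, base_dir: Path | None = None) -> tuple[RunConfig | None, list[str]]:
    """Check a raw mapping; returns (config, []) or (None, aggregated errors)."""
    errors: list[str] = []
    raw = dict(raw)
    base = Path(base_dir) if base_dir else Path.cwd()

    stages = raw.pop("stages", list(STAGES))
    if isinstance(stages, str):
        stages = [s.strip() for s in stages.split(",") if s.strip()]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        errors.append(f"stages: unknown stage(s) {unknown}")
    out_dir = Path(raw.pop("out_dir", "ffpeqc_out"))
    seed = raw.pop("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
        seed = 0

    kwargs: dict = {}
    for key in ("annotation", "reads_ff", "reads_ffpe", "counts", "meta", "rna_vcf", "dna_vcf"):
        if key in raw:
            path = base / str(raw.pop(key))
            if not path.exists():
                errors.append(f"{key}: path does not exist: {path}")
            kwargs[key] = path
    for key, (lo, hi) in _THRESHOLD_RANGES.items():
        if key in raw:
            value = raw.pop(key)
            if not isinstance(value, (int, float)) or not lo <= value <= hi:
                errors.append(f"{key}: must be in [{lo}, {hi}], got {value!r}")
            else:
                kwargs[key] = value

    sim_kwargs = {}
    for key in list(raw):
        if key.startswith("sim_"):
            sim_kwargs[key[4:]] = raw.pop(key)
    for key in ("length_range_bp", "artifact_af_range"):
        if key in sim_kwargs and isinstance(sim_kwargs[key], list):
            sim_kwargs[key] = tuple(sim_kwargs[key])
    if raw:
        errors.append(f"unknown config keys: {sorted(raw)}")
    try:
        simulation = SimulationConfig(seed=seed, **sim_kwargs)
    except Exception as exc:  # noqa: BLE001 - aggregate, don't first-fail
        errors.append(f"simulation: {exc}")
        simulation = None

    # cross-field dependencies
    if "simulate" not in stages:
        if "gcfilter" in stages and not (kwargs.get("annotation") and kwargs.get("reads_ffpe")):
            errors.append("gcfilter without the simulate stage requires annotation and reads_ffpe paths")
        if "expression" in stages and not (kwargs.get("counts") and kwargs.get("meta")):
            errors.append("expression without the simulate stage requires counts and meta paths")
        if "variants" in stages and not (kwargs.get("rna_vcf") and kwargs.get("dna_vcf")):
            errors.append("variants without the simulate stage requires both rna_vcf and dna_vcf paths")
        if "coverage" in stages and not kwargs.get("annotation"):
            errors.append("coverage without the simulate stage requires an annotation path")
    if errors:
        return None, errors
    return (
        RunConfig(out_dir=out_dir, seed=seed, stages=tuple(stages), simulation=simulation, **kwargs),
        [],
    )


@dataclass
class Report:
    """Consolidated per-stage outputs plus provenance and warnings."""

    sections: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sections": self.sections,
            "provenance": self.provenance,
            "warnings": self.warnings,
        }


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir")  # where outputs land does not change what is computed
    for key, value in payload.items():
        if isinstance(value, Path):
            payload[key] = str(value)
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> Report:
    """Execute the selected stages in dependency order.

    A stage failure aborts its dependents; the report records partial results
    and the failure reason in ``warnings``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = Report(
        provenance={
            "config_sha256": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
        }
    )
    state: dict = {}
    failed: set[str] = set()
    deps = {
        "simulate": (),
        "gcfilter": ("simulate",) if "simulate" in config.stages else (),
        "coverage": ("simulate",) if "simulate" in config.stages else (),
        "expression": ("simulate",) if "simulate" in config.stages else (),
        "variants": ("simulate",) if "simulate" in config.stages else (),
    }
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if any(d in failed for d in deps[stage]):
            report.warnings.append(f"{stage}: skipped (dependency failed)")
            failed.add(stage)
            continue
        try:
            _STAGE_FUNCS[stage](config, state, report, out)
        except Exception as exc:  # noqa: BLE001 - recorded, dependents aborted
            logger.error("stage %s failed: %s", stage, exc)
            report.warnings.append(f"{stage}: {exc}")
            failed.add(stage)
    fio.write_json(report.to_dict(), out / "report.json")
    if failed:
        raise StageError(
            f"stage(s) failed: {sorted(failed)}; partial report written to {out / 'report.json'}"
        )
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, state: dict, report: Report, out: Path) -> None:
    sim = config.simulation
    annotation = simulate_annotation(sim)
    fio.write_annotation_bed12(annotation, out / "annotation.bed12")
    state["annotation"] = annotation
    truth: dict = {}
    for storage in (Preservation.FF.value, Preservation.FFPE.value):
        reads, read_truth = simulate_reads(annotation, storage, sim)
        fio.write_reads_bed(reads, out / f"reads_{storage}.bed")
        state[f"reads_{storage}"] = reads
        truth[f"read_region_truth_{storage}"] = read_truth.read_region_truth
    expr = simulate_counts(sim)
    fio.write_counts_tsv(expr.counts, out / "counts.tsv")
    fio.write_sample_meta_tsv(expr.samples, out / "samples.tsv")
    state["expression"] = expr
    truth["gene_log2fc_truth"] = expr.truth.gene_log2fc_truth
    variant_truth_artifact: dict = {}
    variant_truth_af: dict = {}
    variant_sets = []
    for j in range(sim.n_tumor_pairs):
        sample = f"FFPE_subj{j + 1}"
        var = simulate_variants(sim, Preservation.FFPE.value, sample_id=sample)
        variant_sets.append((var.rna_calls, var.dna_evidence))
        fio.write_vcf(var.rna_calls, out / f"rna_calls_{sample}.vcf")
        fio.write_vcf(var.dna_evidence, out / f"dna_evidence_{sample}.vcf")
        variant_truth_artifact[sample] = dict(var.truth.variant_is_artifact)
        variant_truth_af[sample] = var.truth.variant_true_dna_af
    state["variant_sets"] = variant_sets
    truth["variant_is_artifact"] = variant_truth_artifact
    truth["variant_true_dna_af"] = variant_truth_af
    fio.write_json(truth, out / "truth.json")
    state["truth"] = truth
    report.sections["simulate"] = {
        "n_transcripts": len(annotation),
        "n_reads_per_sample": sim.n_reads_per_sample,
        "n_genes": sim.n_genes,
        "n_variant_samples": sim.n_tumor_pairs,
    }


def _stage_gcfilter(config: RunConfig, state: dict, report: Report, out: Path) -> None:
    annotation = state.get("annotation")
    if annotation is None:
        annotation = fio.read_annotation_bed12(config.annotation)
    regions = build_mrna_regions(annotation)
    section: dict = {}
    for storage in ("FF", "FFPE"):
        reads = state.get(f"reads_{storage}")
        if reads is None:
            path = getattr(config, f"reads_{storage.lower()}", None)
            if path is None:
                continue
            reads = fio.read_reads_bed(path)
        labels = classify_reads(reads, regions, min_overlap_bp=config.min_overlap_bp)
        summary = region_fractions(reads, regions, labels=labels)
        before = gc_histogram(reads)
        kept = reads.loc[labels == RegionLabel.MRNA.value]
        after = gc_histogram(kept)
        diff = histogram_max_diff(before, after)
        fio.write_gc_histogram_tsv(before, out / f"gc_{storage}_before.tsv")
        fio.write_gc_histogram_tsv(after, out / f"gc_{storage}_after.tsv")
        fio.write_reads_bed(kept, out / f"reads_{storage}.mrna_only.bed")
        fio.write_json(summary.to_dict(), out / f"regions_{storage}.json")
        section[storage] = {
            "n_reads": int(len(reads)),
            "n_retained": int(len(kept)),
            "region_fractions": summary.fractions,
            "gc_mode_bin_before": before.mode_bin,
            "gc_mode_bin_after": after.mode_bin,
            "max_density_shift": diff.value,
            "max_density_shift_bin": diff.bin,
        }
        logger.info("gcfilter[%s]: %d read, %d retained", storage, len(reads), len(kept))
    report.sections["gcfilter"] = section


def _stage_coverage(config: RunConfig, state: dict, report: Report, out: Path) -> None:
    annotation = state.get("annotation")
    if annotation is None:
        annotation = fio.read_annotation_bed12(config.annotation)
    strands = {tx.transcript_id: tx.strand for tx in annotation.transcripts}
    section = {}
    for storage, rin in (("FF", config.rin_ff), ("FFPE", config.rin_ffpe)):
        coverage = simulate_coverage(annotation, storage, rin, config.simulation)
        profiles = build_profiles(coverage, strands, n_bins=config.n_bins)
        rep = bias_report(profiles)
        fio.write_json(rep.to_dict(), out / f"bias_{storage}.json")
        section[storage] = {"rin": rin, **rep.to_dict()}
    report.sections["coverage"] = section


def _stage_expression(config: RunConfig, state: dict, report: Report, out: Path) -> None:
    expr = state.get("expression")
    if expr is not None:
        counts, samples = expr.counts, expr.samples
    else:
        counts = fio.read_counts_tsv(config.counts)
        samples = fio.read_sample_meta_tsv(config.meta)
    meta = {s.sample_id: s for s in samples}
    qn = quantile_normalize(counts)
    corr = correlation_matrix(qn)
    corr.to_csv(out / "correlation.tsv", sep="\t")
    dend = cluster_samples(corr)
    (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")

    tumors_ff = [s for s in samples if s.preservation is Preservation.FF]
    tumors_ffpe = [s for s in samples if s.preservation is Preservation.FFPE]
    normals = [s for s in samples if s.preservation is Preservation.NORMAL]
    section: dict = {"n_samples": len(samples)}
    first_merges = [
        (sorted(a)[0], sorted(b)[0])
        for a, b, _h in dend.merges()
        if len(a) == 1 and len(b) == 1
    ]
    section["first_leaf_merges"] = first_merges
    if tumors_ff and tumors_ffpe and len(normals) >= 2:
        normal_mat = counts[[s.sample_id for s in normals]]
        fc_ff = log_fold_changes(counts[[s.sample_id for s in tumors_ff]], normal_mat)
        fc_ffpe = log_fold_changes(counts[[s.sample_id for s in tumors_ffpe]], normal_mat)
        shared = fc_ff.index.intersection(fc_ffpe.index)
        fc = pd.DataFrame(
            {
                "log2fc_ff": fc_ff.loc[shared, "log2fc"],
                "log2fc_ffpe": fc_ffpe.loc[shared, "log2fc"],
                "A": fc_ff.loc[shared, "A"],
            }
        )
        fc.to_csv(out / "fold_changes.tsv", sep="\t", index_label="gene_id")
        section["fold_change_pearson_r"] = fold_change_correlation(
            fc["log2fc_ff"], fc["log2fc_ffpe"]
        )
        ma = lowess_curve(
            fc["A"].to_numpy(),
            (fc["log2fc_ff"] - fc["log2fc_ffpe"]).to_numpy(),
            span=config.lowess_span,
        )
        pd.DataFrame({"A": ma.grid, "trend": ma.fitted}).to_csv(
            out / "ma_trend.tsv", sep="\t", index=False
        )
    report.sections["expression"] = section


def _stage_variants(config: RunConfig, state: dict, report: Report, out: Path) -> None:
    variant_sets = state.get("variant_sets")
    if variant_sets is None:
        rna = fio.read_vcf(config.rna_vcf, sample_id="sample")
        dna = fio.read_vcf(config.dna_vcf)
        variant_sets = [(rna, dna)]
    all_before = []
    all_after = []
    for rna, dna in variant_sets:
        paired = pair_variants(rna, dna)
        classified = classify_pairs(
            paired.pairs,
            rna_af_min=config.rna_af_min,
            dna_af_min=config.dna_af_min,
            dna_cov_min=config.dna_cov_min,
        )
        filtered = apply_ffpe_filter(classified.pairs, af_threshold=config.ffpe_af_threshold)
        all_before.append(classified.pairs)
        all_after.append(filtered)
    before = pd.concat(all_before, ignore_index=True)
    after = pd.concat(all_after, ignore_index=True)
    summary = summarize_concordance(before, after)
    summary.to_csv(out / "concordance_summary.tsv", sep="\t", index_label="sample_id")
    spec_table = spectrum(before)
    spec_table.to_csv(out / "spectrum.tsv", sep="\t", index_label="substitution")
    before.to_csv(out / "pairs_classified.tsv", sep="\t", index=False)
    removed = before.merge(
        after[["sample_id", "chrom", "pos", "ref", "alt"]],
        on=["sample_id", "chrom", "pos", "ref", "alt"],
        how="left",
        indicator=True,
    )
    removed_ids = removed.loc[removed["_merge"] == "left_only", "variant_id"].tolist() if "variant_id" in removed else []
    section = {
        "summary": {
            str(k): {c: int(v) for c, v in row.items()} for k, row in summary.iterrows()
        },
        "retained_pct": summary.attrs["retained_pct"],
        "discordant_reduction_pct": summary.attrs["discordant_reduction_pct"],
        "removed_variant_ids": sorted(map(str, removed_ids)),
    }
    fio.write_json(section, out / "concordance_summary.json")
    report.sections["variants"] = section


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "gcfilter": _stage_gcfilter,
    "coverage": _stage_coverage,
    "expression": _stage_expression,
    "variants": _stage_variants,
}
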