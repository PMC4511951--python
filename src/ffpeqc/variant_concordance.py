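"""RNA-vs-DNA variant concordance and the FFPE deamination filter.

RNA-called SNVs are joined to exome (DNA) depth evidence at the same locus and
classified three ways: CONCORDANT when both RNA and DNA show the variant at
>= 10% allele fraction with DNA coverage >= 10X; AMBIGUOUS when DNA coverage
is below 10X; DISCORDANT when well-covered DNA lacks the variant. Formalin
fixation deaminates cytosine, producing C>T (and complementary G>A) artifacts
that appear in FFPE RNA at allele fractions below 0.5; the hard filter removes
deamination-class calls below a 50% AF threshold and leaves every other
substitution untouched. Summaries follow the per-sample before/after layout
of a concordance table.

Positions are 1-based (VCF convention); only SNVs are accepted.
"""

from __future__ import annotations

import logging
from enum import Enum
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
#: The 12 literal ref>alt SNV classes on the genomic plus strand (no
#: collapsing to 6 strand-symmetric classes).
SUBSTITUTION_CLASSES = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)
#: Formalin-induced cytosine-deamination signature.
DEAMINATION_CLASSES = frozenset({"C>T", "G>A"})

#: Canonical columns of RNA-call and DNA-evidence tables.
VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "alt_depth", "total_depth"]
DNA_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_depth", "total_depth"]

_KEY = ["chrom", "pos", "ref", "alt"]


class ConcordanceClass(str, Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT = "DISCORDANT"
    AMBIGUOUS = "AMBIGUOUS"


def allele_fraction(alt_depth: int, total_depth: int) -> float:
    """alt/total; zero total depth is an undefined AF reported as 0.0."""
    if alt_depth < 0 or total_depth < 0:
        raise ValidationError("depths must be non-negative")
    if alt_depth > total_depth:
        raise ValidationError(
            f"alt depth {alt_depth} exceeds total depth {total_depth}"
        )
    if total_depth == 0:
        return 0.0
    return alt_depth / total_depth


def substitution_class(ref: str, alt: str) -> str:
    """Literal ref>alt class as recorded on the plus strand."""
    if ref not in BASES or alt not in BASES:
        raise ValidationError(f"non-ACGT base in substitution {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref equals alt ({ref})")
    return f"{ref}>{alt}"


def is_deamination(ref: str, alt: str) -> bool:
    return substitution_class(ref, alt) in DEAMINATION_CLASSES


def _validate_snvs(frame: pd.DataFrame, what: str) -> None:
    bad_base = ~(frame["ref"].isin(BASES) & frame["alt"].isin(BASES))
    if bad_base.any():
        row = frame.loc[bad_base].iloc[0]
        raise ValidationError(
            f"{what}: only SNVs with single ACGT alleles are supported "
            f"(got {row['ref']!r}>{row['alt']!r} at {row['chrom']}:{row['pos']}); "
            "split multi-allelic records and drop indels upstream"
        )
    if (frame["ref"] == frame["alt"]).any():
        raise ValidationError(f"{what}: record with ref == alt")
    if (frame["alt_depth"] > frame["total_depth"]).any():
        raise ValidationError(f"{what}: alt depth exceeds total depth")
    if (frame[["alt_depth", "total_depth"]].to_numpy() < 0).any():
        raise ValidationError(f"{what}: negative depth")


class PairedVariants(NamedTuple):
    """RNA/DNA variant pairs plus the loci lacking any DNA record."""

    pairs: pd.DataFrame
    missing: pd.DataFrame


def pair_variants(rna_calls: pd.DataFrame, dna_evidence: pd.DataFrame) -> PairedVariants:
    """Join each RNA call to the DNA record at the same (chrom, pos, ref, alt).

    RNA loci with no DNA record of any depth get dna_depth = 0 (so they end
    up AMBIGUOUS) and are listed in the missing-evidence report. Duplicate DNA
    records at one key are an error.
    """
    rna = rna_calls.copy()
    if "sample_id" not in rna.columns:
        rna["sample_id"] = "sample"
    _validate_snvs(rna, "RNA calls")
    _validate_snvs(dna_evidence, "DNA evidence")
    if (rna["total_depth"] == 0).any():
        raise ValidationError("RNA calls require total_depth > 0")
    dup = dna_evidence.duplicated(subset=_KEY)
    if dup.any():
        row = dna_evidence.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate DNA evidence at {row['chrom']}:{row['pos']} "
            f"{row['ref']}>{row['alt']}"
        )
    dna = dna_evidence[DNA_COLUMNS].rename(
        columns={"alt_depth": "dna_alt_depth", "total_depth": "dna_depth"}
    )
    pairs = rna.merge(dna, on=_KEY, how="left")
    missing_mask = pairs["dna_depth"].isna()
    pairs["dna_missing"] = missing_mask
    for col in ("dna_alt_depth", "dna_depth"):
        pairs[col] = pd.to_numeric(pairs[col], errors="coerce").fillna(0).astype(int)
    pairs["rna_af"] = pairs["alt_depth"] / pairs["total_depth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        dna_af = pairs["dna_alt_depth"] / pairs["dna_depth"]
    pairs["dna_af"] = dna_af.fillna(0.0)  # zero-depth DNA: undefined AF, flagged
    pairs["dna_af_defined"] = pairs["dna_depth"] > 0
    pairs["substitution"] = pairs["ref"].str.cat(pairs["alt"], sep=">")
    missing = pairs.loc[missing_mask, ["sample_id"] + _KEY].reset_index(drop=True)
    if len(missing):
        logger.warning("%d RNA loci had no DNA evidence record", len(missing))
    return PairedVariants(pairs=pairs, missing=missing)


def classify_pair(
    rna_af: float,
    dna_af: float,
    dna_depth: int,
    rna_af_min: float = 0.10,
    dna_af_min: float = 0.10,
    dna_cov_min: int = 10,
) -> ConcordanceClass:
    """Three-way rule for one pair (the pair must pass the RNA AF floor).

    DNA coverage below ``dna_cov_min`` is AMBIGUOUS; otherwise DNA AF at or
    above ``dna_af_min`` is CONCORDANT and below it DISCORDANT. Boundaries are
    inclusive ("at least 10%", "at least 10X").
    """
    if rna_af < rna_af_min:
        raise ValidationError(
            f"pair below the RNA AF floor ({rna_af:.3f} < {rna_af_min}); "
            "exclude it upstream"
        )
    if dna_depth < dna_cov_min:
        return ConcordanceClass.AMBIGUOUS
    if dna_af >= dna_af_min:
        return ConcordanceClass.CONCORDANT
    return ConcordanceClass.DISCORDANT


class ClassifiedPairs(NamedTuple):
    """Pairs passing the RNA AF floor, with a concordance column, plus the
    number excluded below the floor."""

    pairs: pd.DataFrame
    n_excluded: int


def classify_pairs(
    pairs: pd.DataFrame,
    rna_af_min: float = 0.10,
    dna_af_min: float = 0.10,
    dna_cov_min: int = 10,
) -> ClassifiedPairs:
    """Vectorized three-way classification of a pair table.

    Pairs with rna_af below ``rna_af_min`` are excluded (the analysis only
    considers RNA variants at or above the floor) and counted.
    """
    considered = pairs[pairs["rna_af"] >= rna_af_min].copy()
    n_excluded = len(pairs) - len(considered)
    ambiguous = considered["dna_depth"] < dna_cov_min
    concordant = ~ambiguous & (considered["dna_af"] >= dna_af_min)
    considered["concordance"] = np.where(
        ambiguous,
        ConcordanceClass.AMBIGUOUS.value,
        np.where(
            concordant, ConcordanceClass.CONCORDANT.value, ConcordanceClass.DISCORDANT.value
        ),
    )
    logger.info(
        "classified %d pairs (%d excluded below RNA AF %.2f)",
        len(considered),
        n_excluded,
        rna_af_min,
    )
    return ClassifiedPairs(pairs=considered, n_excluded=n_excluded)


def apply_ffpe_filter(pairs: pd.DataFrame, af_threshold: float = 0.50) -> pd.DataFrame:
    """Remove deamination-class pairs (C>T, G>A) with RNA AF below threshold.

    All other substitution classes pass regardless of AF; the threshold is
    inclusive (a deamination call at exactly the threshold is kept). Order is
    preserved and the input is untouched.
    """
    deam = pairs["substitution"].isin(DEAMINATION_CLASSES)
    removed = deam & (pairs["rna_af"] < af_threshold)
    logger.info(
        "FFPE filter removed %d of %d pairs (threshold %.2f)",
        int(removed.sum()),
        len(pairs),
        af_threshold,
    )
    return pairs.loc[~removed].copy()


def spectrum(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts for the 12 substitution classes split by concordance class."""
    table = pd.DataFrame(
        0,
        index=list(SUBSTITUTION_CLASSES),
        columns=[c.value for c in ConcordanceClass],
        dtype=int,
    )
    counts = classified.groupby(["substitution", "concordance"]).size()
    for (sub, conc), n in counts.items():
        table.loc[sub, conc] = int(n)
    return table


def summarize_concordance(
    pairs_before: pd.DataFrame, pairs_after: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample before/after class counts with a totals row.

    ``pairs_after`` must be a subset of ``pairs_before`` (the filtered set).
    Output has one row per sample plus ``total``, with columns for concordant
    / discordant / ambiguous counts before, concordant / discordant after,
    ``retained_pct`` (concordant calls surviving the filter) and
    ``discordant_reduction_pct`` = 100·(1 − after/before), both to 2 decimals.
    """
    before_keys = set(map(tuple, pairs_before[["sample_id"] + _KEY].to_numpy()))
    after_keys = set(map(tuple, pairs_after[["sample_id"] + _KEY].to_numpy()))
    if not after_keys <= before_keys:
        raise ValidationError("filtered pair set contains pairs absent before filtering")

    def _counts(frame: pd.DataFrame, cls: ConcordanceClass) -> pd.Series:
        return (
            frame[frame["concordance"] == cls.value].groupby("sample_id").size()
        )

    samples = sorted(pairs_before["sample_id"].unique())
    table = pd.DataFrame(index=samples)
    table["concordant_before"] = _counts(pairs_before, ConcordanceClass.CONCORDANT)
    table["discordant_before"] = _counts(pairs_before, ConcordanceClass.DISCORDANT)
    table["ambiguous_before"] = _counts(pairs_before, ConcordanceClass.AMBIGUOUS)
    table["concordant_after"] = _counts(pairs_after, ConcordanceClass.CONCORDANT)
    table["discordant_after"] = _counts(pairs_after, ConcordanceClass.DISCORDANT)
    table = table.fillna(0).astype(int)
    return _finalize_summary(table)


def summary_from_counts(per_sample: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Build the same summary table directly from per-sample class counts.

    ``per_sample`` maps sample id to a dict with keys ``concordant_before``,
    ``discordant_before``, ``concordant_after``, ``discordant_after`` and
    optionally ``ambiguous_before`` (default 0).
    """
    rows = {}
    for sample, counts in per_sample.items():
        row = {
            "concordant_before": int(counts["concordant_before"]),
            "discordant_before": int(counts["discordant_before"]),
            "ambiguous_before": int(counts.get("ambiguous_before", 0)),
            "concordant_after": int(counts["concordant_after"]),
            "discordant_after": int(counts["discordant_after"]),
        }
        for cls in ("concordant", "discordant"):
            if row[f"{cls}_after"] > row[f"{cls}_before"]:
                raise ValidationError(
                    f"{sample}: {cls} count increased after filtering"
                )
        rows[sample] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return _finalize_summary(table)


def _finalize_summary(table: pd.DataFrame) -> pd.DataFrame:
    total = table.sum(axis=0)
    table = pd.concat([table, total.to_frame("total").T])
    cb, ca = total["concordant_before"], total["concordant_after"]
    db, da = total["discordant_before"], total["discordant_after"]
    table.attrs["retained_pct"] = round(100.0 * ca / cb, 2) if cb else 0.0
    table.attrs["discordant_reduction_pct"] = (
        round(100.0 * (1 - da / db), 2) if db else 0.0
    )
    if table.loc["total", "concordant_before"] and not ca:
        table.attrs["retained_pct"] = 0.0
    return table
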