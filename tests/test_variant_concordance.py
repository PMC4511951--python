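"""Variant pairing, three-way classification, and the deamination filter."""

import numpy as np
import pandas as pd
import pytest

from ffpeqc.errors import ValidationError
from ffpeqc.synthetic_data import SimulationConfig, simulate_variants
from ffpeqc.variant_concordance import (
    ConcordanceClass,
    allele_fraction,
    apply_ffpe_filter,
    classify_pair,
    classify_pairs,
    is_deamination,
    pair_variants,
    spectrum,
    substitution_class,
    summarize_concordance,
    summary_from_counts,
)


def _pairs(rows):
    """rows: (sample, pos, ref, alt, rna_alt, rna_depth, dna_alt, dna_depth)"""
    rna = pd.DataFrame(
        [
            {
                "sample_id": r[0],
                "chrom": "chr1",
                "pos": r[1],
                "ref": r[2],
                "alt": r[3],
                "alt_depth": r[4],
                "total_depth": r[5],
            }
            for r in rows
        ]
    )
    dna = pd.DataFrame(
        [
            {
                "chrom": "chr1",
                "pos": r[1],
                "ref": r[2],
                "alt": r[3],
                "alt_depth": r[6],
                "total_depth": r[7],
            }
            for r in rows
        ]
    ).drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    return pair_variants(rna, dna).pairs


class TestAlleleFraction:
    @pytest.mark.parametrize("alt,total,expected", [(5, 10, 0.5), (0, 50, 0.0), (0, 0, 0.0)])
    def test_values(self, alt, total, expected):
        assert allele_fraction(alt, total) == expected

    def test_impossible_depths_rejected(self):
        with pytest.raises(ValidationError):
            allele_fraction(3, 0)


class TestSubstitutionClass:
    @pytest.mark.parametrize(
        "ref,alt,deam", [("C", "T", True), ("G", "A", True), ("A", "G", False), ("T", "C", False)]
    )
    def test_deamination_flag(self, ref, alt, deam):
        assert substitution_class(ref, alt) == f"{ref}>{alt}"
        assert is_deamination(ref, alt) is deam

    def test_non_acgt_rejected(self):
        with pytest.raises(ValidationError):
            substitution_class("N", "T")


class TestPairing:
    def test_full_evidence_pairs_every_call(self):
        pairs = _pairs(
            [
                ("s", 100, "A", "G", 10, 20, 8, 40),
                ("s", 200, "C", "T", 10, 20, 0, 40),
                ("s", 300, "G", "C", 10, 20, 5, 40),
            ]
        )
        assert len(pairs) == 3 and not pairs["dna_missing"].any()

    def test_missing_dna_record_flagged_and_reported(self):
        rna = pd.DataFrame(
            [
                {"sample_id": "s", "chrom": "chr1", "pos": 1, "ref": "A", "alt": "G",
                 "alt_depth": 5, "total_depth": 10}
            ]
        )
        dna = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "alt_depth", "total_depth"])
        result = pair_variants(rna, dna)
        assert result.pairs["dna_depth"].iloc[0] == 0
        assert len(result.missing) == 1

    def test_duplicate_dna_records_rejected(self):
        rna = pd.DataFrame(
            [{"sample_id": "s", "chrom": "chr1", "pos": 1, "ref": "A", "alt": "G",
              "alt_depth": 5, "total_depth": 10}]
        )
        dna = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 1, "ref": "A", "alt": "G", "alt_depth": 1, "total_depth": 10},
                {"chrom": "chr1", "pos": 1, "ref": "A", "alt": "G", "alt_depth": 2, "total_depth": 12},
            ]
        )
        with pytest.raises(ValidationError, match="duplicate"):
            pair_variants(rna, dna)

    def test_indels_rejected(self):
        rna = pd.DataFrame(
            [{"sample_id": "s", "chrom": "chr1", "pos": 1, "ref": "AT", "alt": "A",
              "alt_depth": 5, "total_depth": 10}]
        )
        with pytest.raises(ValidationError, match="SNV"):
            pair_variants(rna, rna.drop(columns="sample_id"))

    def test_generator_emits_evidence_at_all_loci(self):
        cfg = SimulationConfig(seed=1, n_true_variants=100, n_artifact_variants=150)
        data = simulate_variants(cfg, "FFPE")
        result = pair_variants(data.rna_calls, data.dna_evidence)
        assert len(result.pairs) == 250 and len(result.missing) == 0


class TestClassifier:
    @pytest.mark.parametrize(
        "rna_af,dna_af,dna_depth,expected",
        [
            (0.40, 0.45, 100, ConcordanceClass.CONCORDANT),
            (0.40, 0.00, 50, ConcordanceClass.DISCORDANT),
            (0.40, 0.00, 5, ConcordanceClass.AMBIGUOUS),
            (0.10, 0.10, 10, ConcordanceClass.CONCORDANT),  # inclusive boundaries
            (0.40, 0.09, 10, ConcordanceClass.DISCORDANT),
        ],
    )
    def test_three_way_rule(self, rna_af, dna_af, dna_depth, expected):
        assert classify_pair(rna_af, dna_af, dna_depth) == expected

    def test_below_rna_floor_must_be_excluded_upstream(self):
        with pytest.raises(ValidationError):
            classify_pair(0.05, 0.5, 100)

    def test_vectorized_matches_scalar_rule(self):
        cfg = SimulationConfig(seed=2)
        data = simulate_variants(cfg, "FFPE")
        pairs = pair_variants(data.rna_calls, data.dna_evidence).pairs
        classified = classify_pairs(pairs)
        assert classified.n_excluded == (pairs["rna_af"] < 0.10).sum()
        for _, row in classified.pairs.iterrows():
            want = classify_pair(row["rna_af"], row["dna_af"], row["dna_depth"])
            assert row["concordance"] == want.value

    def test_every_considered_pair_gets_exactly_one_class(self):
        cfg = SimulationConfig(seed=3)
        data = simulate_variants(cfg, "FFPE")
        pairs = pair_variants(data.rna_calls, data.dna_evidence).pairs
        classified = classify_pairs(pairs)
        assert classified.pairs["concordance"].isin(
            [c.value for c in ConcordanceClass]
        ).all()
        assert len(classified.pairs) + classified.n_excluded == len(pairs)


class TestFfpeFilter:
    def test_sub_threshold_deamination_removed(self):
        pairs = _pairs([("s", 1, "C", "T", 30, 100, 0, 50)])
        assert len(apply_ffpe_filter(pairs)) == 0

    def test_threshold_boundary_inclusive(self):
        pairs = _pairs([("s", 1, "G", "A", 50, 100, 0, 50)])
        assert len(apply_ffpe_filter(pairs)) == 1

    def test_non_deamination_passes_at_any_af(self):
        pairs = _pairs([("s", 1, "A", "G", 30, 100, 0, 50)])
        assert len(apply_ffpe_filter(pairs)) == 1

    def test_raising_threshold_never_grows_retained_set(self):
        cfg = SimulationConfig(seed=4)
        data = simulate_variants(cfg, "FFPE")
        pairs = pair_variants(data.rna_calls, data.dna_evidence).pairs
        previous = None
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            kept = set(apply_ffpe_filter(pairs, af_threshold=thr)["variant_id"])
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_concordant_calls_above_half_are_filter_stable(self):
        pairs = _pairs(
            [
                ("s", 1, "C", "T", 60, 100, 45, 100),  # concordant deamination, AF >= 0.5
                ("s", 2, "C", "T", 45, 100, 45, 100),  # concordant deamination, AF < 0.5
            ]
        )
        classified = classify_pairs(pairs).pairs
        assert (classified["concordance"] == "CONCORDANT").all()
        kept = apply_ffpe_filter(classified)
        assert kept["pos"].tolist() == [1]  # the small concordant loss the rule implies


class TestSummaries:
    def test_summary_matches_pair_arithmetic(self):
        cfg = SimulationConfig(seed=5)
        data = simulate_variants(cfg, "FFPE", sample_id="sA")
        pairs = pair_variants(data.rna_calls, data.dna_evidence).pairs
        classified = classify_pairs(pairs).pairs
        filtered = apply_ffpe_filter(classified)
        summary = summarize_concordance(classified, filtered)
        assert summary.loc["total", "concordant_before"] == (
            classified["concordance"] == "CONCORDANT"
        ).sum()
        assert summary.loc["total", "discordant_after"] == (
            filtered["concordance"] == "DISCORDANT"
        ).sum()

    def test_after_superset_rejected(self):
        pairs = _pairs([("s", 1, "A", "G", 30, 100, 40, 100)])
        classified = classify_pairs(pairs).pairs
        extra = _pairs([("s", 2, "A", "C", 30, 100, 40, 100)])
        extra = classify_pairs(extra).pairs
        with pytest.raises(ValidationError):
            summarize_concordance(classified, pd.concat([classified, extra]))

    def test_empty_after_set_gives_zero_retained(self):
        counts = {"s1": dict(concordant_before=10, discordant_before=5,
                             concordant_after=0, discordant_after=0)}
        summary = summary_from_counts(counts)
        assert summary.attrs["retained_pct"] == 0.0

    def test_after_counts_cannot_exceed_before(self):
        counts = {"s1": dict(concordant_before=1, discordant_before=0,
                             concordant_after=2, discordant_after=0)}
        with pytest.raises(ValidationError):
            summary_from_counts(counts)


class TestSpectrum:
    def test_single_class_concentrates_mass(self):
        pairs = _pairs([("s", i, "C", "T", 60, 100, 45, 100) for i in range(1, 6)])
        classified = classify_pairs(pairs).pairs
        table = spectrum(classified)
        assert table.loc["C>T"].sum() == 5 and table.to_numpy().sum() == 5

    def test_counts_conserved(self):
        cfg = SimulationConfig(seed=6)
        data = simulate_variants(cfg, "FFPE")
        classified = classify_pairs(pair_variants(data.rna_calls, data.dna_evidence).pairs).pairs
        assert spectrum(classified).to_numpy().sum() == len(classified)

    def test_ffpe_discordance_is_deamination_dominated_ff_clean(self):
        cfg = SimulationConfig(seed=7)
        tables = {}
        for storage in ("FF", "FFPE"):
            data = simulate_variants(cfg, storage)
            classified = classify_pairs(
                pair_variants(data.rna_calls, data.dna_evidence).pairs
            ).pairs
            tables[storage] = spectrum(classified)
        ffpe_disc = tables["FFPE"]["DISCORDANT"]
        assert ffpe_disc.loc[["C>T", "G>A"]].sum() >= 0.9 * ffpe_disc.sum()
        assert tables["FF"]["DISCORDANT"].loc[["C>T", "G>A"]].sum() == 0
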