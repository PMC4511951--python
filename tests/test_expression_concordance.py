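"""Quantile normalization, correlation/clustering, fold changes, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ffpeqc.errors import ValidationError
from ffpeqc.expression_concordance import (
    Preservation,
    cluster_samples,
    correlation_matrix,
    fold_change_correlation,
    log_fold_changes,
    lowess_curve,
    pvalue_difference,
    quantile_normalize,
    set_overlap,
    size_factors,
)
from ffpeqc.synthetic_data import SimulationConfig, simulate_counts


def _frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(len(next(iter(cols.values()))))])


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        mat = _frame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(mat), mat)

    def test_rank_mean_hand_example(self):
        mat = _frame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(mat)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_ties_share_a_value(self):
        mat = _frame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(mat)
        assert out.loc["g0", "a"] == out.loc["g1", "a"]

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            quantile_normalize(_frame({"a": [1.0, 2.0]}))

    @settings(derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_tie_free_columns_share_sorted_values(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.lognormal(3, 1, size=(30, 4)))
        out = quantile_normalize(mat).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-9)


class TestCorrelation:
    def test_duplicate_columns_correlate_perfectly(self):
        mat = _frame({"a": [1.0, 5.0, 9.0], "b": [1.0, 5.0, 9.0]})
        assert correlation_matrix(mat).loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_columns(self):
        # construct post-transform negation: log2(x+1) values 1,2,3 vs 3,2,1
        mat = _frame({"a": [1.0, 3.0, 7.0], "b": [7.0, 3.0, 1.0]})
        assert correlation_matrix(mat).loc["a", "b"] == pytest.approx(-1.0)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.poisson(50, size=(100, 5)), columns=list("abcde"))
        corr = correlation_matrix(mat)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_shared_subject_signal_dominates(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(4, 1.5, 300)
        signal = rng.normal(0, 0.5, 300)
        s1 = base * 2 ** (signal + rng.normal(0, 0.2, 300))
        s2 = base * 2 ** (signal + rng.normal(0, 0.2, 300))
        s3 = base * 2 ** rng.normal(0, 0.55, 300)
        corr = correlation_matrix(_frame({"s1": s1, "s2": s2, "s3": s3}))
        off = corr.where(~np.eye(3, dtype=bool))
        assert off.max().max() == pytest.approx(corr.loc["s1", "s2"])


class TestClustering:
    def test_closest_pair_merges_first(self):
        corr = pd.DataFrame(
            [[1.0, 0.99, 0.5], [0.99, 1.0, 0.5], [0.5, 0.5, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        first = cluster_samples(corr).merges()[0]
        assert first[0] | first[1] == {"a", "b"}

    def test_block_structure_merges_pairs_before_root(self):
        corr = pd.DataFrame(
            [
                [1.0, 0.95, 0.2, 0.2],
                [0.95, 1.0, 0.2, 0.2],
                [0.2, 0.2, 1.0, 0.9],
                [0.2, 0.2, 0.9, 1.0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
        )
        merges = cluster_samples(corr).merges()
        pairs = {frozenset(m[0] | m[1]) for m in merges[:2]}
        assert pairs == {frozenset("ab"), frozenset("cd")}

    def test_matched_pairs_cluster_first(self, small_config):
        expr = simulate_counts(small_config)
        tumors = [
            s.sample_id
            for s in expr.samples
            if s.preservation in (Preservation.FF, Preservation.FFPE)
        ]
        corr = correlation_matrix(quantile_normalize(expr.counts[tumors]))
        dend = cluster_samples(corr)
        leaf_merges = [m for m in dend.merges() if len(m[0]) == 1 and len(m[1]) == 1]
        for a, b, _h in leaf_merges:
            (sa,), (sb,) = a, b
            assert sa.split("_")[1] == sb.split("_")[1]  # same subject

    def test_nan_correlation_rejected_with_pairs(self):
        corr = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=list("ab"), columns=list("ab")
        )
        with pytest.raises(ValidationError, match="a.*b"):
            cluster_samples(corr)

    def test_newick_contains_all_leaves(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.poisson(40, (50, 4)), columns=list("wxyz"))
        nwk = cluster_samples(correlation_matrix(mat)).to_newick()
        assert nwk.endswith(";") and all(leaf in nwk for leaf in "wxyz")


class TestSizeFactors:
    def test_single_sample_convention(self):
        assert size_factors(_frame({"a": [1.0, 2.0]})).tolist() == [1.0]

    def test_doubled_sample_hand_computation(self):
        mat = _frame({"a": [10.0, 20.0, 30.0], "b": [20.0, 40.0, 60.0]})
        factors = size_factors(mat)
        assert factors["a"] == pytest.approx(1 / np.sqrt(2))
        assert factors["b"] == pytest.approx(np.sqrt(2))

    def test_scale_equivariance(self):
        mat = _frame({"a": [10.0, 5.0, 8.0], "b": [12.0, 6.0, 7.0], "c": [9.0, 4.0, 11.0]})
        base = size_factors(mat)
        scaled = mat.copy()
        scaled["b"] = scaled["b"] * 3.0
        new = size_factors(scaled)
        k = new["a"] / base["a"]
        assert new["b"] == pytest.approx(3.0 * k * base["b"])
        assert new["c"] == pytest.approx(k * base["c"])

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ValidationError):
            size_factors(_frame({"a": [0.0, 5.0], "b": [3.0, 0.0]}))


class TestFoldChanges:
    def test_fourfold_change_recovered(self):
        # one 4x gene on a background of unchanged genes, so that the
        # median-of-ratios size factors stay at 1
        background = {f"g{i}": 1000.0 for i in range(1, 10)}
        tumor = pd.DataFrame(
            {"t1": {"g0": 4000.0, **background}, "t2": {"g0": 4000.0, **background}}
        )
        normal = pd.DataFrame(
            {"n1": {"g0": 1000.0, **background}, "n2": {"g0": 1000.0, **background}}
        )
        fc = log_fold_changes(tumor, normal)
        assert fc.loc["g0", "log2fc"] == pytest.approx(2.0, abs=0.01)
        assert fc.loc["g1", "log2fc"] == pytest.approx(0.0, abs=0.01)

    def test_gene_set_mismatch_names_genes(self):
        tumor = pd.DataFrame({"t": [1.0]}, index=["gX"])
        normal = pd.DataFrame({"n": [1.0]}, index=["gY"])
        with pytest.raises(ValidationError, match="gX"):
            log_fold_changes(tumor, normal)

    def test_recovery_against_generator_truth(self):
        cfg = SimulationConfig(seed=12, n_genes=5000, dispersion=0.05)
        expr = simulate_counts(cfg)
        ff = expr.counts[[s.sample_id for s in expr.samples if s.preservation is Preservation.FF]]
        normals = expr.counts[
            [s.sample_id for s in expr.samples if s.preservation is Preservation.NORMAL]
        ]
        fc = log_fold_changes(ff, normals, min_mean=10.0)
        truth = pd.Series(expr.truth.gene_log2fc_truth).loc[fc.index]
        slope = np.polyfit(truth, fc["log2fc"], 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_identical_tables_correlate_perfectly(self):
        fc = pd.Series([1.0, -2.0, 0.5], index=list("abc"))
        assert fold_change_correlation(fc, fc) == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(7)
        a = pd.Series(rng.normal(size=1000))
        b = pd.Series(rng.normal(size=1000))
        assert abs(fold_change_correlation(a, b)) < 0.1

    def test_too_few_genes_rejected(self):
        fc = pd.Series([1.0, 2.0])
        with pytest.raises(ValidationError):
            fold_change_correlation(fc, fc)


class TestLowess:
    def test_exact_line_reproduced(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 10, 200)
        curve = lowess_curve(a, 3 * a - 2)
        assert np.allclose(curve.fitted, 3 * curve.grid - 2, atol=1e-6)

    def test_constant_reproduced(self):
        rng = np.random.default_rng(2)
        curve = lowess_curve(rng.uniform(0, 10, 100), np.full(100, 1.7))
        assert np.allclose(curve.fitted, 1.7, atol=1e-9)

    def test_attenuation_step_detected(self):
        # high-expression baseline so the attenuated genes are a minority and
        # the median-of-ratios size factors cannot absorb the shift
        cfg = SimulationConfig(
            seed=13, n_genes=4000, lowexpr_attenuation=0.6,
            baseline_log2_mean=11.5, baseline_log2_sd=1.2,
        )
        expr = simulate_counts(cfg)
        cols = {s.sample_id: s for s in expr.samples}
        ff = expr.counts[[c for c, s in cols.items() if s.preservation is Preservation.FF]]
        ffpe = expr.counts[[c for c, s in cols.items() if s.preservation is Preservation.FFPE]]
        normals = expr.counts[[c for c, s in cols.items() if s.preservation is Preservation.NORMAL]]
        fc_ff = log_fold_changes(ff, normals, min_mean=5.0)
        fc_ffpe = log_fold_changes(ffpe, normals, min_mean=5.0)
        shared = fc_ff.index.intersection(fc_ffpe.index)
        m = (fc_ff.loc[shared, "log2fc"] - fc_ffpe.loc[shared, "log2fc"]).to_numpy()
        curve = lowess_curve(fc_ff.loc[shared, "A"].to_numpy(), m)
        below = curve.grid < 9.0
        above = curve.grid > 11.5
        assert curve.fitted[below].mean() > 0.3  # FF higher where FFPE is attenuated
        assert abs(curve.fitted[above].mean()) < 0.1

    @pytest.mark.parametrize("bad_span", [0.0, 1.5])
    def test_invalid_span_rejected(self, bad_span):
        with pytest.raises(ValidationError):
            lowess_curve(np.arange(20.0), np.arange(20.0), span=bad_span)


class TestPValueDifference:
    def test_identical_vectors_give_zero(self):
        idx = [f"g{i}" for i in range(50)]
        p = pd.Series(np.linspace(0.01, 0.99, 50), index=idx)
        a = pd.Series(np.linspace(1, 15, 50), index=idx)
        res = pvalue_difference(p, p, a)
        assert (res.delta == 0).all()

    def test_single_divergent_gene(self):
        idx = [f"g{i}" for i in range(50)]
        p1 = pd.Series(np.full(50, 0.5), index=idx)
        p2 = p1.copy()
        p2.iloc[7] = 0.9
        a = pd.Series(np.linspace(1, 15, 50), index=idx)
        res = pvalue_difference(p1, p2, a)
        assert (res.delta != 0).sum() == 1

    def test_null_trend_is_flat(self):
        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(2000)]
        p1 = pd.Series(rng.uniform(0, 1, 2000), index=idx)
        p2 = pd.Series(rng.uniform(0, 1, 2000), index=idx)
        a = pd.Series(rng.uniform(0, 15, 2000), index=idx)
        res = pvalue_difference(p1, p2, a)
        # interior of the A range: edge windows hold half the neighbors and
        # double the smoother variance, so they are excluded from the bound
        grid = res.curve.grid
        span_a = np.ptp(grid)
        interior = (grid > grid.min() + 0.1 * span_a) & (grid < grid.max() - 0.1 * span_a)
        assert np.abs(res.curve.fitted[interior]).max() < 0.05

    def test_out_of_range_pvalues_rejected(self):
        idx = list("abcdefghij")
        p1 = pd.Series(np.linspace(0, 1, 10), index=idx)
        p2 = p1.copy()
        p2.iloc[0] = 1.2
        a = pd.Series(np.arange(10.0), index=idx)
        with pytest.raises(ValidationError):
            pvalue_difference(p1, p2, a)


class TestSetOverlap:
    def test_identical_sets(self):
        assert set_overlap({1, 2}, {1, 2}).percent == 100.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            set_overlap(set(), {1})

    @pytest.mark.parametrize(
        "n_a,n_shared,expected",
        [(742, 470, 63.3), (270, 151, 55.9), (10, 3, 30.0)],
    )
    def test_percent_rounding(self, n_a, n_shared, expected):
        a = set(range(n_a))
        b = set(range(n_shared)) | {10_000 + i for i in range(5)}
        res = set_overlap(a, b)
        assert res.n_a == n_a and res.n_intersection == n_shared
        assert res.percent == expected
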