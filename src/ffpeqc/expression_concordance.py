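"""Expression concordance between preservation methods and platforms.

Covers the expression arm of the FF/FFPE comparison: quantile normalization,
cross-sample Pearson correlation and average-linkage clustering (matched
FF/FFPE pairs are expected to cluster together), DESeq-style median-of-ratios
size factors, tumor-vs-normal log2 fold changes and their cross-arm
correlation, MA-style difference curves with locally weighted smoothing, the
p-value-difference comparison, and differential-gene-set overlap arithmetic.

Count matrices are pandas DataFrames with genes as rows and samples as
columns; values are non-negative (integers for raw counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ValidationError

logger = logging.getLogger(__name__)


class Preservation(str, Enum):
    FF = "FF"
    FFPE = "FFPE"
    NORMAL = "NORMAL"


class Platform(str, Enum):
    RNASEQ = "RNASEQ"
    NANOSTRING = "NANOSTRING"


@dataclass(frozen=True)
class SampleMeta:
    """Annotation of one sample column of a count matrix."""

    sample_id: str
    subject_id: str
    preservation: Preservation
    platform: Platform = Platform.RNASEQ
    rin: float | None = None


def _validate_counts(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValidationError("count matrix has duplicate gene or sample ids")
    if (matrix.to_numpy() < 0).any():
        raise ValidationError("count matrix has negative entries")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalization.

    The per-rank reference is the mean of each sample's sorted values; every
    value is replaced by the reference at its rank, with ties receiving the
    mean of their tied ranks' references. Afterwards every column has the same
    sorted values.
    """
    _validate_counts(matrix)
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization requires at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # ties: average the references assigned within each tied group
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def correlation_matrix(
    matrix: pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise sample correlation, by default Pearson on log2(x + 1).

    Zero-variance columns yield NaN coefficients for their pairs; they are
    flagged with a warning rather than silently coerced.
    """
    _validate_counts(matrix)
    if matrix.shape[1] < 2:
        raise ValidationError("correlation requires at least 2 samples")
    data = np.log2(matrix + 1.0) if log_transform else matrix.astype(float)
    degenerate = data.columns[data.std(axis=0) == 0].tolist()
    if degenerate:
        logger.warning("zero-variance samples (correlations undefined): %s", degenerate)
    corr = data.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over samples on distance d = 1 - r.

    ``linkage`` is a scipy linkage matrix over ``labels`` (lexicographically
    sorted before clustering so distance ties resolve toward the
    lexicographically smallest members; leaf order is deterministic).
    """

    labels: tuple[str, ...]
    linkage: np.ndarray

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in sch.leaves_list(self.linkage))

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge steps as (member set A, member set B, height), in order."""
        clusters: dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        n = len(self.labels)
        for step, (a, b, height, _size) in enumerate(self.linkage):
            fa, fb = clusters[int(a)], clusters[int(b)]
            out.append((fa, fb, float(height)))
            clusters[n + step] = fa | fb
        return out

    def to_newick(self) -> str:
        n = len(self.labels)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: lab for i, lab in enumerate(self.labels)}
        for step, (a, b, h, _size) in enumerate(self.linkage):
            a, b = int(a), int(b)
            left = f"{node[a]}:{h - height[a]:.6g}"
            right = f"{node[b]}:{h - height[b]:.6g}"
            node[n + step] = f"({left},{right})"
            height[n + step] = float(h)
        return node[n + len(self.linkage) - 1] + ";"


def cluster_samples(corr: pd.DataFrame) -> Dendrogram:
    """Agglomerative average-linkage clustering of a correlation matrix."""
    if corr.isna().any().any():
        bad = [
            (str(corr.index[i]), str(corr.columns[j]))
            for i, j in zip(*np.where(corr.isna().to_numpy()))
            if i < j
        ]
        raise ValidationError(f"undefined correlations for pairs: {bad}")
    labels = tuple(sorted(map(str, corr.columns)))
    dist = 1.0 - corr.loc[list(labels), list(labels)].to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage = sch.linkage(condensed, method="average")
    return Dendrogram(labels=labels, linkage=linkage)


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    The per-gene reference is the geometric mean across samples over genes
    positive in every sample; a sample's factor is the median over those genes
    of count / reference. A single-sample matrix gets factor 1 by convention.
    """
    _validate_counts(matrix)
    if matrix.shape[1] == 1:
        return pd.Series(1.0, index=matrix.columns)
    positive = (matrix > 0).all(axis=1)
    if not positive.any():
        raise ValidationError("no gene with positive counts in all samples")
    logs = np.log(matrix.loc[positive].to_numpy(dtype=float))
    log_ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_ref[:, None], axis=0))
    return pd.Series(factors, index=matrix.columns)


def normalize_counts(matrix: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample by its size factor."""
    if factors is None:
        factors = size_factors(matrix)
    return matrix / factors


def log_fold_changes(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    pseudocount: float = 0.5,
    min_mean: float = 0.0,
) -> pd.DataFrame:
    """Per-gene log2 fold change of tumor vs normal mean expression.

    Size factors are computed on the combined matrix (median-of-ratios); the
    fold change is log2((mean normalized tumor + pseudocount) / (mean
    normalized normal + pseudocount)). Column ``A`` is log2(overall normalized
    mean + pseudocount). Genes whose overall normalized mean falls below
    ``min_mean`` (the expression floor) are dropped.
    """
    if set(tumor.index) != set(normal.index):
        only_t = sorted(set(tumor.index) - set(normal.index))[:5]
        only_n = sorted(set(normal.index) - set(tumor.index))[:5]
        raise ValidationError(
            f"gene sets differ (tumor-only e.g. {only_t}, normal-only e.g. {only_n})"
        )
    normal = normal.loc[tumor.index]
    combined = pd.concat([tumor, normal], axis=1)
    factors = size_factors(combined)
    norm = combined / factors
    mean_tumor = norm[tumor.columns].mean(axis=1)
    mean_normal = norm[normal.columns].mean(axis=1)
    overall = norm.mean(axis=1)
    table = pd.DataFrame(
        {
            "log2fc": np.log2((mean_tumor + pseudocount) / (mean_normal + pseudocount)),
            "A": np.log2(overall + pseudocount),
            "mean_tumor": mean_tumor,
            "mean_normal": mean_normal,
        }
    )
    return table[overall >= min_mean]


def fold_change_correlation(fc_a: pd.Series, fc_b: pd.Series) -> float:
    """Pearson correlation of two fold-change tables over shared genes."""
    shared = fc_a.index.intersection(fc_b.index)
    a = fc_a.loc[shared]
    b = fc_b.loc[shared]
    ok = np.isfinite(a) & np.isfinite(b)
    if int(ok.sum()) < 3:
        raise ValidationError("fewer than 3 shared genes with defined fold changes")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


@dataclass(frozen=True)
class MACurve:
    """(A, M) points plus a locally weighted smoothed trend on a grid."""

    a: np.ndarray
    m: np.ndarray
    grid: np.ndarray
    fitted: np.ndarray
    span: float


def lowess_curve(
    a: Sequence[float],
    m: Sequence[float],
    span: float = 0.3,
    grid_points: int = 200,
) -> MACurve:
    """Degree-1 locally weighted regression with tricube weights.

    The smoother uses the span-nearest neighbors of each grid point, no
    robustness iterations, evaluated on a ``grid_points``-point grid spanning
    the observed A range.
    """
    a = np.asarray(a, dtype=float)
    m = np.asarray(m, dtype=float)
    if len(a) != len(m):
        raise ValidationError("A and M must have equal length")
    if len(a) < 10:
        raise ValidationError("lowess requires at least 10 points")
    if not (0 < span <= 1):
        raise ValidationError("span must be in (0, 1]")
    if int(np.ceil(span * len(a))) < 2:
        raise ValidationError(
            "fewer than 2 neighbors per window; increase the span"
        )
    grid = np.linspace(a.min(), a.max(), grid_points)
    fitted = _sm_lowess(m, a, frac=span, it=0, xvals=grid)
    return MACurve(a=a, m=m, grid=grid, fitted=np.asarray(fitted, dtype=float), span=span)


class PValueDifference(NamedTuple):
    delta: pd.Series
    curve: MACurve


def pvalue_difference(
    pvals_ff: pd.Series,
    pvals_ffpe: pd.Series,
    a: pd.Series,
    span: float = 0.3,
) -> PValueDifference:
    """Per-gene p-value difference (FF − FFPE) with its smoothed trend over A.

    The p-values come from external differential-expression runs of each arm
    against the normals; a flat near-zero trend means expression level does
    not bias significance for either preservation method.
    """
    for name, p in (("FF", pvals_ff), ("FFPE", pvals_ffpe)):
        vals = np.asarray(p, dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{name} p-values outside [0, 1]")
    shared = pvals_ff.index.intersection(pvals_ffpe.index).intersection(a.index)
    if len(shared) != len(pvals_ff) or len(shared) != len(pvals_ffpe):
        raise ValidationError("p-value tables and A must share one gene list")
    delta = pvals_ff.loc[shared] - pvals_ffpe.loc[shared]
    curve = lowess_curve(a.loc[shared].to_numpy(), delta.to_numpy(), span=span)
    return PValueDifference(delta=delta, curve=curve)


class OverlapResult(NamedTuple):
    n_a: int
    n_intersection: int
    percent: float


def set_overlap(set_a: Iterable, set_b: Iterable) -> OverlapResult:
    """|A|, |A ∩ B| and the intersection as a percent of |A| (1 decimal)."""
    a = set(set_a)
    b = set(set_b)
    if not a:
        raise ValidationError("set A is empty")
    inter = len(a & b)
    return OverlapResult(
        n_a=len(a), n_intersection=inter, percent=round(100.0 * inter / len(a), 1)
    )
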