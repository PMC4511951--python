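"""Coverage along normalized transcript length and 3'-bias scoring.

Degraded RNA combined with oligo-dT priming produces excess coverage toward
the 3' end of transcripts, growing with transcript length and with the degree
of degradation (lower RIN). Randomly primed rRNA-depleted libraries (the
usual FFPE preparation) stay flat. Profiles are expressed over 100 bins of
normalized transcript position (5'→3'), stratified into three length classes
(0.5–4 kbp, 4–8 kbp, ≥8 kbp), and scored by the ratio of the last to the
first decile of bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

N_BINS_DEFAULT = 100


class LengthClass(str, Enum):
    SHORT = "SHORT"  # [500, 4000) bp
    MEDIUM = "MEDIUM"  # [4000, 8000) bp
    LONG = "LONG"  # [8000, inf) bp


def length_class(spliced_length_bp: int) -> LengthClass | None:
    """Assign a transcript to a length class; below 500 bp returns None.

    Classes are half-open so that they partition all lengths >= 500 bp.
    """
    if spliced_length_bp < 1:
        raise ValidationError("spliced length must be >= 1")
    if spliced_length_bp < 500:
        return None
    if spliced_length_bp < 4000:
        return LengthClass.SHORT
    if spliced_length_bp < 8000:
        return LengthClass.MEDIUM
    return LengthClass.LONG


@dataclass(frozen=True)
class TranscriptProfile:
    """Mean-normalized coverage over ``n_bins`` bins in 5'→3' orientation."""

    transcript_id: str
    spliced_length_bp: int
    bins: np.ndarray
    raw_mean_coverage: float

    def __post_init__(self) -> None:
        if self.raw_mean_coverage > 0 and not math.isclose(
            float(np.mean(self.bins)), 1.0, abs_tol=1e-9
        ):
            raise ValidationError(
                f"{self.transcript_id}: profile bins are not mean-normalized"
            )


def transcript_profile(
    base_coverage: Sequence[float] | np.ndarray,
    strand: str = "+",
    transcript_id: str = "",
    n_bins: int = N_BINS_DEFAULT,
) -> TranscriptProfile:
    """Bin per-base coverage into ``n_bins`` equal-width bins of position.

    Base *i* of a length-*L* transcript goes to bin ``floor(i·n_bins/L)``.
    Minus-strand coverage arrays (given in genomic orientation) are reversed
    so bins always run 5'→3'. Bin values are per-base means, normalized by
    the profile mean when raw mean coverage is positive.
    """
    cov = np.asarray(base_coverage, dtype=float)
    length = len(cov)
    if length < n_bins:
        raise ValidationError(
            f"{transcript_id or 'transcript'}: length {length} < n_bins {n_bins}"
        )
    if strand not in ("+", "-"):
        raise ValidationError(f"bad strand {strand!r}")
    if strand == "-":
        cov = cov[::-1]
    idx = (np.arange(length) * n_bins // length).astype(int)
    sums = np.bincount(idx, weights=cov, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    bins = sums / counts
    raw_mean = float(cov.mean())
    if raw_mean > 0:
        bins = bins / bins.mean()
    return TranscriptProfile(
        transcript_id=transcript_id,
        spliced_length_bp=length,
        bins=bins,
        raw_mean_coverage=raw_mean,
    )


def build_profiles(
    coverage_by_transcript: Mapping[str, np.ndarray],
    strand_by_transcript: Mapping[str, str],
    n_bins: int = N_BINS_DEFAULT,
) -> list[TranscriptProfile]:
    """Profile every transcript, skipping (with a log line) those shorter
    than the bin count."""
    profiles = []
    for tid, cov in coverage_by_transcript.items():
        try:
            profiles.append(
                transcript_profile(
                    cov,
                    strand=strand_by_transcript.get(tid, "+"),
                    transcript_id=tid,
                    n_bins=n_bins,
                )
            )
        except ValidationError as exc:
            logger.warning("skipping %s: %s", tid, exc)
    return profiles


@dataclass(frozen=True)
class AggregateProfile:
    """Unweighted per-bin mean across transcript profiles."""

    bins: np.ndarray
    n_transcripts: int
    length_class: LengthClass | None = None


def aggregate_profiles(
    profiles: Iterable[TranscriptProfile],
    length_cls: LengthClass | None = None,
    min_mean_coverage: float = 1.0,
) -> AggregateProfile:
    """Average profiles, optionally restricted to one length class.

    Transcripts below ``min_mean_coverage`` raw mean (effectively unexpressed)
    are excluded; transcripts shorter than 500 bp never enter a class filter.
    """
    included = [
        p
        for p in profiles
        if p.raw_mean_coverage >= min_mean_coverage
        and (length_cls is None or length_class(p.spliced_length_bp) == length_cls)
    ]
    if not included:
        raise ValidationError(
            f"no transcripts to aggregate (class={length_cls}, "
            f"min_mean_coverage={min_mean_coverage})"
        )
    bins = np.mean([p.bins for p in included], axis=0)
    return AggregateProfile(bins=bins, n_transcripts=len(included), length_class=length_cls)


def three_prime_bias(bins: np.ndarray) -> float:
    """Ratio of the last decile of bins to the first decile (1.0 = flat).

    Bins are 1-indexed conceptually: the score is mean(bins 91..100) divided
    by mean(bins 1..10). A zero first-decile mean makes the score undefined
    and is reported as NaN.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.shape[-1] % 10 != 0:
        raise ValidationError("bias score requires a bin count divisible by 10")
    decile = bins.shape[-1] // 10
    first = float(np.mean(bins[:decile]))
    last = float(np.mean(bins[-decile:]))
    if first == 0:
        logger.warning("three_prime_bias: zero first-decile mean; undefined")
        return float("nan")
    return last / first


@dataclass(frozen=True)
class BiasReport:
    """3'-bias scores overall and per length class (NaN when a class is empty)."""

    overall: float
    per_class: dict[str, float]

    def to_dict(self) -> dict:
        return {"overall": self.overall, "per_class": dict(self.per_class)}


def bias_report(
    profiles: Sequence[TranscriptProfile], min_mean_coverage: float = 1.0
) -> BiasReport:
    """Aggregate profiles overall and per class, scoring each aggregate."""
    overall = three_prime_bias(
        aggregate_profiles(profiles, min_mean_coverage=min_mean_coverage).bins
    )
    per_class = {}
    for cls in LengthClass:
        try:
            agg = aggregate_profiles(profiles, cls, min_mean_coverage)
            per_class[cls.value] = three_prime_bias(agg.bins)
        except ValidationError:
            per_class[cls.value] = float("nan")
    return BiasReport(overall=overall, per_class=per_class)


def aggregate_by_coverage_quartile(
    profiles: Sequence[TranscriptProfile], min_mean_coverage: float = 1.0
) -> dict[int, AggregateProfile]:
    """Optional stratification by expression: aggregate within raw-mean
    coverage quartiles (1 = lowest). Used to check that expression level does
    not drive positional bias."""
    included = [p for p in profiles if p.raw_mean_coverage >= min_mean_coverage]
    if len(included) < 4:
        raise ValidationError("need at least 4 profiles for quartile stratification")
    means = np.array([p.raw_mean_coverage for p in included])
    edges = np.quantile(means, [0.25, 0.5, 0.75])
    quartile = np.searchsorted(edges, means, side="right") + 1
    out = {}
    for q in (1, 2, 3, 4):
        members = [p for p, g in zip(included, quartile) if g == q]
        if members:
            out[q] = AggregateProfile(
                bins=np.mean([p.bins for p in members], axis=0),
                n_transcripts=len(members),
            )
    return out
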