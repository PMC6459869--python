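"""The spreading statistic and its comparative tests.

For each target region the H3K27me3 signal density (signal per bp) is computed
inside the SUZ12 span and in fixed-width flanks abutting its 5' and 3'
boundaries; the *spreading ratio* is flank density over inside density (out/in,
with a pseudocount on both terms).  A mark that spreads well beyond the bound
footprint gives ratios near 1; a confined mark gives ratios near 0.  Between
conditions the ratio distributions are compared with a two-sample Student's t
or a Wilcoxon rank-sum test, and paired per-region ratios with least-squares
regression (slope, Pearson r, r^2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval
from .regions import FlankSet, TargetRegion, spreading_flanks
from .tracks import CoverageTrack

__all__ = [
    "SpreadingRecord",
    "ComparisonResult",
    "region_density",
    "spreading_table",
    "records_frame",
    "compare_densities",
    "ratio_correlation",
    "top_fraction",
    "promoter_enrichment_score",
]

DEFAULT_PSEUDOCOUNT = 0.01  # signal-per-bp floor added to both ratio terms


@dataclass(frozen=True)
class SpreadingRecord:
    region_id: str
    chrom: str
    start: int
    end: int
    density_in: float
    density_out5: float
    density_out3: float
    ratio5: float
    ratio3: float
    clipped: bool


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    test: str
    n_a: int
    n_b: int
    slope: float | None = None
    intercept: float | None = None
    r: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")


def region_density(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Mean signal per bp over an interval, partial bins weighted by overlap."""
    track.check_interval(interval.chrom, interval.start, interval.end)
    binsize = track.binsize
    arr = track.values[interval.chrom]
    b0, b1 = interval.start // binsize, (interval.end - 1) // binsize
    if b0 == b1:
        return float(arr[b0])
    total = 0.0
    total += arr[b0] * ((b0 + 1) * binsize - interval.start)
    total += arr[b1] * (interval.end - b1 * binsize)
    if b1 - b0 > 1:
        total += arr[b0 + 1:b1].sum() * binsize
    return float(total / len(interval))


def spreading_table(
    track: CoverageTrack,
    regions: Sequence[TargetRegion],
    flank_bp: int = 1200,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[SpreadingRecord]:
    """One :class:`SpreadingRecord` per target region.

    Ratios are ``(density_out + eps) / (density_in + eps)``; regions whose
    flanks are clipped at chromosome ends are flagged (and excluded from the
    distribution tests by default downstream).
    """
    records: list[SpreadingRecord] = []
    for region in regions:
        fl: FlankSet = spreading_flanks(region, flank_bp, track.chrom_lengths)
        d_in = region_density(track, fl.inside)
        d5 = region_density(track, fl.out5) if fl.out5 is not None else 0.0
        d3 = region_density(track, fl.out3) if fl.out3 is not None else 0.0
        records.append(SpreadingRecord(
            region_id=region.region_id,
            chrom=fl.inside.chrom,
            start=fl.inside.start,
            end=fl.inside.end,
            density_in=d_in,
            density_out5=d5,
            density_out3=d3,
            ratio5=(d5 + pseudocount) / (d_in + pseudocount),
            ratio3=(d3 + pseudocount) / (d_in + pseudocount),
            clipped=fl.clipped,
        ))
    return records


def records_frame(records: Sequence[SpreadingRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def compare_densities(
    a: Sequence[float],
    b: Sequence[float],
    test: Literal["student_t", "wilcoxon"] = "student_t",
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample comparison of density (or ratio) distributions.

    ``student_t`` is the classical pooled-variance form (Welch by flag);
    ``wilcoxon`` is the rank-sum test, exact for small tie-free samples and
    normal-approximated with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if test == "student_t":
        res = stats.ttest_ind(a, b, equal_var=not welch)
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                "student_t", len(a), len(b))
    if test == "wilcoxon":
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            # no rank information at all
            return ComparisonResult(float(len(a) * len(b) / 2.0), 1.0,
                                    "wilcoxon", len(a), len(b))
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        return ComparisonResult(float(res.statistic), float(res.pvalue),
                                "wilcoxon", len(a), len(b))
    raise ValueError(f"unknown test {test!r}")


def ratio_correlation(
    ratios_a: Sequence[float], ratios_b: Sequence[float]
) -> ComparisonResult:
    """Least-squares fit of paired per-region ratios (b on a) with Pearson r."""
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("ratio vectors must be paired (equal length)")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(a, a[0]):
        raise ValueError("zero variance in predictor; slope undefined")
    fit = stats.linregress(a, b)
    return ComparisonResult(
        statistic=float(fit.slope),
        p_value=float(fit.pvalue),
        test="linear_regression",
        n_a=len(a),
        n_b=len(b),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
    )


def top_fraction(
    records: Sequence[SpreadingRecord],
    scores: Sequence[float],
    q: float,
    higher_is_better: bool = True,
) -> list[SpreadingRecord]:
    """The ``ceil(q * n)`` records with the best ranking scores.

    Scores align positionally with records (e.g. promoter −log10 p-values,
    where higher is better).  Ties break by region_id for determinism.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    records = list(records)
    scores = list(scores)
    if len(scores) != len(records):
        raise ValueError("scores must align with records")
    if not records:
        return []
    k = math.ceil(q * len(records))
    sign = -1.0 if higher_is_better else 1.0
    order = sorted(
        range(len(records)), key=lambda i: (sign * scores[i], records[i].region_id)
    )
    return [records[i] for i in order[:k]]


def promoter_enrichment_score(
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
    interval: GenomicInterval,
    fragment_length: int = 200,
) -> float:
    """Poisson enrichment score (−log10 upper-tail p) for one interval.

    A minimal stand-in for a peak caller's promoter p-value, used only to rank
    regions: the observed IP fragment count in the interval is tested against
    an input-derived expectation (input count rescaled by the IP/input
    genome-wide totals, floored at 1), with the upper tail including the
    observed count.  Both tracks must be unscaled count-equivalents.
    """
    if len(interval) <= 0:
        raise ValueError("zero-length interval")

    def frag_count(track: CoverageTrack, iv: GenomicInterval) -> float:
        return region_density(track, iv) * len(iv) / fragment_length

    def total(track: CoverageTrack) -> float:
        return sum(
            float(track.values[c].sum()) * track.binsize
            for c in track.values
        ) / fragment_length

    observed = frag_count(ip_track, interval)
    t_in = total(input_track)
    expected = frag_count(input_track, interval) * (total(ip_track) / t_in if t_in else 1.0)
    lam = max(expected, 1.0)
    k = int(round(observed))
    p = float(stats.poisson.sf(k - 1, lam))
    return -math.log10(max(p, 1e-300))
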