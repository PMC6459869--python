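"""Ranked signal matrices around anchors, and promoter intensity summaries.

Two matrix flavours back the heatmap/metaprofile analyses:

* *reference-point*: a fixed window around each TSS (default +/- 5 kb at 50 bp
  bins, 200 columns), rows strand-flipped so column 0 is always upstream;
* *scale-regions*: each gene body resampled to a fixed number of columns by
  length-weighted averaging, plus flanks binned at the track resolution
  (default 100 body bins + 2 x 1 kb / 50 bp = 140 columns).

Matrices sharing one antibody are put on a common intensity scale with a single
pooled ``1 / (max - min)`` factor, which preserves every cell ordering and
makes cross-sample heatmaps comparable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io_formats import GeneModel
from .regions import TargetRegion
from .spreading_stats import ComparisonResult, compare_densities, region_density
from .io_formats import GenomicInterval
from .tracks import CoverageTrack

__all__ = [
    "ProfileMatrix",
    "reference_point_matrix",
    "scale_regions_matrix",
    "minmax_normalize",
    "rank_regions",
    "promoter_intensity_summary",
]


@dataclass
class ProfileMatrix:
    """Regions x bins signal matrix.

    ``flagged`` marks rows with zero-filled out-of-chromosome bins (or bodies
    shorter than one column's worth of bp); ``minmax_factor`` records the
    shared scale applied (1 if unscaled).
    """

    row_ids: list[str]
    values: np.ndarray
    binsize: int
    anchor: Literal["reference_point", "scale_regions"]
    minmax_factor: float = 1.0
    flagged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.row_ids):
            raise ValueError("values must be (n_rows, n_bins)")
        if len(self.flagged) == 0:
            self.flagged = np.zeros(len(self.row_ids), dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def reorder(self, permutation: Sequence[int]) -> "ProfileMatrix":
        perm = list(permutation)
        return ProfileMatrix(
            [self.row_ids[i] for i in perm],
            self.values[perm],
            self.binsize,
            self.anchor,
            self.minmax_factor,
            self.flagged[perm],
        )

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.row_ids).to_csv(
            path, sep="\t", index_label="region_id"
        )


def _anchor_tuple(a) -> tuple[str, int, str]:
    if isinstance(a, GeneModel):
        return a.interval.chrom, a.tss, a.strand
    chrom, tss, strand = a
    return chrom, int(tss), strand


def reference_point_matrix(
    track: CoverageTrack,
    anchors: Sequence,
    window_bp: int = 5000,
    binsize: int = 50,
    ids: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Signal in ``[anchor - window, anchor + window)`` per anchor.

    Anchors are :class:`GeneModel` objects or ``(chrom, tss, strand)`` tuples;
    minus-strand rows are reversed so column 0 is always 5'/upstream.
    """
    if window_bp % binsize:
        raise ValueError("binsize must divide window_bp")
    n_bins = 2 * window_bp // binsize
    rows = np.zeros((len(anchors), n_bins))
    flagged = np.zeros(len(anchors), dtype=bool)
    row_ids: list[str] = []
    for i, a in enumerate(anchors):
        chrom, tss, strand = _anchor_tuple(a)
        vals, clipped = track.per_bp_padded(chrom, tss - window_bp, tss + window_bp)
        row = vals.reshape(n_bins, binsize).mean(axis=1)
        if strand == "-":
            row = row[::-1]
        rows[i] = row
        flagged[i] = clipped
        row_ids.append(
            a.gene_id if isinstance(a, GeneModel) else f"{chrom}:{tss}"
        )
    if ids is not None:
        row_ids = list(ids)
    return ProfileMatrix(row_ids, rows, binsize, "reference_point", flagged=flagged)


def _resample_mean(per_bp: np.ndarray, n_out: int) -> np.ndarray:
    """Length-weighted mean resampling of a per-bp vector to ``n_out`` bins."""
    cum = np.concatenate(([0.0], np.cumsum(per_bp)))
    edges = np.linspace(0.0, len(per_bp), n_out + 1)
    sums = np.interp(edges, np.arange(len(cum)), cum)
    widths = np.diff(edges)
    return np.diff(sums) / widths


def scale_regions_matrix(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    body_bins: int = 100,
    flank_bp: int = 1000,
    binsize: int = 50,
) -> ProfileMatrix:
    """Length-normalized gene-body signal with fixed flanks.

    Columns: ``flank_bp/binsize`` upstream + ``body_bins`` body +
    ``flank_bp/binsize`` downstream, in 5'→3' gene orientation.
    """
    if flank_bp % binsize:
        raise ValueError("binsize must divide flank_bp")
    n_flank = flank_bp // binsize
    n_cols = body_bins + 2 * n_flank
    rows = np.zeros((len(genes), n_cols))
    flagged = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        iv = g.interval
        vals, clipped = track.per_bp_padded(
            iv.chrom, iv.start - flank_bp, iv.end + flank_bp
        )
        if g.strand == "-":
            vals = vals[::-1]
        up = vals[:flank_bp].reshape(n_flank, binsize).mean(axis=1)
        body = _resample_mean(vals[flank_bp:flank_bp + len(iv)], body_bins)
        down = vals[flank_bp + len(iv):].reshape(n_flank, binsize).mean(axis=1)
        rows[i] = np.concatenate([up, body, down])
        flagged[i] = clipped or len(iv) < body_bins
    return ProfileMatrix(
        [g.gene_id for g in genes], rows, binsize, "scale_regions", flagged=flagged
    )


def minmax_normalize(matrices: Sequence[ProfileMatrix]) -> list[ProfileMatrix]:
    """Scale a same-antibody matrix set by one pooled ``1/(max - min)`` factor.

    After scaling, the pooled value range over all cells of all matrices is
    exactly 1.  A constant pooled set gets factor 1 with a warning.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    pooled_max = max(float(m.values.max()) for m in matrices)
    pooled_min = min(float(m.values.min()) for m in matrices)
    if pooled_max == pooled_min:
        warnings.warn("constant pooled matrix set; min-max factor left at 1")
        factor = 1.0
    else:
        factor = 1.0 / (pooled_max - pooled_min)
    return [
        ProfileMatrix(
            list(m.row_ids), m.values * factor, m.binsize, m.anchor,
            minmax_factor=factor, flagged=m.flagged.copy(),
        )
        for m in matrices
    ]


def rank_regions(
    region_ids: Sequence[str],
    signal: Sequence[float],
    rule: Literal["by_signal_desc", "by_signal_asc"] = "by_signal_desc",
) -> list[int]:
    """Stable ranking permutation; ties break by region id."""
    if len(region_ids) != len(signal):
        raise ValueError("signal must align with regions")
    sign = -1.0 if rule == "by_signal_desc" else 1.0
    if rule not in ("by_signal_desc", "by_signal_asc"):
        raise ValueError(f"unknown rule {rule!r}")
    return sorted(
        range(len(region_ids)),
        key=lambda i: (sign * float(signal[i]), region_ids[i]),
    )


def promoter_intensity_summary(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    groups: dict[str, str],
    window_bp: int = 2500,
    test: Literal["wilcoxon", "student_t"] = "wilcoxon",
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], ComparisonResult]]:
    """Per-promoter mean density (TSS +/- window) by group, with pairwise tests.

    ``groups`` maps gene_id -> group label and must cover every gene.  Groups
    with fewer than 2 promoters are reported but skipped in the comparisons.
    """
    values: dict[str, list[float]] = {}
    for g in genes:
        label = groups[g.gene_id]
        tss = g.tss
        vals, _ = track.per_bp_padded(
            g.interval.chrom, tss - window_bp, tss + window_bp
        )
        values.setdefault(label, []).append(float(vals.mean()))
    vectors = {k: np.array(v) for k, v in values.items()}
    comparisons: dict[tuple[str, str], ComparisonResult] = {}
    labels = sorted(vectors)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            if len(vectors[la]) < 2 or len(vectors[lb]) < 2:
                continue
            comparisons[(la, lb)] = compare_densities(
                vectors[la], vectors[lb], test=test
            )
    return vectors, comparisons
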