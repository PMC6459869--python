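"""Analysis geography: Polycomb target regions, flanks, promoters, strata.

A *target region* is a SUZ12 peak passing the significance cutoff that
overlaps (by at least ``min_overlap`` bp) a passing RING1B peak — a
co-occupied PRC2/PRC1 site.  The SUZ12 span defines the region; flank windows
of fixed width abut its two boundaries for the spreading statistic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .io_formats import GeneModel, GenomicInterval, Peak
from .tracks import CoverageTrack

__all__ = [
    "TargetRegion",
    "FlankSet",
    "select_target_regions",
    "spreading_flanks",
    "assign_promoters",
    "stratify_genes",
]

DEFAULT_MIN_NEGLOG10P = 1.0  # p <= 0.1, the peak-call significance cutoff


@dataclass
class TargetRegion:
    """A SUZ12 peak with RING1B evidence; the SUZ12 span defines the region."""

    peak: Peak
    partner: Peak
    gene: GeneModel | None = None
    orientation: Literal["gene_strand", "genomic"] = "genomic"

    @property
    def region_id(self) -> str:
        return self.peak.name

    @property
    def interval(self) -> GenomicInterval:
        return self.peak.interval


@dataclass(frozen=True)
class FlankSet:
    """The inside span and its two abutting flank windows.

    ``out5``/``out3`` are labelled in gene-strand orientation when the region
    has an assigned gene on the minus strand and ``orientation='gene_strand'``;
    otherwise 5' is genomic left.
    """

    inside: GenomicInterval
    out5: GenomicInterval | None
    out3: GenomicInterval | None
    flank_bp: int
    clipped5: bool = False
    clipped3: bool = False

    @property
    def clipped(self) -> bool:
        return self.clipped5 or self.clipped3


def select_target_regions(
    suz12: Sequence[Peak],
    ring1b: Sequence[Peak],
    min_neglog10p: float = DEFAULT_MIN_NEGLOG10P,
    min_overlap: int = 1,
) -> list[TargetRegion]:
    """SUZ12 peaks passing the cutoff that overlap a passing RING1B peak.

    Each selected peak is paired with its maximal-overlap RING1B partner
    (ties: leftmost, then lexicographic name).  Output is genomically sorted.
    """
    def passing(peaks: Sequence[Peak]) -> list[Peak]:
        out = []
        for p in peaks:
            if p.neg_log10_p is None:
                raise ValueError(f"peak {p.name} lacks a p-value")
            if p.neg_log10_p >= min_neglog10p:
                out.append(p)
        return out

    suz_pass = passing(suz12)
    ring_pass = passing(ring1b)
    by_chrom: dict[str, list[Peak]] = {}
    for r in ring_pass:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    chrom_arrays = {
        c: (
            np.array([r.interval.start for r in rs]),
            np.array([r.interval.end for r in rs]),
        )
        for c, rs in by_chrom.items()
    }

    regions: list[TargetRegion] = []
    for s in suz_pass:
        iv = s.interval
        if iv.chrom not in chrom_arrays:
            continue
        starts, ends = chrom_arrays[iv.chrom]
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        ov = np.where(ov > 0, ov, 0)
        if ov.max(initial=0) < min_overlap:
            continue
        cands = np.flatnonzero(ov == ov.max())
        best = min(
            (by_chrom[iv.chrom][int(i)] for i in cands),
            key=lambda r: (r.interval.start, r.name),
        )
        regions.append(TargetRegion(s, best))
    regions.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.interval.end))
    return regions


def spreading_flanks(
    region: TargetRegion,
    flank_bp: int = 1200,
    chrom_lengths: dict[str, int] | None = None,
) -> FlankSet:
    """Fixed-width windows abutting the region's two boundaries.

    Windows are clipped at chromosome bounds and flagged; a boundary with no
    room at all yields ``None`` for that flank (still flagged clipped).
    When the region's orientation is ``gene_strand`` and its gene lies on the
    minus strand, the 5'/3' labels are swapped.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    iv = region.interval
    left_start = max(0, iv.start - flank_bp)
    left = (
        GenomicInterval(iv.chrom, left_start, iv.start)
        if iv.start > 0
        else None
    )
    clipped_left = iv.start - left_start < flank_bp
    length = None if chrom_lengths is None else chrom_lengths[iv.chrom]
    right_end = iv.end + flank_bp if length is None else min(iv.end + flank_bp, length)
    right = (
        GenomicInterval(iv.chrom, iv.end, right_end)
        if right_end > iv.end
        else None
    )
    clipped_right = right_end - iv.end < flank_bp

    flip = (
        region.orientation == "gene_strand"
        and region.gene is not None
        and region.gene.strand == "-"
    )
    if flip:
        out5, out3 = right, left
        c5, c3 = clipped_right, clipped_left
    else:
        out5, out3 = left, right
        c5, c3 = clipped_left, clipped_right
    return FlankSet(iv, out5, out3, flank_bp, c5, c3)


def assign_promoters(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window_bp: int = 2500,
) -> dict[str, GeneModel]:
    """Assign each peak the gene with the nearest TSS within ``window_bp``.

    Distance is from the peak midpoint; equidistant TSSs break by smaller
    gene_id so runs are reproducible.  Returns peak name -> gene.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    tss_sorted = {
        c: sorted(gs, key=lambda g: (g.tss, g.gene_id)) for c, gs in by_chrom.items()
    }
    tss_pos = {c: np.array([g.tss for g in gs]) for c, gs in tss_sorted.items()}

    out: dict[str, GeneModel] = {}
    for p in peaks:
        chrom = p.interval.chrom
        if chrom not in tss_pos:
            continue
        center = (p.interval.start + p.interval.end) // 2
        dist = np.abs(tss_pos[chrom] - center)
        dmin = dist.min()
        if dmin > window_bp:
            continue
        winners = [tss_sorted[chrom][int(i)] for i in np.flatnonzero(dist == dmin)]
        out[p.name] = min(winners, key=lambda g: g.gene_id)
    return out


def _gene_body_density(track: CoverageTrack, gene: GeneModel) -> float:
    iv = gene.interval
    vals, _ = track.per_bp_padded(iv.chrom, iv.start, iv.end)
    return float(vals.mean())


def _kmeans2_threshold(values: np.ndarray) -> float:
    """Deterministic 1-D two-class split (Lloyd's from min/max centers).

    Returns the midpoint between the two final centers; degenerate inputs
    (constant values) get a threshold above the data, i.e. nothing positive.
    """
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return hi + 1.0
    c0, c1 = lo, hi
    for _ in range(100):
        mid = (c0 + c1) / 2.0
        lower, upper = values[values <= mid], values[values > mid]
        n0 = float(lower.mean()) if len(lower) else c0
        n1 = float(upper.mean()) if len(upper) else c1
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    return (c0 + c1) / 2.0


def stratify_genes(
    genes: Sequence[GeneModel],
    target_regions: Sequence[TargetRegion],
    h3k36_track: CoverageTrack,
    threshold: float | None = None,
    threshold_rule: Literal["kmeans2", "median"] = "kmeans2",
    promoter_window: int = 2500,
) -> dict[str, str]:
    """Label every gene PcG, K36pos or K36neg (exhaustive and exclusive).

    PcG: promoter (TSS +/- ``promoter_window``) overlaps a target region —
    this takes precedence whatever the H3K36me3 level.  Remaining genes are
    split on gene-body mean H3K36me3 density: at an absolute ``threshold`` if
    given, otherwise by the ``threshold_rule`` over the non-PcG densities
    (``kmeans2``: deterministic two-class 1-D split; ``median``: strictly
    above the median).
    """
    region_by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in target_regions:
        region_by_chrom.setdefault(t.interval.chrom, []).append(t.interval)

    labels: dict[str, str] = {}
    non_pcg: list[GeneModel] = []
    for g in genes:
        tss = g.tss
        prom = GenomicInterval(
            g.interval.chrom, max(0, tss - promoter_window), tss + promoter_window
        )
        if any(prom.overlap(r) > 0 for r in region_by_chrom.get(prom.chrom, ())):
            labels[g.gene_id] = "PcG"
        else:
            non_pcg.append(g)

    if non_pcg:
        dens = np.array([_gene_body_density(h3k36_track, g) for g in non_pcg])
        if threshold is None:
            if threshold_rule == "median":
                cut = float(np.median(dens))
                positive = dens > cut
            elif threshold_rule == "kmeans2":
                cut = _kmeans2_threshold(dens)
                positive = dens > cut
            else:
                raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
        else:
            positive = dens >= threshold
        for g, pos in zip(non_pcg, positive):
            labels[g.gene_id] = "K36pos" if pos else "K36neg"
    return labels
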