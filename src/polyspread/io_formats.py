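"""Readers/writers for the text formats the pipeline touches.

All coordinates everywhere are 0-based half-open (BED convention).  Files are
UTF-8, tab-separated.  Supported dialects: BED6, ENCODE narrowPeak (10 columns),
bedGraph, and headered TSV truth tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .tracks import CoverageTrack

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "ParseError",
    "read_peaks",
    "write_peaks",
    "read_genes",
    "write_genes",
    "read_bedgraph",
    "write_bedgraph",
]


class ParseError(ValueError):
    """Malformed record; message carries the file and 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str | None = None  # "+", "-" or None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based_closed(
        cls, chrom: str, start: int, end: int, strand: str | None = None
    ) -> "GenomicInterval":
        """Convert a 1-based fully-closed interval (GFF-style) to BED convention."""
        return cls(chrom, start - 1, end, strand)

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak; ``neg_log10_p`` is the −log10 p-value of the call."""

    interval: GenomicInterval
    name: str
    score: float = 0.0
    neg_log10_p: float | None = None

    def __post_init__(self) -> None:
        if self.neg_log10_p is not None and self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")


@dataclass(frozen=True)
class GeneModel:
    """Gene body with a strand-aware TSS."""

    interval: GenomicInterval
    gene_id: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand is required")

    @property
    def strand(self) -> str:
        return self.interval.strand  # type: ignore[return-value]

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


def _lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_peaks(
    path: str | Path, dialect: Literal["narrowPeak", "bed6"] = "narrowPeak"
) -> list[Peak]:
    """Read peak calls, preserving input order.

    narrowPeak column 8 (0-based index 7) is parsed as −log10(p); for bed6 the
    p-value is left unset.
    """
    if dialect not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    ncol = 10 if dialect == "narrowPeak" else 6
    peaks: list[Peak] = []
    for lineno, fields in _lines(path):
        if len(fields) < ncol:
            raise ParseError(
                f"{path}:{lineno}: expected >= {ncol} columns, got {len(fields)}"
            )
        try:
            iv = GenomicInterval(
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[5] if fields[5] in ("+", "-") else None,
            )
            score = float(fields[4])
            neg_log10_p = float(fields[7]) if dialect == "narrowPeak" else None
            peaks.append(Peak(iv, fields[3], score, neg_log10_p))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(
    peaks: Iterable[Peak],
    path: str | Path,
    dialect: Literal["narrowPeak", "bed6"] = "narrowPeak",
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in peaks:
            iv = p.interval
            base = [iv.chrom, str(iv.start), str(iv.end), p.name,
                    f"{p.score:g}", iv.strand or "."]
            if dialect == "narrowPeak":
                nlp = 0.0 if p.neg_log10_p is None else p.neg_log10_p
                base += [f"{nlp:g}", f"{nlp:g}", "-1", "-1"]
                # col7 (signalValue) mirrors -log10 p; cols 9/10 unset per ENCODE
                base[6], base[7] = f"{p.score:g}", f"{nlp:g}"
            fh.write("\t".join(base) + "\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a BED6-like gene table; the strand column is mandatory."""
    genes: list[GeneModel] = []
    for lineno, fields in _lines(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: expected >= 6 columns")
        if fields[5] not in ("+", "-"):
            raise ParseError(
                f"{path}:{lineno}: gene records require strand '+' or '-', "
                f"got {fields[5]!r}"
            )
        try:
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        genes.append(GeneModel(iv, fields[3]))
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n"
            )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued bins.

    Zero-valued runs are written too so the read side can reconstruct the
    track exactly without a chromosome-sizes sidecar.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in track.chroms:
            arr = track.values[chrom]
            length = track.chrom_lengths[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for b0, b1 in zip(starts, ends):
                lo = int(b0) * track.binsize
                hi = min(int(b1) * track.binsize, length)
                fh.write(f"{chrom}\t{lo}\t{hi}\t{float(arr[b0])!r}\n")


def read_bedgraph(
    path: str | Path,
    binsize: int,
    chrom_lengths: dict[str, int],
    genome: str = "target",
    scaled: bool = True,
) -> CoverageTrack:
    """Read a bedGraph into a binned track.

    Input intervals need not be sorted but must not overlap; they must align to
    ``binsize`` boundaries (chromosome ends excepted) for lossless binning.
    """
    values = {
        c: np.zeros(-(-length // binsize)) for c, length in chrom_lengths.items()
    }
    seen = {c: np.zeros(len(v), dtype=bool) for c, v in values.items()}
    for lineno, fields in _lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
        if chrom not in values:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if start % binsize or (end % binsize and end != chrom_lengths[chrom]):
            raise ParseError(
                f"{path}:{lineno}: interval not aligned to binsize {binsize}"
            )
        b0, b1 = start // binsize, -(-end // binsize)
        if seen[chrom][b0:b1].any():
            raise ParseError(f"{path}:{lineno}: overlapping intervals")
        seen[chrom][b0:b1] = True
        values[chrom][b0:b1] = value
    return CoverageTrack(
        binsize=binsize,
        values=values,
        chrom_lengths=dict(chrom_lengths),
        scaled=scaled,
        genome=genome,
    )


def read_reads_bed(path: str | Path) -> list[GenomicInterval]:
    """Read aligned reads stored as BED6 intervals with strand."""
    reads: list[GenomicInterval] = []
    for lineno, fields in _lines(path):
        if len(fields) < 6 or fields[5] not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: reads require 6 columns with strand")
        try:
            reads.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return reads
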