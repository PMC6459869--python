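"""Spike-in (ChIP-Rx) scaling and coverage-track construction.

The scaling convention is reads-per-million-spike-in: for a sample with
``N_spike`` IP reads on the exogenous genome, every coverage bin is multiplied
by ``alpha = 1e6 / N_spike``.  Because the spike-in chromatin amount is constant
across samples, alpha preserves the true between-sample ordering of signal even
under global gains or losses of the mark — the property library-size scaling
destroys.  A ``libsize`` basis (``1e6 / N_target``) is provided for comparison.

Tracks are built the classical way: each read is extended to the expected
fragment length from its 5' end in the strand direction, fragment coverage is
averaged per bin, the scaling factor applied, and (optionally) a scaled input
track subtracted with clamping at zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np

from .io_formats import GenomicInterval
from .tracks import CoverageTrack

__all__ = [
    "ReadSet",
    "Sample",
    "ScalingFactor",
    "CoverageTrack",
    "compute_scaling_factor",
    "build_coverage",
    "subtract_input",
]


class ReadSet:
    """Aligned single-end reads on one genome, stored column-wise.

    Reads are kept as per-chromosome ``(starts, ends, is_plus)`` arrays so
    multi-million-read simulations stay cheap; :meth:`from_intervals` and
    :meth:`__iter__` provide the record view.
    """

    def __init__(
        self,
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        chrom_lengths: dict[str, int],
        genome: Literal["target", "spikein"] = "target",
    ) -> None:
        self.by_chrom = {}
        for chrom, (s, e, plus) in by_chrom.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            plus = np.asarray(plus, dtype=bool)
            if not (len(s) == len(e) == len(plus)):
                raise ValueError(f"{chrom}: ragged read arrays")
            if chrom not in chrom_lengths:
                raise ValueError(f"{chrom}: no chromosome length given")
            if len(s) and (s.min() < 0 or e.max() > chrom_lengths[chrom]):
                raise ValueError(f"{chrom}: read beyond chromosome bounds")
            if len(s) and np.any(s >= e):
                raise ValueError(f"{chrom}: empty or inverted read interval")
            self.by_chrom[chrom] = (s, e, plus)
        self.chrom_lengths = dict(chrom_lengths)
        self.genome = genome

    @classmethod
    def from_intervals(
        cls,
        reads: Iterable[GenomicInterval],
        chrom_lengths: dict[str, int],
        genome: Literal["target", "spikein"] = "target",
    ) -> "ReadSet":
        acc: dict[str, list[tuple[int, int, bool]]] = {}
        for r in reads:
            if r.strand not in ("+", "-"):
                raise ValueError("reads must carry strand")
            acc.setdefault(r.chrom, []).append((r.start, r.end, r.strand == "+"))
        by_chrom = {}
        for chrom, rows in acc.items():
            arr = np.array(rows, dtype=np.int64)
            by_chrom[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2].astype(bool))
        for chrom in chrom_lengths:
            by_chrom.setdefault(
                chrom,
                (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, bool)),
            )
        return cls(by_chrom, chrom_lengths, genome)

    @property
    def n_reads(self) -> int:
        return sum(len(s) for s, _, _ in self.by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom, (s, e, plus) in self.by_chrom.items():
            for i in range(len(s)):
                yield GenomicInterval(
                    chrom, int(s[i]), int(e[i]), "+" if plus[i] else "-"
                )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for chrom, (s, e, plus) in self.by_chrom.items():
                for i in range(len(s)):
                    strand = "+" if plus[i] else "-"
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\tr\t0\t{strand}\n")


@dataclass(frozen=True)
class ScalingFactor:
    alpha: float
    basis: Literal["spikein", "libsize"]

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")


@dataclass
class Sample:
    """One condition/antibody's four read sets plus its scaling factor."""

    condition: str
    antibody: str
    ip_target: ReadSet
    ip_spikein: ReadSet | None = None
    input_target: ReadSet | None = None
    input_spikein: ReadSet | None = None
    factor: ScalingFactor | None = None


def compute_scaling_factor(
    sample: Sample, basis: Literal["spikein", "libsize"] = "spikein"
) -> ScalingFactor:
    """ChIP-Rx alpha = 1e6 / N(IP spike-in); libsize alpha = 1e6 / N(IP target)."""
    if basis == "spikein":
        if sample.ip_spikein is None or sample.ip_spikein.n_reads == 0:
            raise ValueError(
                f"{sample.condition}/{sample.antibody}: spike-in basis requested "
                "but the IP spike-in read set is empty"
            )
        return ScalingFactor(1e6 / sample.ip_spikein.n_reads, "spikein")
    if basis == "libsize":
        if sample.ip_target.n_reads == 0:
            raise ValueError("empty IP target read set")
        return ScalingFactor(1e6 / sample.ip_target.n_reads, "libsize")
    raise ValueError(f"unknown basis {basis!r}")


def build_coverage(
    readset: ReadSet,
    fragment_length: int = 200,
    binsize: int = 50,
    factor: ScalingFactor | None = None,
) -> CoverageTrack:
    """Fragment-extended, binned, scaled coverage.

    Each read is extended to ``fragment_length`` bp from its 5' end in the
    strand direction (clipped at chromosome ends); the bin value is
    ``alpha * (fragment-bp overlapping the bin) / binsize``.
    """
    if binsize < 1:
        raise ValueError("binsize must be >= 1")
    alpha = 1.0 if factor is None else factor.alpha
    values: dict[str, np.ndarray] = {}
    for chrom, length in readset.chrom_lengths.items():
        s, e, plus = readset.by_chrom.get(
            chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0, bool),)
        )
        # fragment [5', 5'+L) on +, (3'..5'] on -; clip at chromosome ends
        frag_start = np.where(plus, s, np.maximum(e - fragment_length, 0))
        frag_end = np.where(plus, np.minimum(s + fragment_length, length), e)
        delta = np.zeros(length + 1)
        np.add.at(delta, frag_start, 1.0)
        np.add.at(delta, frag_end, -1.0)
        cov = np.cumsum(delta[:-1])
        n_bins = -(-length // binsize)
        pad = n_bins * binsize - length
        if pad:
            cov = np.concatenate((cov, np.zeros(pad)))
        values[chrom] = alpha * cov.reshape(n_bins, binsize).sum(axis=1) / binsize
    return CoverageTrack(
        binsize=binsize,
        values=values,
        chrom_lengths=dict(readset.chrom_lengths),
        scaled=factor is not None,
        genome=readset.genome,
    )


def subtract_input(ip: CoverageTrack, input_track: CoverageTrack) -> CoverageTrack:
    """Per-bin ``max(ip − input, 0)``; both tracks must already be scaled."""
    if ip.binsize != input_track.binsize:
        raise ValueError("binsize mismatch between IP and input tracks")
    if set(ip.values) != set(input_track.values) or ip.chrom_lengths != input_track.chrom_lengths:
        raise ValueError("chromosome sets differ between IP and input tracks")
    values = {
        c: np.maximum(ip.values[c] - input_track.values[c], 0.0) for c in ip.values
    }
    return CoverageTrack(
        binsize=ip.binsize,
        values=values,
        chrom_lengths=dict(ip.chrom_lengths),
        scaled=True,
        genome=ip.genome,
    )
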