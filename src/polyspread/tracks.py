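"""Binned genome coverage tracks.

A :class:`CoverageTrack` stores one scaled (or raw) signal value per fixed-width
bin per chromosome.  The per-bp signal is piecewise constant within a bin, which
is the convention every density computation in the package relies on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoverageTrack"]


@dataclass
class CoverageTrack:
    """Per-chromosome binned signal.

    Parameters
    ----------
    binsize:
        Bin width in bp (>= 1).
    values:
        Mapping chromosome -> 1-D float array of length ``ceil(length/binsize)``.
    chrom_lengths:
        Mapping chromosome -> chromosome length in bp.
    scaled:
        Whether a scaling factor has been applied.
    genome:
        Free-text genome label ("target" / "spikein" / assembly name).
    """

    binsize: int
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    scaled: bool = False
    genome: str = "target"

    def __post_init__(self) -> None:
        if self.binsize < 1:
            raise ValueError("binsize must be >= 1")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            self.values[chrom] = arr
            if chrom not in self.chrom_lengths:
                raise ValueError(f"no length recorded for chromosome {chrom!r}")
            expected = -(-self.chrom_lengths[chrom] // self.binsize)
            if len(arr) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(arr)}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{chrom}: non-finite bin values")

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} not in track")
        if start < 0 or end > self.chrom_lengths[chrom] or start >= end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds"
            )

    def per_bp(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Signal expanded to one value per bp over ``[start, end)``.

        Positions beyond the chromosome are not permitted; use
        :meth:`per_bp_padded` for windows that may overhang.
        """
        self.check_interval(chrom, start, end)
        idx = np.arange(start, end) // self.binsize
        return self.values[chrom][idx]

    def per_bp_padded(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, bool]:
        """Like :meth:`per_bp` but zero-fills out-of-chromosome positions.

        Returns ``(values, clipped)`` where ``clipped`` flags any zero-filled
        overhang.
        """
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} not in track")
        if start >= end:
            raise ValueError("empty window")
        length = self.chrom_lengths[chrom]
        lo, hi = max(start, 0), min(end, length)
        out = np.zeros(end - start, dtype=float)
        if lo < hi:
            out[lo - start : hi - start] = self.per_bp(chrom, lo, hi)
        return out, (lo != start or hi != end)

    def scale(self, factor: float) -> "CoverageTrack":
        """Return a new track with every bin multiplied by ``factor``."""
        return CoverageTrack(
            binsize=self.binsize,
            values={c: v * factor for c, v in self.values.items()},
            chrom_lengths=dict(self.chrom_lengths),
            scaled=True,
            genome=self.genome,
        )

    def genome_mean(self) -> float:
        """Length-weighted mean per-bp signal over the whole track."""
        total = 0.0
        nbp = 0
        for chrom, arr in self.values.items():
            length = self.chrom_lengths[chrom]
            # last bin may be partial; weight it by the bp it actually covers
            full = length // self.binsize
            total += arr[:full].sum() * self.binsize
            if full < len(arr):
                total += arr[full] * (length - full * self.binsize)
            nbp += length
        return total / nbp if nbp else 0.0
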