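"""Genome binning and interval↔bin arithmetic.

The genome is partitioned per contig into fixed-width, non-overlapping,
strand-less bins (default 200 bp, roughly one nucleosome plus spacer).
Bins are indexed globally across contigs in contig order; all internal
coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GridError",
    "GenomicInterval",
    "BinGrid",
    "CountTrack",
    "partition_genome",
    "intervals_to_bin_mask",
]


class GridError(ValueError):
    """Invalid grid construction or coordinate lookup."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with optional strand and label."""

    contig: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GridError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise GridError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class BinGrid:
    """Fixed-width binning of an ordered set of contigs.

    Parameters
    ----------
    contigs
        Ordered ``(name, length_bp)`` pairs.
    bin_width
        Bin width in bp. The last bin of a contig may be shorter.
    """

    def __init__(self, contigs: Sequence[tuple[str, int]], bin_width: int = 200):
        if bin_width <= 0:
            raise GridError(f"bin_width must be positive, got {bin_width}")
        names = [name for name, _ in contigs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GridError(f"duplicate contig names: {dupes}")
        for name, length in contigs:
            if length <= 0:
                raise GridError(f"contig {name!r} has non-positive length {length}")
        self.contigs: list[tuple[str, int]] = [(str(n), int(l)) for n, l in contigs]
        self.bin_width = int(bin_width)
        self._nbins = np.array(
            [-(-length // bin_width) for _, length in self.contigs], dtype=np.int64
        )
        self._offsets = np.concatenate([[0], np.cumsum(self._nbins)])
        self._index = {name: i for i, (name, _) in enumerate(self.contigs)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    def __len__(self) -> int:
        return self.n_bins

    def has_contig(self, name: str) -> bool:
        return name in self._index

    def contig_length(self, name: str) -> int:
        return self.contigs[self._contig_idx(name)][1]

    def contig_offset(self, name: str) -> int:
        """Global index of the first bin of *name*."""
        return int(self._offsets[self._contig_idx(name)])

    def contig_nbins(self, name: str) -> int:
        return int(self._nbins[self._contig_idx(name)])

    def contig_slice(self, name: str) -> slice:
        i = self._contig_idx(name)
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def _contig_idx(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise GridError(f"unknown contig {name!r}") from None

    # -- coordinate mapping ------------------------------------------------
    def bin_index(self, contig: str, pos: int) -> int:
        """Global index of the bin containing bp position *pos*."""
        i = self._contig_idx(contig)
        if not 0 <= pos < self.contigs[i][1]:
            raise GridError(f"position {pos} outside contig {contig!r}")
        return int(self._offsets[i] + pos // self.bin_width)

    def bin_bounds(self, gidx: int) -> tuple[str, int, int]:
        """(contig, start_bp, end_bp) of the bin with global index *gidx*."""
        if not 0 <= gidx < self.n_bins:
            raise GridError(f"bin index {gidx} out of range [0, {self.n_bins})")
        ci = int(np.searchsorted(self._offsets, gidx, side="right")) - 1
        name, length = self.contigs[ci]
        local = gidx - int(self._offsets[ci])
        start = local * self.bin_width
        return name, start, min(start + self.bin_width, length)

    def interval_bins(self, interval: GenomicInterval) -> range:
        """Global indices of bins overlapping *interval* by >= 1 bp.

        Out-of-range interval parts are truncated to the contig.
        """
        i = self._contig_idx(interval.contig)
        length = self.contigs[i][1]
        start = max(0, interval.start)
        end = min(length, interval.end)
        if start >= end:
            return range(0)
        off = int(self._offsets[i])
        return range(off + start // self.bin_width, off + (end - 1) // self.bin_width + 1)

    def bin_table(self):
        """Per-bin (bin, contig, start, end) table used by the TSV writers."""
        import pandas as pd

        rows = {"bin": np.arange(self.n_bins, dtype=np.int64)}
        contig_col = np.empty(self.n_bins, dtype=object)
        start_col = np.empty(self.n_bins, dtype=np.int64)
        end_col = np.empty(self.n_bins, dtype=np.int64)
        for ci, (name, length) in enumerate(self.contigs):
            sl = slice(int(self._offsets[ci]), int(self._offsets[ci + 1]))
            n = sl.stop - sl.start
            contig_col[sl] = name
            starts = np.arange(n, dtype=np.int64) * self.bin_width
            start_col[sl] = starts
            end_col[sl] = np.minimum(starts + self.bin_width, length)
        rows["contig"] = contig_col
        rows["start"] = start_col
        rows["end"] = end_col
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinGrid)
            and self.contigs == other.contigs
            and self.bin_width == other.bin_width
        )

    def __repr__(self) -> str:
        return (
            f"BinGrid({len(self.contigs)} contigs, width={self.bin_width}, "
            f"{self.n_bins} bins)"
        )


@dataclass
class CountTrack:
    """Per-bin non-negative integer read counts for one experiment."""

    grid: BinGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (self.grid.n_bins,):
            raise GridError(
                f"count track length {self.values.shape} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        if (self.values < 0).any():
            raise GridError("count track has negative entries")

    @property
    def total(self) -> int:
        return int(self.values.sum())


def partition_genome(
    chrom_sizes: Sequence[tuple[str, int]] | Mapping[str, int],
    bin_width: int = 200,
) -> BinGrid:
    """Partition contigs into non-overlapping fixed-width bins.

    ``chrom_sizes`` is an ordered ``(name, length)`` sequence or mapping, as
    read from a two-column chrom.sizes file.
    """
    if isinstance(chrom_sizes, Mapping):
        chrom_sizes = list(chrom_sizes.items())
    return BinGrid(chrom_sizes, bin_width=bin_width)


def intervals_to_bin_mask(
    intervals: Iterable[GenomicInterval],
    grid: BinGrid,
    strand: str | None = None,
) -> np.ndarray:
    """Binary per-bin vector: 1 iff >= 1 bp of any interval overlaps the bin.

    Strand is ignored unless *strand* is given, in which case only intervals
    on that strand contribute. Intervals on contigs absent from the grid are
    an error; out-of-range parts are truncated.
    """
    mask = np.zeros(grid.n_bins, dtype=np.uint8)
    for iv in intervals:
        if strand is not None and iv.strand != strand:
            continue
        bins = grid.interval_bins(iv)
        if len(bins) > 0:
            mask[bins.start : bins.stop] = 1
    return mask
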