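"""Readers and writers: chrom.sizes, BED, GTF, per-bin TSV tables, BAM counts.

All readers convert to the internal 0-based half-open convention at the
boundary (GTF is 1-based inclusive on disk). Writers round-trip losslessly
with their readers. Lines starting with ``#`` are treated as comments in the
text formats, which is where provenance headers are written.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import BinGrid, CountTrack, GenomicInterval, GridError

__all__ = [
    "FormatError",
    "Transcript",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_gtf",
    "write_gtf",
    "write_bin_table",
    "read_bin_table",
    "count_reads_midpoint",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    """Read a two-column ``contig<TAB>length`` table."""
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                length = int(fields[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
            out.append((fields[0], length))
    return out


def write_chrom_sizes(contigs: Sequence[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in contigs:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 as 0-based half-open intervals.

    Column 4 (name) is kept as the interval label, column 6 as the strand.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end or start < 0:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            out.append(GenomicInterval(fields[0], start, end, strand, label))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
    header: str | None = None,
) -> None:
    """Write BED6 (score column 0 unless *scores* given)."""
    intervals = list(intervals)
    if scores is not None and len(scores) != len(intervals):
        raise ValueError("scores length does not match intervals")
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            name = iv.label or f"iv_{i}"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GTF


@dataclass
class Transcript:
    """A transcript with its exon chain, 0-based half-open, genome order."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"transcript {self.id}: strand must be + or -")
        if self.start >= self.end:
            raise FormatError(f"transcript {self.id}: start >= end")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < self.start or e > self.end:
                raise FormatError(f"transcript {self.id}: exon [{s},{e}) out of bounds")
            if s < prev_end:
                raise FormatError(f"transcript {self.id}: overlapping exons")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand, self.id)


def _gtf_attr(attrs: str, key: str) -> str | None:
    # GTF2.2: key "value"; GFF3: key=value
    for sep, quote in ((' "', '"'), ("=", ";")):
        token = key + sep
        i = attrs.find(token)
        if i >= 0:
            j = i + len(token)
            k = attrs.find(quote, j)
            return attrs[j:k] if k >= 0 else attrs[j:].strip()
    return None


def read_gtf(path: str | Path) -> list[Transcript]:
    """Read transcripts and their exons from GTF2.2/GFF3.

    On-disk coordinates are 1-based inclusive and converted to 0-based
    half-open on ingest. Transcripts without an explicit ``transcript``
    feature are derived from the span of their exons.
    """
    spans: dict[str, list] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _, feature, start1, end1, _, strand, _, attrs = fields
            if feature not in ("transcript", "exon", "mRNA"):
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid coordinates")
            tid = _gtf_attr(attrs, "transcript_id") or _gtf_attr(attrs, "ID")
            if tid is None:
                raise FormatError(f"{path}:{lineno}: missing transcript_id")
            if tid not in spans:
                spans[tid] = [contig, None, None, strand]
                order.append(tid)
            rec = spans[tid]
            if rec[0] != contig or rec[3] != strand:
                raise FormatError(f"{path}:{lineno}: transcript {tid} changes contig/strand")
            if feature in ("transcript", "mRNA"):
                rec[1], rec[2] = start, end
            else:
                exons.setdefault(tid, []).append((start, end))
    out = []
    for tid in order:
        contig, start, end, strand = spans[tid]
        ex = sorted(exons.get(tid, []))
        if start is None:
            if not ex:
                raise FormatError(f"{path}: transcript {tid} has no coordinates")
            start, end = ex[0][0], ex[-1][1]
        if not ex:
            ex = [(start, end)]
        out.append(Transcript(tid, contig, start, end, strand, ex))
    return out


def write_gtf(transcripts: Iterable[Transcript], path: str | Path, source: str = "epigene") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
            fh.write(
                f"{t.contig}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# per-bin TSV tables (counts and class matrices share one layout)


def write_bin_table(
    grid: BinGrid,
    columns: Mapping[str, np.ndarray],
    path: str | Path,
    header: str | None = None,
) -> None:
    """Write a per-bin table: bin, contig, start, end, then one data column each.

    Used for both count tracks (integer counts) and class matrices (0/1 calls).
    """
    df = grid.bin_table()
    for name, values in columns.items():
        values = np.asarray(values)
        if values.shape != (grid.n_bins,):
            raise FormatError(f"column {name!r} length {values.shape} != {grid.n_bins} bins")
        df[name] = values
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_bin_table(path: str | Path) -> tuple[BinGrid, pd.DataFrame]:
    """Read a per-bin table and reconstruct its grid.

    The bin width is the modal bin span in the file (the last bin of a contig
    may be shorter); contig lengths are the last ``end`` per contig.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["bin", "contig", "start", "end"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: first columns must be {required}, got {list(df.columns[:4])}")
    widths = (df["end"] - df["start"]).to_numpy()
    bin_width = int(np.max(widths))
    contigs = [
        (str(name), int(sub["end"].iloc[-1]))
        for name, sub in df.groupby("contig", sort=False)
    ]
    grid = BinGrid(contigs, bin_width=bin_width)
    if grid.n_bins != len(df):
        raise FormatError(f"{path}: table rows ({len(df)}) disagree with inferred grid ({grid.n_bins})")
    if not np.array_equal(df["bin"].to_numpy(), np.arange(grid.n_bins)):
        raise FormatError(f"{path}: bin index column is not 0..{grid.n_bins - 1}")
    return grid, df.drop(columns=required)


# ---------------------------------------------------------------------------
# BAM / SAM fragment counting


def count_reads_midpoint(
    alignments,
    grid: BinGrid,
    min_mapq: int = 255,
    exclude_flag: int = 1024,
    missing_contig: str = "warn",
) -> CountTrack:
    """Count fragment midpoints per bin from a BAM/SAM file or pysam handle.

    Each retained fragment contributes exactly 1 to the bin containing its
    midpoint, ``floor((leftmost_start + rightmost_end) / 2)``. Properly paired
    fragments are counted once, at the leftmost read of the pair (template
    length > 0). Reads with MAPQ < *min_mapq* or any bit of *exclude_flag*
    set (default: 1024, PCR/optical duplicates) are dropped. Single-end reads
    contribute their own midpoint, with a warning.

    *missing_contig* is ``"warn"`` (skip reads on contigs absent from the
    grid, warn once per contig) or ``"error"``.
    """
    import pysam

    own_handle = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        own_handle = True
    values = np.zeros(grid.n_bins, dtype=np.int64)
    warned_single = False
    warned_contigs: set[str] = set()
    try:
        for read in alignments.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if read.flag & exclude_flag:
                continue
            if read.mapping_quality < min_mapq:
                continue
            contig = read.reference_name
            if not grid.has_contig(contig):
                if missing_contig == "error":
                    raise GridError(f"contig {contig!r} in alignments absent from grid")
                if contig not in warned_contigs:
                    warnings.warn(f"skipping reads on contig {contig!r} absent from grid")
                    warned_contigs.add(contig)
                continue
            if read.is_paired:
                if not read.is_proper_pair:
                    continue
                tlen = read.template_length
                if tlen <= 0:  # count each pair once, at its leftmost read
                    continue
                midpoint = read.reference_start + tlen // 2
            else:
                if not warned_single:
                    warnings.warn("single-end reads encountered; using read midpoints")
                    warned_single = True
                midpoint = (read.reference_start + read.reference_end) // 2
            if 0 <= midpoint < grid.contig_length(contig):
                values[grid.bin_index(contig, midpoint)] += 1
    finally:
        if own_handle:
            alignments.close()
    return CountTrack(grid, values)
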