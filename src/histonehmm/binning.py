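"""Genome binning and read counting.

Broad histone marks (H3K27me3, H3K9me3, ...) produce diffuse multi-kilobase
read distributions, so the genome is partitioned into fixed-width windows
(1000 bp by default) and the start positions of uniquely mapping reads are
aggregated per window.  Extreme windows are truncated at the upper 0.1
percentile of the genome-wide counts to guard against pile-up artifacts and
numerically tiny emission probabilities downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd


class Read(NamedTuple):
    """Minimal aligned-read record: 0-based half-open interval plus strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    mapq: int | None = None


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-width tiling of a genome.

    Each chromosome of length L is tiled by ``ceil(L / bin_size)`` half-open
    windows ``[k*bin_size, (k+1)*bin_size)``; the last window of a chromosome
    is clipped to the chromosome end.  Bin order is chromosome by chromosome,
    then by start coordinate.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int = 1000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if len(self.chrom_names) == 0:
            raise ValueError("empty chromosome sizes table")
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def n_bins_per_chrom(self) -> dict[str, int]:
        return {
            name: math.ceil(length / self.bin_size)
            for name, length in zip(self.chrom_names, self.chrom_lengths)
        }

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_per_chrom.values())

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the concatenated per-bin vectors covering one chromosome."""
        per = self.n_bins_per_chrom
        offset = 0
        for name in self.chrom_names:
            n = per[name]
            if name == chrom:
                return slice(offset, offset + n)
            offset += n
        raise KeyError(f"chromosome {chrom!r} not in GenomeBins")

    def iter_bins(self) -> Iterator[tuple[str, int, int]]:
        """Yield (chrom, start, end) for every bin in order."""
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            n = math.ceil(length / self.bin_size)
            for k in range(n):
                start = k * self.bin_size
                yield name, start, min(start + self.bin_size, length)

    def bin_table(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) DataFrame."""
        return pd.DataFrame(self.iter_bins(), columns=["chrom", "start", "end"])

    @property
    def total_basepairs(self) -> int:
        return sum(self.chrom_lengths)

    @property
    def largest_chrom(self) -> str:
        i = int(np.argmax(self.chrom_lengths))
        return self.chrom_names[i]


@dataclass
class BinnedTrack:
    """Per-bin read counts for one sample over a :class:`GenomeBins`."""

    genome_bins: GenomeBins
    counts: np.ndarray
    sample_id: str = "sample"
    truncation_value: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != self.genome_bins.n_bins:
            raise ValueError(
                f"counts length {len(self.counts)} does not match "
                f"{self.genome_bins.n_bins} bins"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def chrom_counts(self, chrom: str) -> np.ndarray:
        return self.counts[self.genome_bins.chrom_slice(chrom)]

    def per_chrom(self) -> list[np.ndarray]:
        """Counts split into per-chromosome arrays, in chromosome order."""
        return [self.chrom_counts(c) for c in self.genome_bins.chrom_names]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column (name, length) chromosome sizes file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"empty chromosome sizes table: {path}")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def iter_bam_reads(path: str | Path, min_mapq: int = 1) -> Iterator[Read]:
    """Stream uniquely mapping reads from a BAM/SAM file.

    Reads that are unmapped, secondary, supplementary or below ``min_mapq``
    are skipped; BED input is assumed pre-filtered and bypasses this.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            yield Read(
                chrom=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end or aln.reference_start + 1,
                strand="-" if aln.is_reverse else "+",
                mapq=aln.mapping_quality,
            )


def iter_bed_reads(path: str | Path) -> Iterator[Read]:
    """Stream read intervals from a 3+-column BED file (0-based half-open)."""
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            strand = parts[5] if len(parts) > 5 else "+"
            yield Read(parts[0], int(parts[1]), int(parts[2]), strand)


def bin_reads(
    reads: Iterable[Read],
    genome: dict[str, int] | GenomeBins,
    bin_size: int = 1000,
    sample_id: str = "sample",
    strand_aware_5prime: bool = False,
    drop_duplicates: bool = False,
) -> BinnedTrack:
    """Count read start positions into fixed-width genome bins.

    Each read contributes 1 to the bin containing its leftmost aligned
    coordinate (or its 5' coordinate when ``strand_aware_5prime`` is set,
    which for reverse-strand reads is ``end - 1``).  Reads on chromosomes
    absent from the sizes table are tallied and reported via a warning, not
    silently dropped.  ``drop_duplicates`` removes reads sharing
    (chrom, start, strand), a convenience for data without upstream
    PCR-duplicate removal.
    """
    if isinstance(genome, GenomeBins):
        bins = genome
    else:
        if not genome:
            raise ValueError("empty chromosome sizes table")
        if bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {bin_size}")
        bins = GenomeBins(tuple(genome), tuple(genome.values()), bin_size)

    counts = np.zeros(bins.n_bins, dtype=np.int64)
    per = bins.n_bins_per_chrom
    offsets: dict[str, int] = {}
    off = 0
    for name in bins.chrom_names:
        offsets[name] = off
        off += per[name]

    skipped: dict[str, int] = {}
    seen: set[tuple[str, int, str]] = set()
    for read in reads:
        if read.chrom not in offsets:
            skipped[read.chrom] = skipped.get(read.chrom, 0) + 1
            continue
        if strand_aware_5prime and read.strand == "-":
            pos = read.end - 1
        else:
            pos = read.start
        if drop_duplicates:
            key = (read.chrom, pos, read.strand)
            if key in seen:
                continue
            seen.add(key)
        idx = pos // bins.bin_size
        if idx >= per[read.chrom]:
            idx = per[read.chrom] - 1  # clip reads hanging off the chrom end
        counts[offsets[read.chrom] + idx] += 1

    if skipped:
        total = sum(skipped.values())
        warnings.warn(
            f"{total} reads on chromosomes absent from the sizes table were "
            f"skipped: {skipped}",
            stacklevel=2,
        )
    return BinnedTrack(bins, counts, sample_id=sample_id)


def truncate_counts(track: BinnedTrack, upper_quantile: float = 0.999) -> BinnedTrack:
    """Cap counts at the genome-wide empirical quantile of the sample.

    The threshold is the nearest-rank (type-1) quantile at ``upper_quantile``
    of all counts of the sample, pooled across chromosomes; every count above
    it is set to the threshold.  Returns a new track; idempotent.
    """
    if not 0 < upper_quantile <= 1:
        raise ValueError(f"upper_quantile must be in (0, 1], got {upper_quantile}")
    counts = track.counts
    if len(counts) == 0:
        raise ValueError("cannot truncate an empty track")
    srt = np.sort(counts)
    rank = math.ceil(upper_quantile * len(counts)) - 1  # nearest-rank, 0-based
    q = int(srt[rank])
    return BinnedTrack(
        track.genome_bins,
        np.minimum(counts, q),
        sample_id=track.sample_id,
        truncation_value=q,
    )


def write_count_table(
    tracks: Sequence[BinnedTrack], path: str | Path
) -> None:
    """Write tracks sharing one GenomeBins as a tab-separated count table."""
    bins = tracks[0].genome_bins
    for t in tracks[1:]:
        if t.genome_bins != bins:
            raise ValueError("all tracks must share the same GenomeBins")
    df = bins.bin_table()
    for t in tracks:
        df[f"count_{t.sample_id}"] = t.counts
    df.to_csv(path, sep="\t", index=False)


def load_count_table(path: str | Path) -> list[BinnedTrack]:
    """Load a ``chrom  start  end  count_*...`` table into BinnedTracks.

    The bin width is inferred from the first row; every bin except the last
    of a chromosome must have that width, and bins must tile each chromosome
    contiguously from zero.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError("count table needs chrom, start, end and >=1 count column")
    chrom_col, start_col, end_col = df.columns[:3]
    count_cols = list(df.columns[3:])
    bin_size = int(df[end_col].iloc[0] - df[start_col].iloc[0])
    if bin_size <= 0:
        raise ValueError("non-positive bin width in first row")

    names: list[str] = []
    lengths: list[int] = []
    for chrom, sub in df.groupby(chrom_col, sort=False):
        starts = sub[start_col].to_numpy()
        ends = sub[end_col].to_numpy()
        if starts[0] != 0:
            raise ValueError(f"chromosome {chrom}: bins must start at 0")
        for i in range(len(sub)):
            if i < len(sub) - 1 and ends[i] - starts[i] != bin_size:
                raise ValueError(
                    f"non-constant bin width at row {chrom}:{starts[i]}-{ends[i]}"
                )
            if i > 0 and starts[i] != ends[i - 1]:
                raise ValueError(
                    f"gap between bins at row {chrom}:{starts[i]}-{ends[i]}"
                )
        names.append(str(chrom))
        lengths.append(int(ends[-1]))

    bins = GenomeBins(tuple(names), tuple(lengths), bin_size)
    tracks = []
    for col in count_cols:
        vals = df[col].to_numpy()
        if not np.all(vals == np.floor(vals)) or np.any(vals < 0):
            raise ValueError(f"column {col}: counts must be non-negative integers")
        sample = col[len("count_"):] if col.startswith("count_") else col
        tracks.append(BinnedTrack(bins, vals.astype(np.int64), sample_id=sample))
    return tracks
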