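"""From aligned reads to a truncated count table and back.

Builds a small set of read records in memory, bins their start positions
into 1 kb windows, caps the extreme upper tail, and round-trips the result
through the tab-separated count-table format that the calling pipelines
accept directly.
"""

import numpy as np

from histonehmm import (
    Read,
    bin_reads,
    load_count_table,
    truncate_counts,
    write_count_table,
)

rng = np.random.default_rng(0)
chrom_sizes = {"chr1": 2_000_000, "chr2": 1_000_000}

# ~50 reads/bin on average, plus a pile-up artifact at one position
reads = [Read("chr1", int(p), int(p) + 36) for p in rng.integers(0, 2_000_000, 100_000)]
reads += [Read("chr2", int(p), int(p) + 36) for p in rng.integers(0, 1_000_000, 50_000)]
reads += [Read("chr1", 50_000, 50_036)] * 500  # e.g. a collapsed repeat

track = bin_reads(reads, chrom_sizes, bin_size=1000, sample_id="H3K27me3_rep1")
print(f"{track.counts.sum()} reads binned into {track.genome_bins.n_bins} bins; "
      f"max bin count {track.counts.max()} (the artifact bin)")

capped = truncate_counts(track, upper_quantile=0.999)
print(f"after truncation at the 0.999 genome-wide quantile "
      f"(= {capped.truncation_value} reads) the max bin count is "
      f"{capped.counts.max()}")

write_count_table([capped], "scratch_counts.tsv")
(reloaded,) = load_count_table("scratch_counts.tsv")
assert np.array_equal(reloaded.counts, capped.counts)
print("count table written to scratch_counts.tsv and reloaded identically")
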