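"""Count reads per transcription unit and normalize to RPKM.

Builds a two-gene annotation and a handful of mapped-read intervals in
memory, counts overlaps with BEDTools-coverage semantics (>= 1 bp overlap
counts), and converts to reads per kilobase per million mapped reads.
"""
from epiloop import (
    GenomicInterval,
    LibraryStats,
    SampleDescriptor,
    TranscriptionUnit,
    UnitSet,
    count_overlapping_reads,
    rpkm,
)

units = UnitSet([
    TranscriptionUnit(GenomicInterval("Chr1", 100, 1100, "+"), "gene_a"),
    TranscriptionUnit(GenomicInterval("Chr1", 2000, 4000, "-"), "gene_b"),
])

reads = [
    GenomicInterval("Chr1", 150, 250),    # inside gene_a
    GenomicInterval("Chr1", 1090, 1190),  # 10 bp overlap with gene_a: counts
    GenomicInterval("Chr1", 1100, 1200),  # zero overlap (half-open): does not
    GenomicInterval("Chr1", 2500, 2600),  # inside gene_b
    GenomicInterval("Chr1", 3900, 4100),  # tail overlap with gene_b
]

counts = count_overlapping_reads(reads, units)
lib = LibraryStats(SampleDescriptor("WT", "H3K36me3", 1), total_mapped_reads=10**6)

print("unit\tlength\tcount\tRPKM")
for u in units:
    value = rpkm(counts[u.id], u.length, lib)
    print(f"{u.id}\t{u.length}\t{counts[u.id]}\t{value:.3f}")

# gene_a: 2 of 5 reads overlap its 1 kb body -> RPKM = 2e9/(1000*1e6) = 2.0.
# RPKM scales counts by unit length and library size so marks can be
# compared across genes and samples.
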