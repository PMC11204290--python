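"""Per-transcription-unit read counting and normalization.

Counting follows BEDTools-coverage semantics: a read is counted for every
unit it overlaps by at least one base. RPKM uses the total mapped-read
library size (which includes reads outside any unit); TPM renormalizes
length-corrected rates to one million.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import GenomicInterval, SampleDescriptor, SignalTable, UnitSet


@dataclass(frozen=True)
class LibraryStats:
    """Library size for normalization (total mapped reads, not in-unit reads)."""

    sample: SampleDescriptor
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads < 1:
            raise ValueError("total_mapped_reads must be >= 1")


def count_overlapping_reads(
    reads: Sequence[GenomicInterval],
    units: UnitSet,
    stranded: str = "none",
) -> dict[str, int]:
    """Count reads overlapping each unit by >= 1 bp.

    stranded="same" keeps reads whose strand equals the unit strand,
    "opposite" the reverse; either mode rejects unstranded (".") reads.
    A read overlapping several units counts once for each.
    """
    if stranded not in ("none", "same", "opposite"):
        raise ValueError(f"invalid stranded mode {stranded!r}")
    trees: dict[str, IntervalTree] = {}
    for u in units:
        iv = u.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, u)
    counts = {u.id: 0 for u in units}
    for r in reads:
        if stranded != "none" and r.strand == ".":
            raise ValueError("stranded counting requires stranded reads")
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(r.start, r.end):
            u = hit.data
            if stranded == "same" and r.strand != u.interval.strand:
                continue
            if stranded == "opposite" and r.strand == u.interval.strand:
                continue
            counts[u.id] += 1
    return counts


def counts_to_table(
    counts_by_sample: Mapping[SampleDescriptor, Mapping[str, int]],
    units: UnitSet,
) -> SignalTable:
    samples = list(counts_by_sample)
    ids = units.ids()
    values = np.array(
        [[counts_by_sample[s][uid] for s in samples] for uid in ids], dtype=float
    )
    return SignalTable(ids, samples, values, "count")


def rpkm(count: float, unit_length_bp: int, lib: LibraryStats) -> float:
    """Reads per kilobase of unit per million mapped reads."""
    if unit_length_bp < 1:
        raise ValueError("unit length must be >= 1 bp")
    return count * 1e9 / (unit_length_bp * lib.total_mapped_reads)


def rpkm_table(
    counts: SignalTable, units: UnitSet, libs: Mapping[SampleDescriptor, LibraryStats]
) -> SignalTable:
    """Convert a count table to RPKM column by column."""
    lengths = np.array([units[uid].length for uid in counts.units], dtype=float)
    values = np.empty_like(counts.values)
    for j, s in enumerate(counts.samples):
        total = libs[s].total_mapped_reads
        values[:, j] = counts.values[:, j] * 1e9 / (lengths * total)
    return SignalTable(list(counts.units), list(counts.samples), values, "rpkm")


def tpm(counts: Sequence[float], lengths: Sequence[int]) -> np.ndarray:
    """Transcripts per million: length-corrected rates scaled to sum 1e6."""
    c = np.asarray(counts, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if np.any(ln < 1):
        raise ValueError("all unit lengths must be >= 1")
    if not np.any(c > 0):
        raise ValueError("TPM undefined when all counts are zero")
    rate = c / ln
    return 1e6 * rate / rate.sum()


def log2_tpm_offset(tpm_value, offset: float = 0.05):
    """log2(TPM + offset); the offset keeps silent units finite."""
    arr = np.asarray(tpm_value, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("TPM values must be non-negative")
    out = np.log2(arr + offset)
    return float(out) if np.isscalar(tpm_value) else out


def average_replicates(table: SignalTable) -> SignalTable:
    """Mean over replicates within each (genotype, assay, line) group.

    NaN propagates: a group mean is missing if any replicate is missing.
    """
    if not table.samples:
        raise ValueError("cannot average an empty table")
    groups: dict[tuple, list[int]] = {}
    for i, s in enumerate(table.samples):
        groups.setdefault((s.genotype, s.assay, s.line), []).append(i)
    out_samples = []
    cols = []
    for (genotype, assay, line), idx in groups.items():
        out_samples.append(SampleDescriptor(genotype, assay, 1, line))
        cols.append(table.values[:, idx].mean(axis=1))  # NaN propagates
    return SignalTable(
        list(table.units), out_samples, np.column_stack(cols), table.kind
    )


def choose_te_strand(
    sense_counts_by_sample: Mapping[SampleDescriptor, float],
    antisense_counts_by_sample: Mapping[SampleDescriptor, float],
) -> str:
    """Pick the transcribed strand of a TE gene by total counts over samples.

    Ties go to sense.
    """
    if set(sense_counts_by_sample) != set(antisense_counts_by_sample):
        raise ValueError("sense/antisense counts must cover the same samples")
    sense_total = sum(sense_counts_by_sample.values())
    anti_total = sum(antisense_counts_by_sample.values())
    return "antisense" if anti_total > sense_total else "sense"
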