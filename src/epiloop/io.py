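"""Readers and writers for the text formats the pipeline touches.

Formats: BED6 (0-based half-open), GFF3 (1-based inclusive, converted at
this boundary), bedGraph coverage, Bismark-style per-cytosine CX reports
(1-based), and the package's own TSV signal tables with ``#`` metadata lines.
"""
from __future__ import annotations

import logging
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .core import (
    CONTEXTS,
    CytosineCall,
    GenomicInterval,
    SampleDescriptor,
    SignalTable,
    TranscriptionUnit,
    UnitSet,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record; the message names the file and line number."""


def _error(path, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- annotation


def read_annotation(
    path,
    format: str = "bed6",
    te_gene_ids: Optional[Iterable[str]] = None,
    biotype_attribute: str = "biotype",
) -> UnitSet:
    """Read transcription units from BED6 or GFF3.

    BED6 biotype comes from the sidecar ``te_gene_ids`` list (default
    protein_coding); GFF3 biotype from the attribute named by
    ``biotype_attribute`` when present.
    """
    if format not in ("bed6", "gff3"):
        raise ValueError(f"unknown annotation format {format!r}")
    te_ids = set(te_gene_ids or ())
    units = UnitSet()
    n = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if format == "bed6":
                    chrom, start, end, uid = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    strand = fields[5] if len(fields) > 5 else "."
                    biotype = "te_gene" if uid in te_ids else "protein_coding"
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 record needs 9 columns")
                    chrom = fields[0]
                    # GFF3 is 1-based inclusive
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6]
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    uid = attrs.get("ID")
                    if uid is None:
                        raise ValueError("GFF3 record lacks an ID attribute")
                    biotype = attrs.get(biotype_attribute, "protein_coding")
                    if uid in te_ids:
                        biotype = "te_gene"
                unit = TranscriptionUnit(
                    GenomicInterval(chrom, start, end, strand), uid, biotype
                )
            except (ValueError, IndexError) as exc:
                raise _error(path, lineno, str(exc)) from exc
            try:
                units.add(unit)
            except ValueError as exc:
                raise _error(path, lineno, str(exc)) from exc
            n += 1
    if n == 0:
        logger.warning("annotation file %s contained no records", path)
    return units


def write_annotation_bed6(path, units: UnitSet) -> None:
    with open(path, "w") as fh:
        for u in units:
            iv = u.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{u.id}\t0\t{iv.strand}\n")


# ------------------------------------------------------------- read intervals


def read_read_intervals(path) -> list[GenomicInterval]:
    """Read mapped-read intervals from a BED3+ file, in file order."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) > 5 else "."
                out.append(GenomicInterval(chrom, start, end, strand))
            except (ValueError, IndexError) as exc:
                raise _error(path, lineno, str(exc)) from exc
    return out


def write_read_intervals_bed(path, reads: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")


# ----------------------------------------------------------------- coverage


class CoverageTrack:
    """Piecewise-constant per-base coverage; 0 wherever no record covers.

    Backed by sorted, non-overlapping segments per chromosome, with a
    cumulative integral so bin means over arbitrary (fractional) spans are
    exact.
    """

    def __init__(self, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # segments: chrom -> (starts, ends, values), sorted and disjoint
        self._seg = segments
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (starts, ends, values) in segments.items():
            areas = (ends - starts).astype(float) * values
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(areas)])

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]], source: str = "<records>"
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if start >= end:
                raise ValueError(f"{source}: empty/inverted record {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        segments = {}
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"{source}: overlapping bedGraph records on {chrom} near "
                    f"{starts[i + 1]}"
                )
            segments[chrom] = (starts, ends, values)
        return cls(segments)

    def chroms(self) -> list[str]:
        return sorted(self._seg)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self._seg:
            return 0.0
        starts, ends, values = self._seg[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def _cumulative(self, chrom: str, x: float) -> float:
        """Integral of coverage over (-inf, x)."""
        starts, ends, values = self._seg[chrom]
        cum = self._cum[chrom]
        i = int(np.searchsorted(starts, x, side="right")) - 1
        if i < 0:
            return 0.0
        total = float(cum[i])  # full segments strictly before segment i
        total += float(values[i]) * (min(x, float(ends[i])) - float(starts[i]))
        return total

    def integral(self, chrom: str, a: float, b: float) -> float:
        """Integral of per-base coverage over [a, b)."""
        if b <= a:
            return 0.0
        if chrom not in self._seg:
            return 0.0
        return self._cumulative(chrom, b) - self._cumulative(chrom, a)

    def mean(self, chrom: str, a: float, b: float) -> float:
        if b <= a:
            raise ValueError("empty span")
        return self.integral(chrom, a, b) / (b - a)

    def add_constant(self, c: float) -> "CoverageTrack":
        """A track with c added everywhere coverage is defined (segment-wise).

        Only meaningful when the segments tile every position of interest.
        """
        out = {
            chrom: (starts.copy(), ends.copy(), values + c)
            for chrom, (starts, ends, values) in self._seg.items()
        }
        return CoverageTrack(out)


def read_coverage(path) -> CoverageTrack:
    """Read a bedGraph file into a CoverageTrack (overlaps are an error)."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except (ValueError, IndexError) as exc:
                raise _error(path, lineno, str(exc)) from exc
    try:
        return CoverageTrack.from_records(records, source=str(path))
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_coverage_bedgraph(path, track: CoverageTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            starts, ends, values = track._seg[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


# ----------------------------------------------------------- cytosine report


def read_cytosine_report(path) -> Iterator[CytosineCall]:
    """Stream per-cytosine calls from a Bismark CX-style report.

    Columns: chrom, pos (1-based), strand, n_meth, n_unmeth, context
    [, trinucleotide]. Zero-coverage cytosines are retained.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 6:
                    raise ValueError("CX report record needs >= 6 columns")
                context = fields[5]
                if context not in CONTEXTS:
                    raise ValueError(f"unknown cytosine context {context!r}")
                yield CytosineCall(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    strand=fields[2],
                    context=context,
                    n_meth=int(fields[3]),
                    n_unmeth=int(fields[4]),
                )
            except ValueError as exc:
                raise _error(path, lineno, str(exc)) from exc


def write_cytosine_report(path, calls: Iterable[CytosineCall]) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.n_meth}\t{c.n_unmeth}\t"
                f"{c.context}\t{c.context}\n"
            )


# -------------------------------------------------------------- signal table


def write_table(path, table: SignalTable, metadata: Optional[dict] = None) -> None:
    """Write a SignalTable as TSV with '#'-prefixed metadata lines."""
    with open(path, "w") as fh:
        fh.write(f"#kind={table.kind}\n")
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        fh.write("unit\t" + "\t".join(s.key() for s in table.samples) + "\n")
        for uid, row in zip(table.units, table.values):
            cells = ["NA" if np.isnan(v) else f"{v:.12g}" for v in row]
            fh.write(uid + "\t" + "\t".join(cells) + "\n")


def read_table(path) -> SignalTable:
    kind = "rpkm"
    units: list[str] = []
    rows: list[list[float]] = []
    samples: Optional[list[SampleDescriptor]] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#kind="):
                    kind = line.split("=", 1)[1]
                continue
            fields = line.split("\t")
            if samples is None:
                if fields[0] != "unit":
                    raise _error(path, lineno, "expected header starting with 'unit'")
                try:
                    samples = [SampleDescriptor.from_key(k) for k in fields[1:]]
                except ValueError as exc:
                    raise _error(path, lineno, str(exc)) from exc
                continue
            if len(fields) != len(samples) + 1:
                raise _error(
                    path, lineno,
                    f"row has {len(fields) - 1} values for {len(samples)} samples",
                )
            units.append(fields[0])
            rows.append([np.nan if c == "NA" else float(c) for c in fields[1:]])
    if samples is None:
        raise ParseError(f"{path}: no header row found")
    values = np.array(rows, dtype=float).reshape(len(units), len(samples))
    return SignalTable(units, samples, values, kind)


# -------------------------------------------------------------- sample sheet


def read_sample_sheet(path) -> list[tuple[SampleDescriptor, dict]]:
    """Read a TSV sample sheet: genotype, assay, replicate[, line, ...extras].

    Extra columns (e.g. total_mapped_reads, path) are returned as a dict.
    """
    out = []
    header: Optional[list[str]] = None
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for col in ("genotype", "assay", "replicate"):
                    if col not in header:
                        raise _error(path, lineno, f"sample sheet lacks column {col!r}")
                continue
            rec = dict(zip(header, fields))
            line_val = rec.get("line") or None
            desc = SampleDescriptor(
                rec["genotype"], rec["assay"], int(rec["replicate"]), line_val
            )
            if desc in seen:
                raise _error(path, lineno, f"duplicate sample {desc.key()}")
            seen.add(desc)
            extras = {
                k: v for k, v in rec.items()
                if k not in ("genotype", "assay", "replicate", "line")
            }
            out.append((desc, extras))
    return out
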