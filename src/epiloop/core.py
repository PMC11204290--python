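"""Domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open. Conversion to and from
1-based conventions (GFF3, per-cytosine reports) happens only in
:mod:`epiloop.io`, at the format boundary.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

STRANDS = ("+", "-", ".")
CONTEXTS = ("CG", "CHG", "CHH")
BIOTYPES = ("protein_coding", "te_gene")

TABLE_KINDS = ("count", "rpkm", "tpm", "log2tpm", "methylation_level")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptionUnit:
    """A gene or TE gene: the unit over which all signals are aggregated."""

    interval: GenomicInterval
    id: str
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"invalid biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return len(self.interval)


class UnitSet:
    """An ordered collection of transcription units with unique ids."""

    def __init__(self, units: Sequence[TranscriptionUnit] = ()):
        self._units: list[TranscriptionUnit] = []
        self._by_id: dict[str, TranscriptionUnit] = {}
        for u in units:
            self.add(u)

    def add(self, unit: TranscriptionUnit) -> None:
        if unit.id in self._by_id:
            raise ValueError(f"duplicate transcription-unit id {unit.id!r}")
        self._units.append(unit)
        self._by_id[unit.id] = unit

    def __len__(self) -> int:
        return len(self._units)

    def __iter__(self) -> Iterator[TranscriptionUnit]:
        return iter(self._units)

    def __contains__(self, unit_id: str) -> bool:
        return unit_id in self._by_id

    def __getitem__(self, unit_id: str) -> TranscriptionUnit:
        return self._by_id[unit_id]

    def ids(self) -> list[str]:
        return [u.id for u in self._units]

    def subset(self, ids: Sequence[str]) -> "UnitSet":
        return UnitSet([self._by_id[i] for i in ids])


@dataclass(frozen=True)
class SampleDescriptor:
    """One sequencing sample: genotype x assay x replicate (x transgenic line)."""

    genotype: str
    assay: str
    replicate: int = 1
    line: Optional[str] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    def key(self) -> str:
        """Stable text encoding used in table headers."""
        parts = [self.genotype, self.assay, f"r{self.replicate}"]
        if self.line is not None:
            parts.append(self.line)
        return ".".join(parts)

    @classmethod
    def from_key(cls, key: str) -> "SampleDescriptor":
        parts = key.split(".")
        if len(parts) not in (3, 4) or not parts[2].startswith("r"):
            raise ValueError(f"cannot parse sample key {key!r}")
        line = parts[3] if len(parts) == 4 else None
        return cls(parts[0], parts[1], int(parts[2][1:]), line)


@dataclass(frozen=True)
class CytosineCall:
    """Methylation read counts at one cytosine (1-based position)."""

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid cytosine context {self.context!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative methylation counts")

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass
class SignalTable:
    """A units x samples matrix of per-unit signal values.

    Missing values are NaN (explicitly distinct from zero: zero RPKM means
    measured-and-empty, NaN means unmeasured).
    """

    units: list[str]
    samples: list[SampleDescriptor]
    values: np.ndarray
    kind: str = "rpkm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.units), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.units)} units x {len(self.samples)} samples"
            )
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"invalid table kind {self.kind!r}")
        if len(set(self.units)) != len(self.units):
            raise ValueError("duplicate unit ids in SignalTable")
        keys = [s.key() for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate sample descriptors in SignalTable")
        if self.kind == "count":
            finite = self.values[np.isfinite(self.values)]
            if np.any(finite < 0):
                raise ValueError("count table contains negative values")
        if self.kind == "methylation_level":
            finite = self.values[np.isfinite(self.values)]
            if np.any((finite < 0) | (finite > 1)):
                raise ValueError("methylation levels must lie in [0, 1]")

    def column(self, sample: SampleDescriptor) -> np.ndarray:
        return self.values[:, self.samples.index(sample)]

    def select_samples(self, keep) -> "SignalTable":
        """Subset columns by a predicate over SampleDescriptor."""
        idx = [i for i, s in enumerate(self.samples) if keep(s)]
        return SignalTable(
            list(self.units),
            [self.samples[i] for i in idx],
            self.values[:, idx].copy(),
            self.kind,
        )

    def series(self, sample_key: str) -> dict[str, float]:
        keys = [s.key() for s in self.samples]
        col = self.values[:, keys.index(sample_key)]
        return dict(zip(self.units, col))

    def equals(self, other: "SignalTable", rtol: float = 0.0) -> bool:
        if (
            self.units != other.units
            or self.samples != other.samples
            or self.kind != other.kind
        ):
            return False
        a, b = self.values, other.values
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, atol=0.0)
        return bool(np.all(both_nan | close))
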