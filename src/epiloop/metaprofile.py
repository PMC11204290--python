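"""Scaled gene-body average profiles (metaplots).

Each unit contributes one row: upstream flank in fixed-width bins, the body
rescaled into a fixed number of bins, then the downstream flank. Bin values
are exact means of per-base coverage over the (possibly fractional) bin
span. Minus-strand units are reversed so every profile reads 5'->3'.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CytosineCall, UnitSet
from .io import CoverageTrack


@dataclass
class MetaProfile:
    n_flank_bins: int
    n_body_bins: int
    flank_bp: int
    unit_ids: list[str]
    matrix: np.ndarray  # units x (2*n_flank + n_body); NaN = off-chromosome bin
    mean_profile: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        width = 2 * self.n_flank_bins + self.n_body_bins
        if self.matrix.shape != (len(self.unit_ids), width):
            raise ValueError("metaprofile matrix shape mismatch")
        counts = np.sum(~np.isnan(self.matrix), axis=0)
        with np.errstate(invalid="ignore"):
            sums = np.nansum(self.matrix, axis=0)
        self.mean_profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _bin_edges(start: float, end: float, n_bins: int) -> np.ndarray:
    return start + (end - start) * np.arange(n_bins + 1) / n_bins


def _unit_bin_edges(
    unit, flank_bp: int, n_body_bins: int, n_flank_bins: int
) -> np.ndarray:
    """All bin edges for one unit, left-to-right in genome coordinates."""
    iv = unit.interval
    up = _bin_edges(iv.start - flank_bp, iv.start, n_flank_bins)
    body = _bin_edges(iv.start, iv.end, n_body_bins)
    down = _bin_edges(iv.end, iv.end + flank_bp, n_flank_bins)
    return np.concatenate([up[:-1], body[:-1], down])


def scaled_metaprofile(
    track: CoverageTrack,
    units: UnitSet,
    flank_bp: int = 2000,
    n_body_bins: int = 100,
    n_flank_bins: int = 40,
    normalize: str = "none",
    library_size: int | None = None,
) -> MetaProfile:
    """Average coverage per scaled bin over a set of units.

    normalize="per_million" divides by library_size / 1e6. Bins reaching
    below coordinate 0 are NaN and excluded from the mean profile.
    """
    if len(units) == 0:
        raise ValueError("metaprofile needs a non-empty unit set")
    if n_body_bins < 1 or n_flank_bins < 1 or flank_bp < 1:
        raise ValueError("bin parameters must be >= 1")
    if normalize not in ("none", "per_million"):
        raise ValueError(f"invalid normalize mode {normalize!r}")
    scale = 1.0
    if normalize == "per_million":
        if not library_size or library_size < 1:
            raise ValueError("per_million normalization needs a library size")
        scale = 1e6 / library_size

    width = 2 * n_flank_bins + n_body_bins
    matrix = np.empty((len(units), width))
    ids = []
    for i, unit in enumerate(units):
        edges = _unit_bin_edges(unit, flank_bp, n_body_bins, n_flank_bins)
        chrom = unit.interval.chrom
        row = np.empty(width)
        for b in range(width):
            a, bnd = edges[b], edges[b + 1]
            if a < 0:  # off the left chromosome end
                row[b] = np.nan
            else:
                row[b] = track.integral(chrom, a, bnd) / (bnd - a)
        if unit.interval.strand == "-":
            row = row[::-1]
        matrix[i] = row * scale
        ids.append(unit.id)
    return MetaProfile(n_flank_bins, n_body_bins, flank_bp, ids, matrix)


def methylation_metaprofile(
    calls: list[CytosineCall],
    units: UnitSet,
    context: str,
    flank_bp: int = 2000,
    n_body_bins: int = 100,
    n_flank_bins: int = 40,
) -> MetaProfile:
    """Weighted methylation per scaled bin: sum n_meth / sum total within bin.

    Cytosines of the requested context from both strands are pooled; bins
    with no covered cytosine are NaN.
    """
    if len(units) == 0:
        raise ValueError("metaprofile needs a non-empty unit set")
    by_chrom: dict[str, list[CytosineCall]] = {}
    for c in calls:
        if c.context == context:
            by_chrom.setdefault(c.chrom, []).append(c)
    pos_by_chrom = {
        chrom: np.array([c.pos - 1 for c in cs])  # to 0-based
        for chrom, cs in by_chrom.items()
    }
    width = 2 * n_flank_bins + n_body_bins
    matrix = np.full((len(units), width), np.nan)
    ids = []
    for i, unit in enumerate(units):
        edges = _unit_bin_edges(unit, flank_bp, n_body_bins, n_flank_bins)
        chrom = unit.interval.chrom
        cs = by_chrom.get(chrom, [])
        positions = pos_by_chrom.get(chrom)
        row = np.full(width, np.nan)
        if cs:
            bin_of = np.searchsorted(edges, positions, side="right") - 1
            meth = np.zeros(width)
            total = np.zeros(width)
            for c, b in zip(cs, bin_of):
                if 0 <= b < width:
                    meth[b] += c.n_meth
                    total[b] += c.total
            covered = total > 0
            row[covered] = meth[covered] / total[covered]
        row[edges[:-1] < 0] = np.nan
        if unit.interval.strand == "-":
            row = row[::-1]
        matrix[i] = row
        ids.append(unit.id)
    return MetaProfile(n_flank_bins, n_body_bins, flank_bp, ids, matrix)


def write_metaprofile_tsv(path, profile: MetaProfile) -> None:
    n_units = len(profile.unit_ids)
    with open(path, "w") as fh:
        fh.write(f"#n_flank_bins={profile.n_flank_bins}\n")
        fh.write(f"#n_body_bins={profile.n_body_bins}\n")
        fh.write(f"#flank_bp={profile.flank_bp}\n")
        fh.write("bin\tregion\tmean\tn_units\n")
        nf, nb = profile.n_flank_bins, profile.n_body_bins
        for b, v in enumerate(profile.mean_profile):
            region = "upstream" if b < nf else ("body" if b < nf + nb else "downstream")
            n_used = int(np.sum(~np.isnan(profile.matrix[:, b])))
            cell = "NA" if np.isnan(v) else f"{v:.10g}"
            fh.write(f"{b}\t{region}\t{cell}\t{n_used}\n")
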