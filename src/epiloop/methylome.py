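"""Weighted methylation levels by context and the TE-silencing classifiers.

The weighted methylation level of a region is the ratio of methylated
cytosine read calls to all cytosine read calls within it, per context
(both strands pooled). The two classifiers test, over reciprocal F1
hybrids, whether losing the demethylase (LDL2) lowers mCHG establishment
or losing the methyltransferase (ASHH3) raises it, consistently across
both crosses and both biological replicates (four comparisons in total),
after a coverage filter of more than ``min_counts`` CHG read calls in
every sample and replicate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import CONTEXTS, CytosineCall, TranscriptionUnit, UnitSet


@dataclass(frozen=True)
class UnitMethylation:
    unit_id: str
    context: str
    n_meth_total: int
    n_total: int

    @property
    def level(self) -> float:
        """Weighted methylation level; NaN when no call covers the unit."""
        if self.n_total == 0:
            return float("nan")
        return self.n_meth_total / self.n_total


@dataclass(frozen=True)
class TEClassification:
    unit_id: str
    label: str  # ldl2_regulated | ashh3_regulated | none
    diffs: tuple[float, ...]
    coverage_ok: bool


def context_of(triplet: str) -> str:
    """Cytosine context of a 3-mer read 5'->3' on the cytosine's strand."""
    t = triplet.upper()
    if len(t) != 3 or t[0] != "C":
        raise ValueError(f"triplet {triplet!r} must start with C")
    if t[1] == "G":
        return "CG"
    if t[2] == "G":
        return "CHG"
    return "CHH"


def weighted_methylation(
    calls: Iterable[CytosineCall], unit: TranscriptionUnit, context: str
) -> UnitMethylation:
    """Pool calls of one context within the unit's interval (both strands)."""
    if context not in CONTEXTS:
        raise ValueError(f"invalid context {context!r}")
    iv = unit.interval
    n_meth = 0
    n_total = 0
    for c in calls:
        if c.context != context or c.chrom != iv.chrom:
            continue
        if iv.start <= c.pos - 1 < iv.end:  # report positions are 1-based
            n_meth += c.n_meth
            n_total += c.total
    return UnitMethylation(unit.id, context, n_meth, n_total)


def unit_methylation_table(
    calls: Sequence[CytosineCall], units: UnitSet, context: str
) -> dict[str, UnitMethylation]:
    """Per-unit weighted methylation for every unit, one pass over calls."""
    # per-chrom sorted positions with prefix sums -> O(log) per unit
    by_chrom: dict[str, list[CytosineCall]] = {}
    for c in calls:
        if c.context == context:
            by_chrom.setdefault(c.chrom, []).append(c)
    index = {}
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: c.pos)
        pos = np.array([c.pos for c in cs], dtype=np.int64)
        cum_m = np.concatenate([[0], np.cumsum([c.n_meth for c in cs])])
        cum_t = np.concatenate([[0], np.cumsum([c.total for c in cs])])
        index[chrom] = (pos, cum_m, cum_t)
    out = {}
    for u in units:
        iv = u.interval
        if iv.chrom in index:
            pos, cum_m, cum_t = index[iv.chrom]
            lo = int(np.searchsorted(pos, iv.start + 1, side="left"))
            hi = int(np.searchsorted(pos, iv.end, side="right"))
            out[u.id] = UnitMethylation(
                u.id, context, int(cum_m[hi] - cum_m[lo]), int(cum_t[hi] - cum_t[lo])
            )
        else:
            out[u.id] = UnitMethylation(u.id, context, 0, 0)
    return out


MethBySample = Mapping[str, Mapping[int, Mapping[str, UnitMethylation]]]
# genotype -> replicate -> unit_id -> UnitMethylation


def _classify_four_way(
    meth: MethBySample,
    unit_ids: Sequence[str],
    genotype_pairs: Sequence[tuple[str, str]],
    replicates: Sequence[int],
    min_counts: int,
    threshold: float,
    direction: str,  # "below" or "above"
    label: str,
) -> dict[str, TEClassification]:
    for mut, ref in genotype_pairs:
        for g in (mut, ref):
            if g not in meth:
                raise ValueError(f"missing genotype {g!r} in methylation data")
            for rep in replicates:
                if rep not in meth[g]:
                    raise ValueError(f"missing replicate {rep} for genotype {g!r}")
    out = {}
    for uid in unit_ids:
        diffs = []
        coverage_ok = True
        for mut, ref in genotype_pairs:
            for rep in replicates:
                m_mut = meth[mut][rep][uid]
                m_ref = meth[ref][rep][uid]
                if m_mut.n_total <= min_counts or m_ref.n_total <= min_counts:
                    coverage_ok = False
                diffs.append(m_mut.level - m_ref.level)
        if direction == "below":
            passes = all(np.isfinite(d) and d < threshold for d in diffs)
        else:
            passes = all(np.isfinite(d) and d > threshold for d in diffs)
        out[uid] = TEClassification(
            uid, label if (coverage_ok and passes) else "none",
            tuple(diffs), coverage_ok,
        )
    return out


def classify_ldl2_regulated(
    meth: MethBySample,
    unit_ids: Sequence[str],
    min_counts: int = 100,
    threshold: float = -0.05,
    replicates: Sequence[int] = (1, 2),
) -> dict[str, TEClassification]:
    """TE genes whose mCHG establishment depends on the H3K4me1 demethylase.

    Labelled iff (i) CHG read-call totals exceed min_counts in both
    replicates of all four F1 samples and (ii) the replicate-matched mCHG
    differences (cxs_ldl2 - cxs_LDL2) and (sxc_ldl2 - sxc_LDL2) are all
    strictly below the (negative) threshold.
    """
    pairs = [("cxs_ldl2", "cxs_LDL2"), ("sxc_ldl2", "sxc_LDL2")]
    return _classify_four_way(
        meth, unit_ids, pairs, replicates, min_counts, threshold,
        "below", "ldl2_regulated",
    )


def classify_ashh3_regulated(
    meth: MethBySample,
    unit_ids: Sequence[str],
    min_counts: int = 100,
    threshold: float = 0.05,
    replicates: Sequence[int] = (1, 2),
) -> dict[str, TEClassification]:
    """TE genes whose mCHG establishment is restrained by the H3K36
    methyltransferase: all four replicate-matched mCHG differences
    (cxs_ashh3 - cxs_ASHH3), (sxc_ashh3 - sxc_ASHH3) strictly above the
    threshold, with the same coverage filter."""
    pairs = [("cxs_ashh3", "cxs_ASHH3"), ("sxc_ashh3", "sxc_ASHH3")]
    return _classify_four_way(
        meth, unit_ids, pairs, replicates, min_counts, threshold,
        "above", "ashh3_regulated",
    )


def write_te_classification_tsv(path, calls: Mapping[str, TEClassification]) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tlabel\tcoverage_ok\tdiffs\n")
        for uid, c in calls.items():
            diffs = ",".join(
                "NA" if not np.isfinite(d) else f"{d:.6g}" for d in c.diffs
            )
            fh.write(f"{uid}\t{c.label}\t{int(c.coverage_ok)}\t{diffs}\n")
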