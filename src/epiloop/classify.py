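"""Replicate-consistent change calls, gene categorization, FLAG-tag
binding/enrichment calls, and the figure-level statistics.

A gene changes only when every matched replicate pair moves the same way by
more than the threshold (strict inequality, default |delta RPKM| > 3). The
FLAG-ASHH3 calls use the same "in every line" logic with thresholds 5
(enriched in the mutant) and 2 (bound above the nontransgenic control).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ChangeCall:
    gene: str
    direction: str  # up | down | stay
    deltas: tuple[float, ...]
    flagged_missing: bool = False


@dataclass(frozen=True)
class GeneCategory:
    gene: str
    h3k9: str
    h3k36: str
    h3k4: str
    label: str


def call_change(
    gene: str,
    wt_reps: Sequence[float],
    mut_reps: Sequence[float],
    delta: float = 3.0,
) -> ChangeCall:
    """Call up/down/stay from replicate-matched RPKM differences.

    direction=up iff every (mut - wt) > +delta; down iff every < -delta;
    otherwise stay. Missing values force stay and set flagged_missing.
    """
    if len(wt_reps) != len(mut_reps):
        raise ValueError(
            f"{gene}: replicate count mismatch ({len(wt_reps)} vs {len(mut_reps)})"
        )
    if len(wt_reps) == 0:
        raise ValueError(f"{gene}: no replicates")
    diffs = tuple(float(m) - float(w) for w, m in zip(wt_reps, mut_reps))
    if any(not np.isfinite(d) for d in diffs):
        return ChangeCall(gene, "stay", diffs, flagged_missing=True)
    if all(d > delta for d in diffs):
        direction = "up"
    elif all(d < -delta for d in diffs):
        direction = "down"
    else:
        direction = "stay"
    return ChangeCall(gene, direction, diffs)


def call_change_table(
    table, wt_genotype: str, mut_genotype: str, assay: str, delta: float = 3.0
) -> dict[str, ChangeCall]:
    """call_change over every unit of a SignalTable for one contrast."""
    def reps(genotype):
        cols = sorted(
            (s for s in table.samples if s.genotype == genotype and s.assay == assay),
            key=lambda s: s.replicate,
        )
        if not cols:
            raise ValueError(f"no {assay} samples for genotype {genotype}")
        return np.column_stack([table.column(s) for s in cols])

    wt = reps(wt_genotype)
    mut = reps(mut_genotype)
    return {
        uid: call_change(uid, wt[i], mut[i], delta)
        for i, uid in enumerate(table.units)
    }


def categorize_genes(
    h3k9_calls: Mapping[str, ChangeCall],
    h3k36_calls: Mapping[str, ChangeCall],
    h3k4_calls: Mapping[str, ChangeCall],
) -> list[GeneCategory]:
    """Partition H3K9me2-gaining genes by their H3K36me3 and H3K4me1 calls.

    Genes not gaining H3K9me2 are labelled "background". Every H3K9me2-up
    gene gets exactly one H3K36me3 sub-label (up/down/stay) and one H3K4me1
    sub-label (down/stay; an H3K4me1 "up" counts as stay for labelling).
    """
    universe = set(h3k9_calls)
    if universe != set(h3k36_calls) or universe != set(h3k4_calls):
        raise ValueError("change-call sets cover different gene universes")
    out = []
    for gene in h3k9_calls:
        k9 = h3k9_calls[gene].direction
        k36 = h3k36_calls[gene].direction
        k4 = h3k4_calls[gene].direction
        if k9 != "up":
            label = "background"
        else:
            label = f"H3K9me2 up H3K36me3 {k36}"
        k4_label = "down" if k4 == "down" else "stay"
        out.append(GeneCategory(gene, k9, k36, k4_label, label))
    return out


def _all_lines_exceed(
    a_by_line: Mapping[str, float], b_by_line: Mapping[str, float], delta: float
) -> bool:
    if set(a_by_line) != set(b_by_line):
        raise ValueError("line sets differ between the two conditions")
    if len(a_by_line) < 2:
        raise ValueError("call requires both transgenic lines")
    return all(a_by_line[l] - b_by_line[l] > delta for l in a_by_line)


def call_flag_enriched(
    flag_mut: Mapping[str, float], flag_wt: Mapping[str, float], delta: float = 5.0
) -> bool:
    """True iff the tagged-protein RPKM gain in the mutant exceeds delta in
    every transgenic line (strict)."""
    return _all_lines_exceed(flag_mut, flag_wt, delta)


def call_flag_bound(
    flag_wt: Mapping[str, float], control: Mapping[str, float], delta: float = 2.0
) -> bool:
    """True iff tagged-protein RPKM exceeds the nontransgenic control by
    delta in every line (strict)."""
    return _all_lines_exceed(flag_wt, control, delta)


# --------------------------------------------------------------- statistics


def hypergeom_enrichment(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """One-sided over-representation p-value P(X >= overlap),
    X ~ Hypergeometric(universe, set_a, set_b)."""
    k, m, n, N = overlap, set_a, set_b, universe
    if not (0 <= k <= min(m, n) and m <= N and n <= N and m >= 0 and n >= 0):
        raise ValueError(
            f"inconsistent hypergeometric counts k={k}, m={m}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def paired_t(values_a: Sequence[float], values_b: Sequence[float]):
    """Paired t test: one-sample t on the per-gene differences, df = n - 1.

    Returns (t, two-sided p). Degenerate zero-variance differences: all-zero
    gives (0, 1); constant nonzero differences give (inf-signed t, p = 0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    keep = np.isfinite(a) & np.isfinite(b)
    d = (a - b)[keep]
    n = len(d)
    if n < 2:
        raise ValueError("paired t needs >= 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return t, p


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_below: int = 10
):
    """Spearman rank correlation with average ranks.

    Returns (rho, two-sided p). p comes from the t approximation; below
    ``exact_below`` complete pairs an exact permutation p is used instead.
    Zero rank variance (all ties) -> (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs >= 3 complete pairs")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = float(stats.pearsonr(rx, ry).statistic)
    if n < exact_below:
        from itertools import permutations

        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float(stats.pearsonr(rx, ry[list(perm)]).statistic)
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p
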