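"""Correlation screen for silencer / anti-silencer chromatin features.

The per-gene statistic is the fractional decrease of H3K4me1 in the H3K9
demethylase mutant, (RPKM_WT - RPKM_mut) / RPKM_WT, computed over genes
that gain H3K9me2. Each candidate chromatin feature (its wild-type level)
is correlated against this decrease; features are ranked by signed R^2 —
positive for silencer candidates (high feature level, more loss), negative
for anti-silencer candidates (high level, less loss).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenResult:
    feature: str
    pearson_r: float
    r_squared: float
    signed_r2: float
    n: int


@dataclass(frozen=True)
class DecreaseResult:
    """Per-gene decrease values plus the genes excluded for zero WT signal."""

    decrease: dict[str, float]
    excluded: frozenset[str]


def h3k4me1_decrease(
    rpkm_wt: Mapping[str, float], rpkm_mut: Mapping[str, float]
) -> DecreaseResult:
    """Fractional H3K4me1 loss per gene: (wt - mut) / wt.

    1 is total loss, 0 no change, negative values a gain. Genes with zero
    (or missing) WT signal are excluded, not errors: the statistic is
    undefined there.
    """
    decrease: dict[str, float] = {}
    excluded = set()
    for gene, wt in rpkm_wt.items():
        if gene not in rpkm_mut:
            excluded.add(gene)
            continue
        mut = rpkm_mut[gene]
        if not np.isfinite(wt) or not np.isfinite(mut) or wt <= 0:
            excluded.add(gene)
            continue
        decrease[gene] = (wt - mut) / wt
    return DecreaseResult(decrease, frozenset(excluded))


def screen_features(
    decrease: Mapping[str, float],
    features: Mapping[str, Mapping[str, float]],
    gene_filter: Optional[Sequence[str]] = None,
    min_n: int = 3,
) -> list[ScreenResult]:
    """Rank features by signed R^2 against the decrease statistic.

    Missing values are handled by pairwise-complete deletion; n is reported
    per feature. Zero-variance features are logged and dropped from the
    ranking.
    """
    genes = list(decrease) if gene_filter is None else [
        g for g in gene_filter if g in decrease
    ]
    results = []
    for name, levels in features.items():
        xs, ys = [], []
        for g in genes:
            if g in levels and np.isfinite(levels[g]) and np.isfinite(decrease[g]):
                xs.append(levels[g])
                ys.append(decrease[g])
        n = len(xs)
        if n < min_n:
            logger.warning("feature %s has only %d complete genes; skipped", name, n)
            continue
        x = np.asarray(xs)
        y = np.asarray(ys)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("feature %s has zero variance; skipped", name)
            continue
        r = float(stats.pearsonr(x, y).statistic)
        r2 = r * r
        results.append(ScreenResult(name, r, r2, r2 if r > 0 else -r2, n))
    results.sort(key=lambda s: s.signed_r2, reverse=True)
    return results


def linear_regression(x: Sequence[float], y: Sequence[float]):
    """Ordinary least-squares fit; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    fit = stats.linregress(x, y)
    # linregress leaves r undefined only for constant y; treat as r = 0
    r = 0.0 if np.ptp(y) == 0 else float(fit.rvalue)
    return float(fit.slope), float(fit.intercept), r * r


def write_screen_tsv(path, results: Sequence[ScreenResult]) -> None:
    with open(path, "w") as fh:
        fh.write("#ranked by signed_r2, descending\n")
        fh.write("feature\tpearson_r\tr_squared\tsigned_r2\tn\n")
        for s in results:
            fh.write(
                f"{s.feature}\t{s.pearson_r:.10g}\t{s.r_squared:.10g}\t"
                f"{s.signed_r2:.10g}\t{s.n}\n"
            )
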