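"""Seeded synthetic epigenomes with planted ground truth.

The gene-panel generator plants the incoherent-feedforward structure the
analysis is built to detect: a subset of genes gains H3K9me2 in the H3K9
demethylase mutant; among those, protection (H3K36me3 gain, dependent on
the H3K36 methyltransferase) is drawn from a logistic function of the
baseline H3K36me3 latent, while the fractional H3K4me1 loss is drawn with
a configurable correlation to the realized baseline H3K36me3 level. Both
are downstream of H3K36me3 but not conditioned on each other, so the
screen's target correlation is controlled exactly while protected genes
still tend to high H3K36me3 and small loss.

The TE-methylome generator emulates the reciprocal-F1 establishment
experiment: wild type has high mCHG, F1s recover to an intermediate level,
and planted subsets shift down without the demethylase (LDL2) or up
without the methyltransferase (ASHH3). Per-cytosine counts are binomial.

The generators are test harnesses with documented free parameters, not a
biological claim; identical config + seed gives bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .core import (
    CytosineCall,
    GenomicInterval,
    SampleDescriptor,
    SignalTable,
    TranscriptionUnit,
    UnitSet,
)
from .io import CoverageTrack
from .methylome import UnitMethylation
from .quantify import LibraryStats, rpkm_table

# ----------------------------------------------------------------- gene panel

MARKS_DYNAMIC = ("H3K4me1", "H3K36me3", "H3K9me2")
MARKS_BASELINE = ("H2Bub", "H2A.Z", "H2A.W")

GENOTYPES_BY_MARK = {
    "H3K4me1": ("WT", "ibm1", "ldl2", "ibm1_ldl2", "ashh3", "ibm1_ashh3"),
    "H3K36me3": ("WT", "ibm1", "ldl2", "ibm1_ldl2", "ashh3", "ibm1_ashh3"),
    "H3K9me2": ("WT", "ibm1"),
    "H2Bub": ("WT",),
    "H2A.Z": ("WT",),
    "H2A.W": ("WT",),
}


@dataclass(frozen=True)
class GenePanelConfig:
    n_genes: int = 2000
    frac_h3k9_gain: float = 0.2
    protection_logistic: tuple[float, float] = (-1.0, 1.5)  # intercept, slope on z
    h3k4_loss_effect: float = 0.6       # mean fractional H3K4me1 loss when gained
    h3k4_loss_sd: float = 0.18
    h3k36_gain_effect: float = 8.0      # additive RPKM gain on protected genes
    h3k9_gain_effect: float = 10.0
    anti_silencer_r: float = -0.5       # target corr(baseline H3K36me3, decrease)
    ashh3_deepen: float = 0.25          # extra loss in the double mutant
    flag_bound_extra_frac: float = 0.1
    library_size: Optional[int] = 20_000_000  # None = infinite-library limit
    replicate_cv: float = 0.05
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.frac_h3k9_gain <= 1):
            raise ValueError("frac_h3k9_gain must lie in [0, 1]")
        if min(self.h3k4_loss_effect, self.h3k36_gain_effect,
               self.h3k9_gain_effect) < 0:
            raise ValueError("effect sizes must be >= 0")
        if not (-1 <= self.anti_silencer_r <= 1):
            raise ValueError("anti_silencer_r must be a correlation")
        if self.library_size is not None and self.library_size < 10_000:
            raise ValueError("library_size must be >= 1e4 (or None for noiseless)")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")

    @property
    def noiseless(self) -> bool:
        return self.replicate_cv == 0 and self.library_size is None


@dataclass
class GenePanel:
    config: GenePanelConfig
    units: UnitSet
    truth: pd.DataFrame          # indexed by gene id
    true_rpkm: dict[tuple[str, str], np.ndarray]  # (mark, genotype) -> values
    counts: dict[str, SignalTable]  # mark/assay -> count table ({} if noiseless)
    rpkm: dict[str, SignalTable]    # mark/assay -> RPKM table
    libs: dict[SampleDescriptor, LibraryStats] = field(default_factory=dict)


def _make_units(n: int, rng: np.random.Generator, chrom: str,
                biotype: str = "protein_coding", prefix: str = "g") -> UnitSet:
    lengths = rng.integers(1000, 5001, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    units = UnitSet()
    pos = 3000  # leave room for metaprofile flanks
    for i in range(n):
        end = pos + int(lengths[i])
        units.add(TranscriptionUnit(
            GenomicInterval(chrom, pos, end, str(strands[i])),
            f"{prefix}{i + 1:05d}", biotype,
        ))
        pos = end + 500
    return units


def generate_gene_panel(config: GenePanelConfig) -> GenePanel:
    """Generate the per-gene signal panel plus planted truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    units = _make_units(n, rng, chrom="chrS")
    ids = units.ids()
    lengths = np.array([units[i].length for i in ids], dtype=float)

    # latent baseline structure
    z36 = rng.standard_normal(n)
    x36 = np.exp(np.log(8.0) + 0.8 * z36)                       # H3K36me3 RPKM
    z4 = 0.5 * z36 + np.sqrt(0.75) * rng.standard_normal(n)
    x4 = np.exp(np.log(10.0) + 0.6 * z4)                        # H3K4me1 RPKM

    gains = np.zeros(n, dtype=bool)
    n_gain = int(round(config.frac_h3k9_gain * n))
    gains[rng.choice(n, size=n_gain, replace=False)] = True

    # fractional H3K4me1 loss, correlated with baseline H3K36me3 RPKM at the
    # configured target within the H3K9me2-gaining subset
    decrease = np.zeros(n)
    if n_gain >= 2:
        xg = x36[gains]
        xs = (xg - xg.mean()) / xg.std()
        r = config.anti_silencer_r
        # orthogonalize the noise against the feature so the planted latent
        # correlation is exact in-sample, not just in expectation
        eps = rng.standard_normal(n_gain)
        eps = eps - (eps @ xs) / (xs @ xs) * xs
        eps = (eps - eps.mean()) / eps.std()
        lat = r * xs + np.sqrt(max(0.0, 1 - r * r)) * eps
        decrease[gains] = np.clip(
            config.h3k4_loss_effect + config.h3k4_loss_sd * lat, -1.0, 0.98
        )

    a, b = config.protection_logistic
    p_protect = 1.0 / (1.0 + np.exp(-(a + b * z36)))
    protected = gains & (rng.random(n) < p_protect)
    silenced = gains & ~protected

    # baseline features correlated (in sign) with the planted loss
    d_full = rng.standard_normal(n)
    if n_gain >= 2:
        dg = decrease[gains]
        d_full[gains] = (dg - dg.mean()) / (dg.std() if dg.std() > 0 else 1.0)

    def feature(log_mean, sigma, rho):
        zf = rho * d_full + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
        return np.exp(log_mean + sigma * zf)

    x_h2bub = feature(np.log(6.0), 0.7, -0.45)   # anti-silencer-like
    x_h2az = feature(np.log(5.0), 0.7, +0.45)    # silencer-like
    x_h2aw = feature(np.log(3.0), 0.7, +0.35)    # silencer-like

    flag_bound = protected | (rng.random(n) < config.flag_bound_extra_frac)
    flag_enriched = protected.copy()

    # true RPKM per (mark, genotype)
    true_rpkm: dict[tuple[str, str], np.ndarray] = {}
    k9_base = np.full(n, 0.5)
    true_rpkm[("H3K9me2", "WT")] = k9_base
    true_rpkm[("H3K9me2", "ibm1")] = k9_base + config.h3k9_gain_effect * gains

    gain36 = config.h3k36_gain_effect * protected
    for g in GENOTYPES_BY_MARK["H3K36me3"]:
        if g in ("ibm1", "ibm1_ldl2"):
            true_rpkm[("H3K36me3", g)] = x36 + gain36
        else:  # WT, ldl2, ashh3, ibm1_ashh3: no (or suppressed) gain
            true_rpkm[("H3K36me3", g)] = x36

    deep = np.clip(decrease + config.ashh3_deepen * gains, -1.0, 0.98)
    for g in GENOTYPES_BY_MARK["H3K4me1"]:
        if g == "ibm1":
            true_rpkm[("H3K4me1", g)] = x4 * (1 - decrease)
        elif g == "ibm1_ashh3":
            true_rpkm[("H3K4me1", g)] = x4 * (1 - deep)
        else:  # WT, ldl2, ibm1_ldl2 (restored), ashh3
            true_rpkm[("H3K4me1", g)] = x4

    for mark, x in (("H2Bub", x_h2bub), ("H2A.Z", x_h2az), ("H2A.W", x_h2aw)):
        true_rpkm[(mark, "WT")] = x

    control = np.full(n, 1.0)
    flag_wt = control + 4.0 * flag_bound
    flag_ibm1 = flag_wt + 8.0 * flag_enriched
    true_rpkm[("FLAG_ASHH3", "control")] = control
    true_rpkm[("FLAG_ASHH3", "WT")] = flag_wt
    true_rpkm[("FLAG_ASHH3", "ibm1")] = flag_ibm1

    truth = pd.DataFrame(
        {
            "gains_h3k9": gains,
            "protected": protected,
            "silenced": silenced,
            "flag_enriched": flag_enriched,
            "flag_bound": flag_bound,
            "decrease_true": decrease,
        },
        index=pd.Index(ids, name="gene"),
    )

    # assemble sample tables
    def samples_for(assay, genotypes, lines=(None,)):
        return [
            SampleDescriptor(g, assay, rep, line)
            for g in genotypes
            for line in lines
            for rep in range(1, config.n_replicates + 1)
        ]

    assays: dict[str, list[SampleDescriptor]] = {}
    for mark, genotypes in GENOTYPES_BY_MARK.items():
        assays[mark] = samples_for(mark, genotypes)
    assays["FLAG_ASHH3"] = [
        SampleDescriptor(g, "FLAG_ASHH3", rep, line)
        for g in ("control", "WT", "ibm1")
        for line in ("TG1", "TG2")
        for rep in (1,)
    ]

    counts: dict[str, SignalTable] = {}
    rpkm_tables: dict[str, SignalTable] = {}
    libs: dict[SampleDescriptor, LibraryStats] = {}

    for assay, samples in assays.items():
        cols = []
        for s in samples:
            truth_col = true_rpkm[(assay, s.genotype)]
            if config.noiseless:
                cols.append(truth_col.astype(float))
            else:
                noise = (
                    np.ones(n)
                    if config.replicate_cv == 0
                    else rng.lognormal(
                        -0.5 * np.log1p(config.replicate_cv**2),
                        np.sqrt(np.log1p(config.replicate_cv**2)),
                        size=n,
                    )
                )
                mean_counts = (
                    truth_col * noise * lengths * config.library_size / 1e9
                )
                cols.append(rng.poisson(mean_counts).astype(float))
            libs[s] = LibraryStats(
                s, config.library_size if config.library_size else 10**9
            )
        values = np.column_stack(cols)
        if config.noiseless:
            rpkm_tables[assay] = SignalTable(ids, samples, values, "rpkm")
        else:
            counts[assay] = SignalTable(ids, samples, values, "count")
            rpkm_tables[assay] = rpkm_table(counts[assay], units, libs)

    return GenePanel(config, units, truth, true_rpkm, counts, rpkm_tables, libs)


# --------------------------------------------------------------- TE methylome

F1_GENOTYPES = (
    "cxs_LDL2", "cxs_ldl2", "sxc_LDL2", "sxc_ldl2",
    "cxs_ASHH3", "cxs_ashh3", "sxc_ASHH3", "sxc_ashh3",
)


@dataclass(frozen=True)
class TEMethylomeConfig:
    n_te: int = 400
    n_planted_ldl2: int = 20   # ~ the published fraction at desk scale
    n_planted_ashh3: int = 14
    wt_mchg_mean: float = 0.7
    f1_recovery_level: float = 0.4
    ldl2_effect: float = -0.15
    ashh3_effect: float = 0.15
    chh_scale: float = 0.3     # CHH level relative to CHG
    cytosines_per_te: int = 30
    coverage_per_cytosine: int = 20
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_ldl2 + self.n_planted_ashh3 > self.n_te:
            raise ValueError("planted counts exceed n_te")
        for lvl in (self.wt_mchg_mean, self.f1_recovery_level):
            if not (0 <= lvl <= 1):
                raise ValueError("methylation levels must lie in [0, 1]")
        if self.cytosines_per_te < 1 or self.coverage_per_cytosine < 0:
            raise ValueError("invalid cytosine/coverage configuration")


@dataclass
class TEMethylome:
    config: TEMethylomeConfig
    units: UnitSet
    truth: pd.DataFrame
    # genotype -> replicate -> context -> meth counts (n_te x n_cyt) ints
    meth_counts: dict[str, dict[int, dict[str, np.ndarray]]]
    coverage: int
    positions: dict[str, np.ndarray]  # context -> (n_te x n_cyt) 1-based pos
    strands: dict[str, np.ndarray]

    def samples(self) -> Iterator[tuple[str, int]]:
        for g in ("WT",) + F1_GENOTYPES:
            for rep in range(1, self.config.n_replicates + 1):
                yield g, rep

    def iter_calls(self, genotype: str, replicate: int) -> Iterator[CytosineCall]:
        """Materialize per-cytosine calls for one sample, in position order."""
        rows = []
        for context in ("CHG", "CHH"):
            pos = self.positions[context]
            strand = self.strands[context]
            meth = self.meth_counts[genotype][replicate][context]
            for i in range(pos.shape[0]):
                for j in range(pos.shape[1]):
                    rows.append(
                        (int(pos[i, j]), str(strand[i, j]), context,
                         int(meth[i, j]))
                    )
        rows.sort()
        for p, s, ctx, m in rows:
            yield CytosineCall("chrT", p, s, ctx, m, self.coverage - m)

    def meth_by_sample(self, context: str = "CHG"):
        """Per-unit weighted-methylation totals, computed directly from the
        generator's count arrays (equal to pooling the emitted per-cytosine
        report through weighted_methylation; tested for equality)."""
        ids = self.units.ids()
        n_cyt = self.positions[context].shape[1]
        out: dict[str, dict[int, dict[str, UnitMethylation]]] = {}
        for g, rep in self.samples():
            meth = self.meth_counts[g][rep][context]
            totals = meth.sum(axis=1)
            denom = n_cyt * self.coverage
            out.setdefault(g, {})[rep] = {
                uid: UnitMethylation(uid, context, int(totals[i]), int(denom))
                for i, uid in enumerate(ids)
            }
        return out


def generate_te_methylomes(config: TEMethylomeConfig) -> TEMethylome:
    """Generate per-cytosine methylomes for the reciprocal-F1 experiment."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_te

    units = _make_units(n, rng, chrom="chrT", biotype="te_gene", prefix="TE")
    ids = units.ids()
    starts = np.array([units[i].interval.start for i in ids])
    ends = np.array([units[i].interval.end for i in ids])

    order = rng.permutation(n)
    ldl2_set = np.zeros(n, dtype=bool)
    ashh3_set = np.zeros(n, dtype=bool)
    ldl2_set[order[: config.n_planted_ldl2]] = True
    ashh3_set[
        order[config.n_planted_ldl2: config.n_planted_ldl2 + config.n_planted_ashh3]
    ] = True

    wt_level = np.clip(rng.normal(config.wt_mchg_mean, 0.08, n), 0.05, 0.95)
    f1_level = np.clip(rng.normal(config.f1_recovery_level, 0.06, n), 0.02, 0.9)

    levels_chg: dict[str, np.ndarray] = {"WT": wt_level}
    n_clamped = 0
    for g in F1_GENOTYPES:
        lvl = f1_level.copy()
        if g in ("cxs_ldl2", "sxc_ldl2"):
            lvl = lvl + config.ldl2_effect * ldl2_set
        if g in ("cxs_ashh3", "sxc_ashh3"):
            lvl = lvl + config.ashh3_effect * ashh3_set
        clamped = np.clip(lvl, 0.001, 0.999)
        n_clamped += int(np.sum(clamped != lvl))
        levels_chg[g] = clamped
    if n_clamped > 0.1 * n * len(F1_GENOTYPES):
        import warnings

        warnings.warn("more than 10% of TE methylation levels were clamped")

    n_chg = config.cytosines_per_te
    n_chh = 2 * config.cytosines_per_te
    positions = {}
    strands = {}
    for context, n_cyt in (("CHG", n_chg), ("CHH", n_chh)):
        # evenly spaced 1-based positions inside each TE body
        frac = (np.arange(n_cyt) + 0.5) / n_cyt
        pos = (starts[:, None] + frac[None, :] * (ends - starts)[:, None]).astype(
            np.int64
        ) + 1
        if context == "CHH":
            pos = pos + 1  # offset so CHG and CHH never collide
        positions[context] = pos
        strands[context] = np.broadcast_to(
            np.where((np.arange(n_cyt) % 2) == 0, "+", "-"), (n, n_cyt)
        ).copy()

    meth_counts: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    cov = config.coverage_per_cytosine
    for g in ("WT",) + F1_GENOTYPES:
        meth_counts[g] = {}
        for rep in range(1, config.n_replicates + 1):
            per_context = {}
            for context, n_cyt in (("CHG", n_chg), ("CHH", n_chh)):
                lvl = levels_chg[g]
                if context == "CHH":
                    lvl = np.clip(lvl * config.chh_scale, 0.0, 1.0)
                per_context[context] = rng.binomial(
                    cov, np.repeat(lvl[:, None], n_cyt, axis=1)
                )
            meth_counts[g][rep] = per_context

    truth = pd.DataFrame(
        {
            "ldl2_regulated": ldl2_set,
            "ashh3_regulated": ashh3_set,
            "wt_mchg": wt_level,
            "f1_mchg": f1_level,
        },
        index=pd.Index(ids, name="te"),
    )
    return TEMethylome(
        config, units, truth, meth_counts, cov, positions, strands
    )


# -------------------------------------------------------------- track fixture


def generate_uniform_track(units: UnitSet, value: float, flank_bp: int = 2000
                           ) -> CoverageTrack:
    """Constant coverage over the annotated span of each chromosome plus
    flanks (clipped at 0)."""
    if value < 0:
        raise ValueError("coverage value must be >= 0")
    span: dict[str, list[int]] = {}
    for u in units:
        iv = u.interval
        lo, hi = span.setdefault(iv.chrom, [iv.start, iv.end])
        span[iv.chrom] = [min(lo, iv.start), max(hi, iv.end)]
    records = [
        (chrom, max(0, lo - flank_bp), hi + flank_bp, value)
        for chrom, (lo, hi) in span.items()
    ]
    return CoverageTrack.from_records(records, source="<uniform>")
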