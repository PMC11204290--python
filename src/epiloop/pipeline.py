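"""End-to-end demo wiring: simulate -> quantify -> screen -> classify -> report.

Every output is TSV with ``#`` metadata headers; the run is a pure function
of (workdir, seed, config), so identical invocations produce byte-identical
files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import classify, io, methylome, metaprofile, quantify, screen
from .simulate import (
    F1_GENOTYPES,
    GenePanelConfig,
    TEMethylomeConfig,
    generate_gene_panel,
    generate_te_methylomes,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    delta_change: float = 3.0
    delta_flag_enriched: float = 5.0
    delta_flag_bound: float = 2.0
    te_min_counts: int = 100
    te_threshold: float = 0.05
    n_genes: int = 600
    n_te: int = 150
    n_flank_bins: int = 20
    n_body_bins: int = 40
    flank_bp: int = 1000

    def validate(self) -> None:
        if min(self.delta_change, self.delta_flag_enriched,
               self.delta_flag_bound, self.te_threshold) <= 0:
            raise ValueError("thresholds must be positive")


def run_demo(workdir, seed: int, config: PipelineConfig = PipelineConfig()) -> Path:
    """Run every stage on a default synthetic panel; returns the report dir."""
    config.validate()
    out = Path(workdir)
    out.mkdir(parents=True, exist_ok=True)
    summary_lines = [f"#seed={seed}", f"#config={config}"]

    # ---- gene panel: simulate, quantify, screen, categorize, flag calls
    panel_cfg = GenePanelConfig(n_genes=config.n_genes, seed=seed)
    panel = generate_gene_panel(panel_cfg)
    io.write_annotation_bed6(out / "genes.bed", panel.units)
    for assay, table in panel.rpkm.items():
        io.write_table(out / f"rpkm_{assay.replace('.', '')}.tsv", table)

    k9_calls = classify.call_change_table(
        panel.rpkm["H3K9me2"], "WT", "ibm1", "H3K9me2", config.delta_change
    )
    k36_calls = classify.call_change_table(
        panel.rpkm["H3K36me3"], "WT", "ibm1", "H3K36me3", config.delta_change
    )
    k4_calls = classify.call_change_table(
        panel.rpkm["H3K4me1"], "WT", "ibm1", "H3K4me1", config.delta_change
    )
    categories = classify.categorize_genes(k9_calls, k36_calls, k4_calls)
    with open(out / "categories.tsv", "w") as fh:
        fh.write(f"#delta={config.delta_change}\n")
        fh.write("gene\th3k9\th3k36\th3k4\tlabel\n")
        for c in categories:
            fh.write(f"{c.gene}\t{c.h3k9}\t{c.h3k36}\t{c.h3k4}\t{c.label}\n")

    up_genes = [g for g, c in k9_calls.items() if c.direction == "up"]
    truth_up = set(panel.truth.index[panel.truth["gains_h3k9"]])
    summary_lines.append(
        f"h3k9_up_called\t{len(up_genes)}\tplanted\t{int(len(truth_up))}"
    )
    label_counts: dict[str, int] = {}
    for c in categories:
        label_counts[c.label] = label_counts.get(c.label, 0) + 1
    for label in sorted(label_counts):
        summary_lines.append(f"category\t{label}\t{label_counts[label]}")

    # screen: decrease statistic vs baseline WT features over the called genes
    avg = {a: quantify.average_replicates(t) for a, t in panel.rpkm.items()}
    wt_k4 = avg["H3K4me1"].series("WT.H3K4me1.r1")
    mut_k4 = avg["H3K4me1"].series("ibm1.H3K4me1.r1")
    dec = screen.h3k4me1_decrease(wt_k4, mut_k4)
    features = {
        "H3K36me3": avg["H3K36me3"].series("WT.H3K36me3.r1"),
        "H2Bub": avg["H2Bub"].series("WT.H2Bub.r1"),
        "H2A.Z": avg["H2A.Z"].series("WT.H2A.Z.r1"),
        "H2A.W": avg["H2A.W"].series("WT.H2A.W.r1"),
    }
    results = screen.screen_features(dec.decrease, features, gene_filter=up_genes)
    screen.write_screen_tsv(out / "screen.tsv", results)
    for s in results:
        summary_lines.append(
            f"screen\t{s.feature}\t{s.signed_r2:.6g}\t{s.n}"
        )

    # FLAG-tag calls
    flag = panel.rpkm["FLAG_ASHH3"]
    def by_line(genotype):
        cols = {}
        for s in flag.samples:
            if s.genotype == genotype:
                cols[s.line] = flag.column(s)
        return cols

    wt_cols, mut_cols, ctl_cols = by_line("WT"), by_line("ibm1"), by_line("control")
    enriched, bound = [], []
    for i, gene in enumerate(flag.units):
        mut_g = {l: v[i] for l, v in mut_cols.items()}
        wt_g = {l: v[i] for l, v in wt_cols.items()}
        ctl_g = {l: v[i] for l, v in ctl_cols.items()}
        if classify.call_flag_enriched(mut_g, wt_g, config.delta_flag_enriched):
            enriched.append(gene)
        if classify.call_flag_bound(wt_g, ctl_g, config.delta_flag_bound):
            bound.append(gene)
    summary_lines.append(f"flag_enriched\t{len(enriched)}")
    summary_lines.append(f"flag_bound\t{len(bound)}")

    up36 = {c.gene for c in categories if c.label == "H3K9me2 up H3K36me3 up"}
    overlap = len(up36 & set(enriched))
    p = classify.hypergeom_enrichment(
        overlap, len(up36), len(enriched), len(flag.units)
    )
    summary_lines.append(
        f"flag_enrichment_in_H3K36me3_up\toverlap={overlap}\tp={p:.6g}"
    )

    # ---- TE methylome: simulate, write + re-read reports, classify
    te_cfg = TEMethylomeConfig(
        n_te=config.n_te,
        n_planted_ldl2=min(20, max(1, config.n_te // 8)),
        n_planted_ashh3=min(14, max(1, config.n_te // 10)),
        seed=seed + 1,
    )
    tem = generate_te_methylomes(te_cfg)
    io.write_annotation_bed6(out / "te_genes.bed", tem.units)
    reports = out / "cx_reports"
    reports.mkdir(exist_ok=True)
    meth: dict[str, dict[int, dict]] = {}
    for g, rep in tem.samples():
        path = reports / f"{g}_rep{rep}.cx.tsv"
        io.write_cytosine_report(path, tem.iter_calls(g, rep))
        calls = list(io.read_cytosine_report(path))
        meth.setdefault(g, {})[rep] = methylome.unit_methylation_table(
            calls, tem.units, "CHG"
        )
    ids = tem.units.ids()
    ldl2_calls = methylome.classify_ldl2_regulated(
        meth, ids, config.te_min_counts, -config.te_threshold
    )
    ashh3_calls = methylome.classify_ashh3_regulated(
        meth, ids, config.te_min_counts, config.te_threshold
    )
    methylome.write_te_classification_tsv(out / "te_calls_ldl2.tsv", ldl2_calls)
    methylome.write_te_classification_tsv(out / "te_calls_ashh3.tsv", ashh3_calls)

    for mode, calls, col in (
        ("ldl2", ldl2_calls, "ldl2_regulated"),
        ("ashh3", ashh3_calls, "ashh3_regulated"),
    ):
        called = {u for u, c in calls.items() if c.label != "none"}
        planted = set(tem.truth.index[tem.truth[col]])
        tp = len(called & planted)
        fp = len(called - planted)
        fn = len(planted - called)
        tn = len(ids) - tp - fp - fn
        summary_lines.append(
            f"te_{mode}\ttp={tp}\tfp={fp}\tfn={fn}\ttn={tn}"
        )

    # ---- metaprofile of mCHG over planted LDL2-regulated TEs
    planted_ldl2 = list(tem.truth.index[tem.truth["ldl2_regulated"]])
    if planted_ldl2:
        calls_wt = list(io.read_cytosine_report(reports / "WT_rep1.cx.tsv"))
        prof = metaprofile.methylation_metaprofile(
            calls_wt, tem.units.subset(planted_ldl2), "CHG",
            flank_bp=config.flank_bp, n_body_bins=config.n_body_bins,
            n_flank_bins=config.n_flank_bins,
        )
        metaprofile.write_metaprofile_tsv(out / "metaprofile_mCHG_WT.tsv", prof)

    with open(out / "summary.tsv", "w") as fh:
        fh.write("\n".join(summary_lines) + "\n")
    logger.info("demo complete: %s", out)
    return out
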