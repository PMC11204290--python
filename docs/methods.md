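# Methods

## The analysis model

The package operates on per-transcription-unit signal. All coordinates are
0-based half-open internally; GFF3 and per-cytosine reports (1-based) are
converted at the format boundary only. A unit is a protein-coding gene or
a TE gene; TE-gene identity is annotation metadata, taken as a fixed input
universe rather than inferred from sequence.

**Counting and normalization.** A read counts toward every unit it
overlaps by at least one base (BEDTools-coverage semantics); there is no
fractional assignment. RPKM divides by the *total mapped-read* library
size supplied with the sample (reads outside units included); when no
library size is given the number of input read intervals is the fallback.
Replicate averaging happens after RPKM conversion, and missing values
propagate (zero signal and unmeasured are distinct states throughout).
ChIP counting is unstranded; mRNA counting of TE genes is per-strand, and
the transcribed strand is the one with the larger count total over all
samples (ties go to sense). TPM renormalizes length-corrected rates to
10⁶; expression contrasts use log₂(TPM + 0.05).

**Change calls.** A mark changes on a gene only if every replicate-matched
difference (rep1 vs rep1, rep2 vs rep2) exceeds the threshold strictly
(default ΔRPKM > 3). This is deliberately conservative and monotone:
raising the threshold can only move calls toward "stay". The
tagged-protein calls apply the same every-line logic with thresholds 5
(mutant vs wild type) and 2 (wild type vs nontransgenic control), both
strict. Categories are composite labels over the H3K9me2 / H3K36me3 /
H3K4me1 calls; genes that do not gain H3K9me2 are "background".

**Screen.** The silencing statistic is the fractional H3K4me1 decrease
(WT − mutant)/WT, computed over genes that gain H3K9me2; genes with zero
wild-type signal are excluded (the ratio is undefined, and such genes are
outside the expressed, marked universe the screen addresses) rather than
clamped. Each feature is the replicate-averaged wild-type level; Pearson r
is computed with pairwise-complete deletion and reported per feature with
its n. Ranking is by signed R² — R² with the sign of r — with no p-values;
zero-variance features are logged and dropped. The screen is invariant to
positive affine transforms of a feature and to consistent gene
permutations.

**Methylome classifiers.** Weighted methylation is Σ methylated calls /
Σ all calls per unit and context, both strands pooled, with no
sub-context split. A TE gene is LDL2-regulated when all four
replicate-matched mCHG differences (mutant − wild-type F1, in both
reciprocal crosses × both replicates) are strictly below −0.05 and every
sample has strictly more than 100 CHG read calls in the unit;
ASHH3-regulated mirrors this above +0.05. "Counts" in the coverage filter
means read-level calls, not distinct cytosine positions. Both classifiers
are monotone in the coverage filter and the threshold magnitude. mCHH is
computed alongside but does not drive labels.

**Metaprofiles.** Each unit contributes fixed-width flank bins (default
2 kb in 40 bins) and a body rescaled into 100 bins. A bin's value is the
exact integral of piecewise-constant coverage over its (possibly
fractional) span divided by the span — so short units are handled without
special cases and the body area identity (Σ bin·width = per-base sum)
holds to rounding error. Minus-strand rows are reversed so profiles read
5′→3′. Bins reaching below coordinate 0 are NaN and excluded from the
mean; right-hand chromosome ends are unknown to a bedGraph-backed track
and read as zero coverage. Methylation metaprofiles bin Σ meth / Σ total
within each bin instead of coverage; bins with no covered cytosine are
NaN.

**Statistics.** The hypergeometric enrichment is the one-sided
over-representation tail P(X ≥ k). The paired *t* test is the one-sample
t on differences with df = n − 1; all-zero differences give (0, 1) and
constant nonzero differences a signed infinite t with p = 0. Spearman ρ
is the Pearson correlation of average ranks; p uses the large-sample t
approximation, switching to exact permutation below 10 pairs; all-tied
input is flagged undefined (NaN) rather than guessed. These routines are
thin, validated wrappers over scipy.stats; the tests check them against
exact rational enumeration (hypergeometric), extended-precision normal
equations (regression), and hand-written rank/t formulas.

## The synthetic generators

The generators are test harnesses with documented free parameters, not a
biological claim: they produce data with the statistical structure the
analysis assumes, plus the truth labels needed to measure recovery.

**Gene panel.** Baseline RPKM for H3K36me3 and H3K4me1 are log-normal
(medians 8 and 10 RPKM, log-sd 0.8 and 0.6, mildly correlated), typical
of gene-body marks. A fraction (default 0.2) of genes gains H3K9me2
(+10 RPKM) in the demethylase-mutant genotypes. Two consequences are
planted downstream of baseline H3K36me3, but not conditioned on each
other:

- *Protection* is Bernoulli(logistic(−1 + 1.5·z)), where z is the
  H3K36me3 log-latent: protected genes gain H3K36me3 (+8 RPKM, suppressed
  in the methyltransferase mutant).
- The *fractional H3K4me1 loss* is drawn with an exact in-sample
  correlation (default −0.5) to the realized baseline H3K36me3 RPKM
  (mean loss 0.6, sd 0.18, clipped to [−1, 0.98]); the noise component is
  orthogonalized against the feature so the planted correlation is exact
  by construction, and only measurement noise and clipping attenuate what
  the screen recovers (≈ −0.49 at the defaults). The loss is reversed in
  the silencer-mutant double and deepened (+0.25) in the
  methyltransferase-mutant double.

Because protection and loss share the H3K36me3 latent, protected genes
still tend to high H3K36me3 and small loss — the qualitative loop
structure — while the screen's target stays controllable. Three further
baseline features are planted with fixed-sign latent correlations to the
loss: H2Bub-like (−0.45, anti-silencer-like) and H2A.Z/H2A.W-like
(+0.45/+0.35, silencer-correlated). Tagged-protein truth: bound =
protected plus a 10% constitutive background; enriched = protected.

Counts are Poisson with mean RPKM·length·library/10⁹ per replicate, with
log-normal replicate noise (CV 0.05) and a 2×10⁷-read library — count
depths of a few hundred per gene, as in a typical ChIP-seq experiment.
Setting `replicate_cv=0, library_size=None` is the documented noise-off
switch: tables then equal the configured truth exactly, which is what the
exactness tests use. Gene lengths are uniform on 1–5 kb on one synthetic
chromosome with 500 bp gaps, so overlap handling is exercised separately
in the counting tests rather than confounded here.

**TE methylome.** Default 400 TE genes with 20 planted LDL2-regulated
(matching the published ~5% fraction at desk scale) and 14 planted
ASHH3-regulated. True mCHG: wild type ≈ 0.70 ± 0.08; all F1 genotypes
share a per-TE recovery level ≈ 0.40 ± 0.06; planted sets shift by −0.15
(ldl2 F1s) or +0.15 (ashh3 F1s). Each TE carries 30 CHG and 60 CHH
cytosines at fixed 20× coverage (≈ 600 CHG calls per TE — comfortably
past the >100 filter; binomial noise on a level difference is then
σ ≈ 0.028, so a 0.15 effect clears the 0.05 threshold at ≈ 3.5σ per
comparison and the planted set is recovered exactly in ≥ 95% of seeds,
while four independent false exceedances are vanishingly rare). mCHH runs
at 0.3× the CHG level and does not drive labels. Since the four F1
genotypes share each TE's true level exactly (bar planted effects), null
differences have mean zero by construction.

Determinism is full-config: one `numpy` Generator per call, consumed in a
fixed documented order; identical config + seed gives bit-identical
output, but partial config changes may reshuffle downstream draws.

**What passing does and does not show.** The generators emulate
per-unit signal magnitudes, replicate noise, and binomial methylation
sampling. They do not emulate mappability artifacts, copy-number and
duplication structure, fragment-length effects, sequence-composition
bias in methylation calls, overlapping/nested transcription units, or
organellar contamination of library size. Recovery on synthetic panels
therefore validates the statistical machinery and its thresholds, not
robustness to those real-data pathologies.

## Numerical and design choices

- Strict inequalities everywhere a threshold is crossed ("more than"),
  so boundary values never change a call.
- Tie-break in TE strand selection: sense.
- Missing replicate values force a flagged "stay" call; missing values in
  averages propagate, keeping downstream filters honest.
- Demo problem sizes (600 genes, 150 TE genes) and the acceptance
  script's (2000 genes × 20 seeds, 400 TE genes × 20 seeds) were chosen
  to estimate every reported rate with comfortable margins at desk scale;
  the screen's sampling sd at n = 400 in-screen genes is ≈ 0.04, small
  against the ±0.1 recovery band.
- The demo scales the planted TE counts down proportionally when
  configured below the default TE panel size.

## Known limitations

- The coverage reader requires non-overlapping bedGraph records and holds
  tracks in memory; bigWig input is not supported (text formats only).
- `screen_features` fits one feature at a time by design; no joint or
  regularized model is attempted.
- The per-cytosine report parser accepts the CX column order only.
- Chromosome lengths are unknown to the profiler, so only the left
  chromosome edge can be masked; a unit running off the right end of its
  real chromosome would read zero coverage there.
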