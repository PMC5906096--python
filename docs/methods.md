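# Methods

This note documents the statistical models, the defaults and why they were
chosen, the numerical choices, and what the synthetic data do and do not
demonstrate.

## Count model and differential expression

Counts are modelled as negative binomial with variance `mu + alpha*mu^2`.
Per-sample sequencing depth is corrected by median-of-ratios size factors
(median over features of the count divided by the feature's geometric mean
across samples, rescaled so the factors' geometric mean is 1). If no feature
is observed in every sample the factors are undefined and the fit refuses to
proceed rather than silently switching reference.

The per-feature model is log-linear: intercept, batch indicator(s), and a
condition indicator, fitted by IRLS with log size factors as offsets,
vectorised across features (batched normal-equation solves). Features whose
raw mean across the compared samples is at or below `min_mean` (default 40
reads) are excluded before normalization and testing.

**Dispersion.** Per-feature dispersion uses a method-of-moments estimator on
the fitted model's residuals: `alpha` solves
`sum_j (k_j - mu_j)^2 / (mu_j + alpha*mu_j^2) = n - p` (bisection on a log
grid, clipped to [1e-8, 10]). Unlike within-group variance estimators, this
retains all `n - p` residual degrees of freedom, which matters in the small
batched layouts this pipeline targets (3-4 animals per group across 2
batches). A parametric trend `alpha(mu) = a0 + a1/mu` is fitted across
features by least squares, and each feature's log-dispersion is shrunk toward
the trend with fixed weight 0.5. The full empirical-Bayes machinery of
dedicated DE tools is intentionally not reproduced.

**Testing.** The Wald statistic `lfc / se` is referred to a t distribution
with `n - p + 4` degrees of freedom: the residual df plus a fixed prior-df
credit of 4 for the shared dispersion trend. A plain normal reference is
noticeably anticonservative at n = 5 per group (empirical type-I ~0.075 at
nominal 0.05), while the residual df alone over-corrects (~0.038); the
credited reference is calibrated (0.04-0.06 across simulation seeds), and the
package's null-calibration test verifies this on every run. P-values are
BH-adjusted across tested features.

**LFC shrinkage.** Shrunken log2 fold changes are the posterior mean under a
zero-centered normal prior. The prior scale is fitted by matching the upper
tail of the raw LFC distribution — `sigma^2 = (q95(|lfc|)/1.96)^2 - mean(se^2)`,
floored at 1e-6 — because a plain variance-matching fit is collapsed by the
null majority. Like any zero-centered normal prior, this visibly shrinks
large effects (a true log2FC of 2 may report ~1.5 shrunken at n = 3-4 per
group); threshold classification therefore exposes both scales, and the
default follows the figure-legend convention of filtering on the shrunken
value. Shrunken magnitudes never exceed raw magnitudes.

**Classification.** DEGs: shrunken fold >= threshold (2.0, or 1.2 for the
">20%" convention, 1.25 for ">25%") and FDR < 0.05, direction-specific.
Rescue taxonomy for genes significantly down in the mutant at baseline:
`unchanged` if the stimulation contrast has FDR >= 0.05; `partial` if
significant but below a 20% increase; `rescued` if significant and above it.
`strict_baseline` additionally requires the stimulated mutant group mean to
reach the WT sham mean; the baseline-reached flag is reported either way and
the flag defaults to off (the legend definition governs).

**Clustering.** Average-linkage hierarchical clustering on correlation
distance of log2(normalized counts + 1), with deterministic tie handling; a
constant matrix returns a flat ordering with a warning instead of failing.

## Isoforms

Route A is the NB Wald test run on isoform counts with gene-level size
factors (isoform counts are compositional within a gene; per-isoform factors
would absorb real switches). Route B re-uses route A's point estimate and
inflates its variance with the quantifier's per-isoform technical variance
(`se_B^2 = se_A^2 + tech_var*(1/nA + 1/nB)`), referred to the same
moderated-t — so with zero technical variance the two routes coincide
exactly, which is the contract the dual-route consensus is tested against. A
consensus DEI must be significant by both routes at the fold threshold with
concordant sign. A switch is a consensus DEI (>=30% change) whose gene shows
no overall change (gene FDR >= 0.05 or gene fold < 1.2); isoforms of untested
genes are flagged and never called switches.

## Methylome

Methylation level is methylated/total reads per cytosine; positions under 10
reads are dropped, records with methylated > total rejected and counted. mCH
is the union of CHG and CHH.

DMR calling normalizes each sample's counts to the across-sample median
coverage (multiplicative, rounded half-up, ratio preserved), pools replicates
by summation, and tests each unit — a single cytosine, or a fixed tile
(default 1000 bp) whose level is the average of constituent base levels —
with a two-sided Fisher exact test on pooled methylated/unmethylated counts.
DMRs require BH q < 0.05 and an absolute level difference of at least 50
percentage points. The "q < 0.05" reading of an ambiguous printed cutoff is a
deliberate interpretation, exposed as a parameter.

Annotation uses a strict precedence partition (promoter > exon > intron >
intergenic) over one coordinate system, with promoters defined as 2000 bp
upstream of the TSS (strand-aware, configurable); a region is labelled by its
midpoint. Enrichment compares the fraction of DMRs per feature with the
feature's genome fraction (fold), and the empirical p redraws the same number
of regions with the observed length multiset uniformly over the genome
(overlaps permitted — the simplest null), 1000 trials by default, add-one
rule `p = (r+1)/(n+1)`, both one-sided p's reported. With heavy ties (few
DMRs, coarse proportion lattice) the empirical p is slightly conservative;
uniformity holds well at a few hundred regions.

Metagene profiles are scale-regions matrices: fixed-width flank bins, gene
body rescaled to a fixed bin count, minus-strand genes reversed, bin value =
mean level of covered cytosines, empty bins excluded from set means.

## Deconvolution (PSEA-style)

Reference signals are per-sample means of the marker genes' normalized
expression, rescaled to mean 1 (so `coef.2` reads as the mean expression
attributable to the population). Marker defaults are the four dentate-gyrus
sets (granule: C1ql2, Dsp, Trpc6, Pitpnm2, Btg1; mossy: Calb2, Fgf1; NSC:
Nes, Sox2, Fabp7; NPC: Dcx, Dpysl3), supplied via configuration. One OLS
model per gene and cell type — `expr = coef.1 + coef.2*signal +
coef.3*(signal x condition)` — where the interaction form (rather than a bare
condition term) makes `coef.3` the population-specific condition difference;
a constant condition makes the design collinear and is rejected. Selection:
model F p < 0.01, adjusted R^2 > 0.8, and the large-intercept exclusion
operationalized as `|coef.1| <= 0.5 * |coef.2| * mean(signal)` (scale-free;
the ratio is configurable because no threshold is printed anywhere).

## Gene sets and network

Overlap tests are one-sided (enrichment) Fisher exact tests on the 2x2
membership table over an explicit universe; inputs are clipped to the
universe; the reported percentage is of the comparison list. The default
universe is the expressed-gene background (raw mean > 40) from the DE stage;
the alternative (protein-coding GO background) is a caller choice. Symbol
harmonization is a local, case-insensitive alias table with keep/drop/strict
policies — no live database queries.

Network extraction: layer 1 = direct targets of the seed TFs; layer 2 =
targets of layer-1 nodes that are themselves TFs (the TF-gated reading of a
two-step cascade). Retained nodes need a DEG or DEI call, except mediating
layer-1 TFs, which are kept (flagged `TF-path`) so layer-2 nodes stay
connected. Node attributes: layer, overlay category, log2FC, out-degree
within the subgraph. Self-loops are dropped with a warning; cycles are fine.

## Assays

qPCR: replicate wells averaged per sample and gene; dCt against the geometric
mean of three reference genes (Gapdh, Actb, Atf2 by default); relative
quantity `2^-dCt` scaled to control-group mean 1; Welch two-tailed t-test by
default (pooled-variance mode available). The geometric mean of Ct values is
only approximately shift-equivariant; sample-wide Ct offsets cancel to ~1e-4
relative.

TMT: PSMs with summed signal-to-noise < 200 across the 10 channels or
precursor isolation specificity < 0.5 are excluded; protein channel
intensities are sums of passing PSMs; columns are normalized to equal totals
(residual loading correction after nominally 1:1 mixing); per-protein Welch
two-tailed t-test; proteins with a group-mean ratio >= 1.5 either way are
flagged (the ratio reading of "50% difference"; the alternative
|difference|/mean reading is not used).

## Synthetic data: what it emulates, and what it does not

The generators are first-class, seeded, and deterministic (one
`numpy.random.Generator` per invocation; identical seeds give byte-identical
serialized outputs). Defaults mirror the study design: 3 sham + 4 DBS animals
per genotype in two batches; gene baselines log-normal around mean 200 with
dispersion 0.05 and ~10% log-normal batch effects; WGBS with 2 animals per
arm on a single 2-Mb synthetic chromosome (80 genes, contexts read off a
generated reference sequence, ~4% of cytosines retained to emulate coverage
dropout, Poisson coverage mean 30); isoforms per gene 1-4 with Dirichlet(5)
proportions and ~500 counts per gene; 10-plex PSM tables with 4 PSMs per
protein and 20% failing the quality gates; Ct tables with 0.1-cycle noise.

Planted effects are chosen to be *detectable at the study's sample sizes*,
not to mimic real effect-size distributions (which the source data do not
constrain): stimulation-induced genes at log2FC 2.5 (immediate-early-gene
scale), mutant-low genes at a 4-fold loss planted in the upper expression
tier (baseline >= 1.5x the configured mean — synaptic genes of interest are
robustly expressed, and a 4-fold loss must stay above the mean-40 filter to
be classifiable at n = 3 sham animals per genotype), 120 mutant-low genes
with 25% rescued and 25% partial, isoform switches that boost the minor
isoform 2.5-fold in genes where that fold fits below a 0.9 proportion,
planted DMRs of 1000 bp with ±0.8 shifts from 0.1/0.9 baselines, a 1.6-fold
planted protein effect, and a 4-fold qPCR induction. Conservation laws hold
exactly: isoform counts are multinomial partitions of the gene total, and
methylated counts never exceed coverage.

Consequently, passing tests show that the estimators recover what was
planted under their own model family, that the testing machinery is
calibrated under the generator's null, and that each stage's contracts and
closed-form identities hold. They do not show robustness to features real
data have and the generator lacks: outlier samples, gene-correlated
dispersion structure, GC/length biases, bisulfite conversion errors,
isoform-mapping ambiguity, co-isolation interference beyond the specificity
field, or effect sizes at the detection boundary.

## Problem sizes and numerics

Test-suite and acceptance-script problem sizes (2000 genes for null
calibration, 200 x 999-trial permutation runs, 20 planted DMRs over 2 Mb, 100
random graphs) were chosen so the whole suite completes in about a minute on
one core while keeping Monte-Carlo error well inside the asserted margins.
IRLS runs at most 30 iterations with eta clipped to ±30 and a 1e-10 ridge so
all-zero features stay solvable; flat features (identical counts, unit
factors) short-circuit to the exact degenerate answer (LFC 0, p 1).
Coordinates are 0-based half-open internally; cytosine reports are written
1-based, bedGraph 0-based, matching the standard dialects. Fisher tests use
scipy's exact implementation and are checked against brute-force
hypergeometric enumeration in the test suite. Dispersion bisection uses 40
halvings on [1e-8, 10], accurate to ~7 significant digits.

## Known limitations

- The DE engine approximates, but does not replicate, any published tool's
  numerics (no outlier replacement, no independent filtering, simplified
  shrinkage); agreement with an established NB implementation is checked in
  the suite at loose tolerance on a small dataset.
- Route B of the isoform test shares route A's point estimate; it models a
  technical-variance-aware method's *decision*, not its estimator.
- Permutation enrichment p-values are conservative for very small DMR sets.
- The rescue taxonomy's "partial" class is underpowered at realistic planted
  effect sizes (a 12% increase at n = 3-4 is rarely significant); the class
  is exercised by construction in unit tests rather than by recovery.
- Event-level splicing classification, read-level simulation, GO enrichment,
  and reference-free deconvolution are out of scope.
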