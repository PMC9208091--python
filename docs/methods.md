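# Methods

## Design and data model

The pipeline targets a reciprocal-cross trio design: maternal inbred P1,
paternal inbred P2, and the reciprocal F1 hybrids F1a (P1×P2) and F1b
(P2×P1), each with replicated bulk RNA-seq libraries (three replicates is
the canonical layout; two is the minimum for dispersion estimation). Inputs
are a gene × sample matrix of raw, non-negative integer counts, a YAML
design mapping samples to genotypes/replicates, and — for the allele-level
stages — a TSV of per-SNP read counts supporting the P1 vs P2 allele within
hybrid samples, with gene assignments. Alignment, quantification and SNP
discovery are upstream of this package; allele counts arrive pre-tabulated.
SNP positions are 1-based; missing counts are errors, never imputed.

## Normalization

Size factors are the median-of-ratios estimator: for sample j, the median
over genes (restricted to genes with a positive count in every sample) of
count/geometric-mean. This corrects depth and moderate composition
differences under the assumption that most genes are not changing; a
dataset in which nearly every gene shifts in one direction will have part
of that shift absorbed into the factors. Factors are defined only up to the
geometric-mean reference, so the meaningful invariant is on between-sample
factor ratios. Normalized counts are counts divided by the sample's factor.

## Dispersion and differential expression

Counts are treated as NB(m, α) with variance m + αm². Per gene, α is
estimated by method of moments within each genotype having ≥ 2 replicates,
(s² − m̄)/m̄², averaged across genotypes, clipped at zero and floored at
1e-8. No empirical-Bayes shrinkage is applied — the estimator is simple and
auditable, at a cost in power that the pipeline's intended effect sizes
(≥ 2-fold) absorb.

The test statistic for a contrast (numerator, denominator) is
log₂(m_num/m_den) divided by the delta-method standard error
SE² = (1/ln2)² Σ_groups (1/m_i + α̂)/n_i, computed on normalized group
means. When a group mean is exactly zero a pseudo-mean floor of 0.5
normalized counts is applied inside the logarithm (typical genes are
untouched); genes at zero in both groups get log2fc 0 and p = 1. P-values
are two-sided against a **t reference with n₁+n₂−2 degrees of freedom**
rather than the normal: with three replicates the moment dispersion has two
residual degrees of freedom per group, and genes whose estimate truncates
near zero receive near-Poisson standard errors, which makes the
normal-reference Wald visibly anticonservative (≈11% empirical type-I at
nominal 5% in a 5,000-gene null simulation); the t₄ reference restores
≈4–4.5% across seeds. Benjamini–Hochberg adjustment (statsmodels) is
applied within each contrast separately. A gene is a DEG iff |log₂FC| > 1
and FDR < 0.05, both strict. This stage is deliberately **not** a DESeq2
replica: no shrinkage, no Cook's filtering, no independent filtering — the
downstream logic needs only fold-change and FDR flags, and an auditable
test is preferred to a black-box reimplementation.

## Inheritance classification

Each gene is classified from (log₂(hyb/P1), log₂(hyb/P2)) computed on
normalized genotype means (same 0.5 zero-mean floor as the DE stage) with
strict unit-threshold inequalities into eight divergent classes — additive
(two orientations), P1/P2 expression-level dominance (up/down), and
transgressive (up/down) — or conserved (both ratios inside the open unit
band). Points with a coordinate exactly at ±1 satisfy no strict rule and
are labelled UNCLASSIFIED_BOUNDARY; with continuous data this set has
measure zero. The summarised set is restricted to genes flagged DEG between
the hybrid and **at least one** parent (the union of the two hybrid-parent
DEG sets); class percentages use only the eight divergent classes in the
denominator and are rounded half-up to two decimals. The direction split of
reciprocal-hybrid DEGs (F1a vs F1b) is reported with one-decimal
percentages, undefined (null) when there are no DEGs.

## ASE calling

Hybrid replicates are pooled by summation per SNP before testing — the
design reports one ASE gene set per cross, and pooling maximises depth at
the cost of masking replicate heterogeneity (a per-replicate mode is out of
scope). Three filters: (1) a SNP needs ≥ 5 pooled supporting reads;
(2) gene-level allelic deviation is the two-sided exact binomial on the
summed counts vs 0.5, BH-adjusted across genes, significant at FDR < 0.05;
(3) SNPs within a gene that are individually significant (unadjusted
p < 0.05 — a consistency filter, not an inference) must not point in
opposite directions. The volcano export uses a +0.5 Haldane correction on
both alleles when either pooled count is zero.

## Cis/trans classification

The parental proportion is mean_P1/(mean_P1+mean_P2) on normalized counts
(inbreds are homozygous, so whole-gene expression stands in for allele
expression; both-zero genes return 0.5 with a degenerate flag). A gene is:

- **CIS** if it is ASE and its hybrid allelic ratio is statistically
  indistinguishable from the parental proportion;
- **TRANS** if it is not ASE but its parents are differentially expressed
  (balanced alleles despite divergent parents imply a diffusible factor);
- **CONSERVED** if neither; **AMBIGUOUS** if ASE but deviating from the
  parental proportion (unresolved cis+trans mixtures).

"Indistinguishable" means failing to reject at α = 0.05 (configurable) a
test of hybrid allelic ratio = parental ratio. Both sides of that
comparison are estimates, so the test is a Wald z on the log-odds
difference with variance 1/(g1+0.5) + 1/(g2+0.5) (Haldane-corrected allele
counts) **plus** the delta-method variance of the parental log-odds,
Σ_parents (1/m_i + α̂)/n_i. Treating the parental proportion as a known
constant (an exact binomial against it) rejects true cis genes far above
the nominal rate once gene depth is a few hundred reads — at depth ≈300
with three replicates and α = 0.05 about a quarter of true-cis genes were
mislabelled AMBIGUOUS — so the variance-propagating form is the default;
the exact-binomial form remains available when no parental variance is
supplied.

## Synthetic-data generator

The generator emulates the study conditions: four genotypes × 3 replicates;
per-gene base means log-normal (ln-scale mean 5.0, sd 1.5, i.e. median
≈150 counts); NB dispersion 0.05; per-sample library-size multipliers
log-uniform in [0.7, 1.4] so size-factor estimation is non-trivial. Each
gene draws a true class — by default 50% conserved and the other half split
across the eight divergent classes in proportion to the tallies observed in
the motivating maize study — and its noise-free genotype means place the
log₂ hybrid/parent ratios at 0 or ±`log2_effect` (default 2.0, a 1.0-log₂
margin beyond the unit thresholds, so finite-sample noise rarely flips
classes). Reciprocal hybrids share gene-level means unless a
`reciprocal_fraction` perturbs a subset. Regulatory truth follows the class
geometry: genes with equal parental means are conserved-regulation (allele
proportion 0.5); genes with unequal parents are cis (allele proportion =
parental proportion) or trans (0.5) with probability `cis_fraction`
(default 0.5). Allele counts are binomial splits of Poisson per-SNP depths
(default 2 SNPs/gene, mean depth 50 per SNP per hybrid replicate, so
default pooled gene depth ≈300).

What the generator does **not** emulate: mapping bias toward the reference
allele, genotyping error, SNP-level depth correlation within a gene,
partial cis+trans architectures, batch effects, and count correlation
between genes. Passing recovery tests therefore demonstrates that the
statistical machinery is correct under its own model, not that real maize
libraries would behave this well.

## Numerical choices

- Dispersion floor 1e-8; pseudo-mean floor 0.5 normalized counts applied
  only to exactly-zero group means.
- Exact binomial p-values from the standard two-sided "sum of outcomes no
  more probable" definition (scipy), verified exhaustively against rational
  tail enumeration for totals ≤ 50.
- Percentages: half-up rounding (decimal arithmetic), 2 decimals for class
  shares, 1 decimal for the reciprocal split.
- Classification boundaries are strict on both sides; exact-threshold
  points are reported as a separate boundary label rather than forced into
  a class.
- NB sampling uses the (r = 1/α, p = r/(r+m)) parameterization; dispersions
  below 1e-7 switch to Poisson sampling.

## Problem sizes

The bundled experiments run on 2,000-gene simulations (class and cis/trans
recovery), 5,000-gene null simulations (calibration), and exhaustive
small-n enumeration for the binomial machinery; together they complete in
well under a minute on one CPU, and all are regenerated programmatically —
no data files ship with the package.

## Known limitations

- The DE stage trades power for transparency; near-threshold effects
  (≈2-fold) at low expression will be under-called relative to
  shrinkage-based tools, and log₂ fold changes are unshrunken.
- ASE inherits any mapping bias present in the upstream allele counting.
- The cis/trans scheme is categorical; it does not quantify cis and trans
  contributions for genes carrying both (those land in AMBIGUOUS).
- Boundary-exact ratios are reported but unclassified by design.
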