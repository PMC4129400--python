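# Methods

This note documents the statistical procedures `pqtlkit` implements, the
generating model of its synthetic cohorts, the numerical choices made where
the design was genuinely open, and what the test suite does and does not
establish about real data.

## Protein quantification

**Feature screening.** Each printed feature carries a raw integrated
intensity, a local background estimate, and a pixel-noise SD. Background is
subtracted per feature; features with negative corrected intensity are
excluded, as are features with signal-to-noise ratio (corrected intensity /
noise SD) below 3 — the boundary is inclusive (SNR exactly 3 is retained),
and a one-sided normal tail probability of the SNR is attached for
reference. Antibody screening classifies a lane profile as RPPA when a band
within ±15% of the predicted molecular weight has SNR >= 3 and carries more
than 75% of the lane signal, as MWA when a qualifying on-size band exists
but the 75% rule fails, and as failed otherwise. The ±15% MW tolerance is a
package choice (configurable); no tolerance is inherent to the rule.

**Normalization.** Feature intensities are log2-transformed and
quantile-normalized across the arrays of a print: each array's sorted
values are replaced by the across-array mean of order statistics and
reassigned by rank. Ties receive the average of the order-statistic values
they span ("average ties"); arrays of unequal length (after feature
exclusions) are mapped through the mean distribution by linear
interpolation on a common quantile grid. Sample load is removed by the
median model `y_jp ~ mu_jp + lambda_j + e` with
`lambda_j = median(mu_jp over the print)`: subtracting a per-sample median
guarantees the per-sample median residual in a print is exactly zero, and
deliberately avoids housekeeping-protein normalization (housekeeping levels
co-vary with growth rate, so dividing by them would inject a growth
artifact). MWA antibodies additionally have a per-(antibody, gel) median
removed, since each biological replicate runs on its own gel.

A consequence worth knowing: `lambda_j` is estimated from finitely many
antibodies, so it absorbs a `O(1/sqrt(n_arrays))` share of true biological
signal. With large prints this is negligible, but exact rank recovery of a
noise-free trait is attenuated to Spearman rho ~ 0.95–0.99 rather than
exactly 1; the tests assert the realistic bound. (The estimate is
essentially the first principal component of the data — which is the
intended behavior, since overall lysate concentration dominates that
component.)

**Aggregation and QC.** Technical replicates are averaged within
(individual, biological replicate, antibody, platform). Antibodies measured
on both platforms keep the platform with the higher median
background-corrected intensity. The biological-replicate axis is preserved
for mixed-model validation; the per-individual mean is the primary trait.
Quality filtering drops antibodies below the lower quantile of median
intensity or median SNR or above the upper quantile of technical CV —
quartile bounds by default, decile bounds as a mode (both rules appear in
the assay literature; quartile is the stricter and later description).
Quantiles use linear interpolation and boundaries are retention-inclusive,
so fully tied metrics drop nothing. Technical CV is computed across
technical replicates on the linear intensity scale; a bio-by-tech
alternative exists but is not the default.

## Covariates and hidden confounders

The covariate model is a replicate-level linear mixed model per trait:
fixed effects for EBV copy number, mitochondrial DNA copy number, baseline
ATP, intrinsic growth rate, sex, phase and any surrogate variables, with a
random per-individual intercept. Each biological replicate is an
independent freeze-thaw, so with one observation per thaw a separate
thaw-level intercept is not identifiable from the residual; the
per-individual intercept carries the thaw-within-individual structure.
Fixed-effect p-values use a Wald t statistic with denominator degrees of
freedom `n_individuals - n_fixed_effects` (an F-type choice with
between-individual residual df); in the zero-variance random-effect limit
this reproduces ordinary regression on replicate means. Constant covariates
are dropped with a warning rather than producing a singular fit.

Surrogate variables are estimated by permutation-calibrated parallel
analysis: SVD of the centered residual matrix, retaining leading components
while their explained-variance share beats the (1 - alpha) quantile of the
share obtained after permuting each trait column independently, stopping at
the first failure. This is a deliberate simplification of iteratively
reweighted SVA: it detects the same low-rank structure, is deterministic
under a seed, and its null behavior (k = 0 on noise) is directly testable.
Storey q-values use the lambda-smoothing pi0 estimate (grid 0.05–0.95,
cubic smoothing spline evaluated at the last grid point, clipped to (0, 1];
pi0 = 1 for small inputs where the spline is meaningless).

Association scans run on *unadjusted* traits by default — consistent with
the pQTL literature this pipeline targets, where covariate/SV correction
reduced discoveries — with adjustment available via `residualize`.

## Association mapping

Traits are inverse-normal transformed with the Blom offset c = 3/8
(`Phi^-1((rank - c)/(n - 2c + 1))`, average ranks for ties), making the
scan invariant to monotone transforms of the raw trait. Genotypes are mean
dosages in [0, 2]; variants are excluded when empirical MAF < 0.05 or when
the exact Hardy-Weinberg test (conditional enumeration over heterozygote
counts given allele counts, p = sum of configuration probabilities no
larger than the observed one) gives p < 0.001 on rounded hard calls.

The scan itself is ordinary least squares per (trait, variant), vectorized
as the cross-product of standardized matrices: r is the Pearson
correlation, the p-value is the two-sided t test with n - 2 df (floored at
1e-300 against perfect-fit underflow), and beta is the slope on the dosage
scale. Missing trait values are dropped listwise per trait; missing dosages
are mean-imputed per variant. Per trait, only the minimum-p variant in each
recombination block is retained (ties broken by smaller position, then
variant id). Blocks are derived from the recombination map as the intervals
between positions with rate > 10 cM/Mb. A hit is cis when the variant lies
on the trait gene's chromosome within [TSS - 1 Mb, TES + 1 Mb] in
transcription orientation, endpoints inclusive; since the default window is
symmetric, strand only matters for asymmetric windows. Hits below 1e-4 can
be re-validated with the replicate-level mixed model (fixed dosage, random
per-individual intercept, df as above).

## Permutation FDR

Individual labels of the trait matrix are permuted — jointly across
biological replicates by default, preserving within-individual replicate
correlation (per-replicate shuffling is a mode) — and the *entire* scan,
block-best reduction and cis/trans classification re-run per permutation
replicate. The empirical FDR at a threshold is the permutation-mean count
of null hits below it divided by the observed count, capped at 1, per
stratum; NA when no observed hits exist.

Two counting conventions are implemented. The default (`mode="hits"`)
counts permuted hits exactly like observed ones — every block-best
association below the threshold — so on fully null data the estimate is
near 1 at any threshold. The alternative (`mode="per_trait_best"`) keeps at
most one null hit per (trait, replicate): a family-wise-style null per
phenotype that is conservative per trait but *understates* the FDR wherever
a null trait could pass the threshold in more than one block; at desk
scales the deflation is large at loose thresholds, which is why it is not
the default. With symmetric counting the estimate at a *fixed* threshold is
unbiased for the realized false fraction; the threshold *search* (largest
observed-grid p with FDR <= target, grid points taken via `nextafter` so
strict counting includes them) still carries a winner's-curse selection
bias when the counts at the admitted threshold are small — an intrinsic
property of the procedure, visible in simulations with few traits and worth
remembering when reading small hit lists. The default number of permutation
replicates is 3 (matching the procedure the pipeline reproduces); the test
suite and the acceptance script use 10.

## Enrichment and concordance

Annotation enrichment builds, per functional class (the fixed 11-label
vocabulary), the 2x2 table of QTL membership against class membership over
the annotated background and computes the two-sided Fisher exact p by
direct hypergeometric enumeration in exact integer arithmetic (summing the
probabilities of all tables no more likely than the observed one); odds
ratios use the Haldane 0.5 correction when a cell is zero. LD expansion
adds all variants within ±1 Mb of a seed SNP with dosage r² > 0.8.
MAF-matched null sets preserve the catalog's per-bin counts exactly (5%
bins, half-open, top bin closed at 0.5), sampled without replacement within
a set; the sets are index-aligned to the catalog so any trait-wise
partition of the catalog induces matched partitions of every null set —
this is what makes per-trait empirical overlap p-values well defined. The
empirical p is the fraction of sets whose overlap strictly exceeds the
observed one; zero exceedances are reported censored at 1/n_sets, and
add-one smoothing is available.

Replication between cohorts is defined as nominal p < 0.05 with concordant
effect direction, giving a chance level of 0.025; replication-rate curves
use decade bins of discovery p. A knockdown is significant when the
percentage reduction exceeds twice its percentage standard error.

## The synthetic cohort

Genotypes: biallelic variants in LD blocks of consecutive variants, evenly
spaced (10 kb default) across 4 chromosomes. Haplotypes follow a Gaussian
copula — each haplotype draws one latent normal per block, and each
variant's allele indicator thresholds a mixture of the block latent and
private noise — so marginal allele frequencies are exact Bernoulli draws at
the configured MAF while within-block dosages are correlated. Variants
within a block share their allele frequency, as tightly linked real
variants do; with the default copula correlation (0.999) adjacent in-block
dosage r² is ~0.94 and a 50-variant block contains roughly 3 effective
tests, matching the strong within-block LD regime that best-per-block
reduction presupposes (real within-block pairs reach r² 0.87–0.99). The
recombination map places >10 cM/Mb spikes at block boundaries so block
detection reconstructs the planted blocks exactly.

Traits: each latent protein trait is `sum_k beta_k * z(dosage_k) + e` with
residual variance chosen for unit total variance, so beta is the population
dosage-trait correlation (planted effects span |R| 0.3–0.65, the largest
matching the strongest association the pipeline is designed to detect at
n = 68). Effect targets route effects to the protein layer, the mRNA layer,
or both, emulating discordant eQTL/pQTL architecture; phospho-only effects
act on the protein layer of their own antibody trait. Gene models are
placed so cis effects fall inside and trans effects outside the 1 Mb
window.

Arrays: raw intensity is `gain * 2^(latent + thaw + load + batch) +
background + N(0, noise_sd)` with gain 1e4 (scanner-count scale), load
effects per (print, sample) on the log2 scale (SD 0.25), batch shifts per
(MWA antibody, gel) (SD 0.25), thaw (biological-replicate) noise SD 0.3,
additive background 200 and noise SD 30. RPPA antibodies get 4 technical x
3 biological replicates on one array each, grouped into prints of 8; MWA
antibodies get 3 x 3 with one gel per biological replicate. The additive
Gaussian background plus multiplicative gain is an assumption — the true
scanner noise model is not validated against real arrays. Covariates are
generated with plantable correlations to chosen trait sets (feasible when
r <= 1/sqrt(|set|)); expression matrices add platform noise (SD 0.5) to
the latent mRNA layer.

What passing tests show, and what they do not: the generator reproduces the
*statistical* structure the pipeline assumes — replicate nesting,
multiplicative load, block LD, planted effect sizes — so recovery results
demonstrate the pipeline's correctness and calibration under that model.
They do not certify performance under real-array pathologies the generator
omits: spatial gradients within arrays, saturation and nonlinearity of
antibody response, heavy-tailed or intensity-dependent noise, cross-reactive
antibodies, or population structure in genotypes.

## Numerical choices and scales

Scan p-values are floored at 1e-300; quantile thresholds use linear
interpolation; QC boundaries retain exact ties; HWE uses a log-gamma pmf
normalized over the enumerated support; the INT denominator is
`n - 2c + 1`. KS uniformity checks on null scans use a 20,000-p-value
random subsample: scan p-values are dependent across LD-linked variants,
and a KS test on the full 10-million-value grid is sensitive far below the
dependence scale. The test suite runs null calibration at 68 x 200 x 50,000
with 10 permutation replicates (a single vectorized matrix product per
scan), parameter recovery over 100 cohorts at 1,500 variants, and the
acceptance script simulates the primary study at 60 antibodies and 6,000
variants — sizes chosen so the full suite completes in minutes while
keeping every estimate's Monte-Carlo error well inside the asserted bounds.

## Known limitations

- The load estimator consumes signal on small prints (see above).
- `mode="per_trait_best"` FDR is deflated at loose thresholds; the
  threshold search is subject to selection noise when admitted counts are
  small in either mode.
- The SVA variant is parallel analysis, not the iteratively reweighted
  algorithm; surrogate variables orthogonal to large planted structure are
  found, subtle signal-correlated confounding may differ.
- Serial-dilution linearity checks, image processing, probe remapping and
  genotype imputation are out of scope; the pipeline begins at exported
  feature tables and mean dosages.
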