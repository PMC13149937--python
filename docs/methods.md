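# Methods

This note documents the statistical models, the synthetic data the package
validates itself against, the numerical choices, and the limitations a
user should know before trusting the output on real data.

## Synthetic study design

All downstream methods consume summary statistics only, so the generator
simulates directly at the z-score level; no genotypes exist anywhere in
the package.  For each LD block with correlation matrix R,

    z_d = R (lambda_d + u_d) + L eps_d,        L = chol(R),

per disease d, where

* `lambda_d` is the per-SNP noncentrality — nonzero only inside planted
  genes whose disease subset contains d (the planted causal signal);
* `u` is a polygenic background, i.i.d. per SNP across the genome with
  cross-disease covariance `polygenic_var * rg_target`;
* `eps` is unit noise whose cross-disease correlation models sample
  overlap; it defaults to `rg_target` itself, i.e. all diseases measured
  on one cohort, which makes the marginal null z correlation across
  diseases equal rg exactly.

This construction yields the LD-score-regression moment structure
E[z²] = 1 + sigma_g² ℓ and E[z_a z_b] = sigma_g² rg ℓ + overlap, with ℓ
the LD score, so rg is identifiable from the regression slopes and the
free intercept absorbs overlap.

Default study conditions (the "fixture"): 6 diseases in 4 nosological
categories, case counts 3,000–20,000 against ~390,000 controls
(n_eff = 4/(1/n_case + 1/n_ctrl)); 4 chromosomes × 15 AR(1) LD blocks
(decay 0.6) × 50 SNPs at 2 kb spacing, blocks 1 Mb apart; one gene per
block covering SNPs 10–29; MAF uniform on (0.01, 0.5) with 2 % of SNPs
below 1e-5 to exercise the MAF filter; an MHC-like excluded region
covering one whole block; `polygenic_var = 0.25`; rg 0.5 between all
pairs; six planted genes spanning disease subsets of size 2–4 with
per-SNP noncentrality lambda = 4.  The AR(1) LD smears lambda to an
expected peak z of roughly lambda(1+r)/(1−r) = 16, i.e. essentially
complete single-SNP power at 5e-8 (critical z 5.45), which is what the
planted-gene recovery checks assume.

What the generator does **not** emulate: imputation quality and allele
mismatches, MAF-dependent effect sizes, LD between blocks and across
chromosomes, population stratification, and the X chromosome (autosomes
only by design).  Passing tests therefore demonstrate the correctness of
the algorithms under a clean summary-statistic model, not robustness to
real-data artifacts.

## Genetic correlations at desk scale

`estimate_rg` implements cross-trait LD-score regression with free
intercepts and a 20-block delete-one jackknife.  LD-score regression
needs many independent loci: at the fixture's 3,000 SNPs the estimates
are unbiased but noisy, so few disease pairs reach nominal significance
and the fully connected cluster is typically much smaller than the full
disease set.  For this reason the pipeline by default reports the cluster
but does not gate the downstream gene routes on it
(`restrict_to_cluster=False`); at biobank scale one would gate.  The
dedicated recovery check uses a design with stronger LD-score contrast
(500 blocks × 20 SNPs, AR decay 0.9, `polygenic_var = 0.5`), chosen by a
pre-hoc power analysis so that the slope regressors actually vary; there
the mean of 50 replicate estimates recovers rg = 0.5 to well within 0.1.

The maximum clique is found exactly (Bron–Kerbosch with pivoting via
networkx, all maximal cliques enumerated).  Ties are broken by the larger
sum of −log10(rg p) over clique edges, then lexicographically — this
makes the reported cluster deterministic, which matters because the
significance graph at nominal alpha is rarely unique in its largest
clique.

## Gene-based tests

The null model is z ~ N(0, R) for a gene's z-score vector with R the
local genotype correlation matrix, regularized by adding 1e-6 (retry
1e-4) to the diagonal.  MAF weights follow a beta density; the default
beta(1,1) is flat, implemented literally.

**SKAT-O.**  Q_rho = (1−rho) Σ w²z² + rho (Σ wz)² over the standard grid
rho ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}.  Per-rho p-values refer
Q_rho to its exact null, a weighted chi-square mixture with weights from
the eigenvalues of Psi^{1/2} A_rho Psi^{1/2}, Psi = W R W.  Mixture tails
are computed by numerical inversion of the characteristic function
(Imhof's integral — the same quantity Davies' algorithm evaluates) to
1e-9 absolute accuracy, with the kurtosis-modified Liu moment
approximation as fallback for tails below the inversion's resolution.

The omnibus correction for taking the minimum over the grid is computed
by one-dimensional integration over the shared burden component.  Writing
u = eta v + u_perp with v the unit vector along Psi^{1/2} 1, every Q_rho
decomposes exactly as

    Q_rho = (1 - rho)(T + eta² r²) + rho (1'Psi 1) eta²,

where T | eta is a *noncentral* chi-square mixture whose weights are the
eigenvalues of Psi^{1/2}(I − vv')Psi^{1/2} and whose noncentralities are
proportional to eta².  The crossing probability P(min_rho p_rho ≤ p_min)
is then an exact one-dimensional integral over eta²: the rho < 1
constraints form a piecewise-linear lower envelope in eta² (integrated
with Gauss–Legendre panels between its kinks), and rho = 1 contributes a
hard cutoff in eta².  The conditional noncentral tails use a noncentral
Imhof inversion in the tail region and a noncentral Liu moment
approximation in the bulk (crossing probability > 0.02), where a few
permille of absolute error is immaterial.  This construction replaces the
common moment-matched approximation of the conditional law, which we
measured to be 5–10 % anticonservative at nominal 0.05 for flat-weight
AR-correlated genes; against a 10⁶-draw Monte-Carlo ground truth the
implementation is accurate to ~1–2 % across p ∈ [1e-3, 0.2].  Observed
min-p is mapped to per-rho quantiles by inverting the same accurate
survival functions (interpolants when an engine is reused, direct
root-finding otherwise), never a different approximation.

**PCA test.**  Eigendecompose R; take the smallest k whose eigenvalue
share reaches 85 %; T = Σ_{i≤k} (v_i'z)²/λ_i ~ chi²_k.

**ACAT.**  Equal-weight Cauchy combination; p = 1 inputs are clipped to
1 − 1e-15 before the tangent transform.  Combining the two dependent gene
tests this way is the tail-robust convention.  Because the two component
tests are strongly dependent, the combination is slightly anticonservative
in the bulk: over 10⁵ simulated null genes spanning AR decays 0.1–0.8 we
measure a relative excess of about 6 % at alpha = 0.05, shrinking to about
4 % at alpha = 1e-3 — consistent with the combination's tail-exactness
guarantee, which holds only as alpha tends to zero.

Transcription bounds are 1-based inclusive and boundary SNPs belong to
the gene.  The LD-cluster evidence filter treats "identical association
pattern" as exact equality of significant-disease sets; looser matching
was rejected for reproducibility.

## Subset meta-analysis and loci

For one SNP, traits with two-sided p < 0.1 enter an exhaustive search
over nonempty subsets of the largest standardized combined z, with signs
free per trait (so opposite-direction effects can join) and weights
proportional to √n_eff.  A `max_traits` cap (default 10, smallest-p kept)
bounds the 2^k search, standing in for the trait-partitioning device used
by fast subset-search implementations at hundreds of traits.

The multiplicity of the search is absorbed by Monte Carlo: the null
distribution of the max statistic — *including the pre-filter step*, and
conditioned on at least one trait surviving it — is sampled once per
trait panel (2×10⁵ common-random-number draws, seeded), so null p_meta is
uniform among SNPs that return a result, and the genome-wide threshold is
slightly conservative marginally.  Beyond Monte-Carlo resolution the tail
is extended by an effective-number-of-tests normal tail m_eff·2Φ(−t),
with m_eff matched to the empirical tail at its 100/n quantile; this
keeps extreme p-values finite and monotone and preserves
p_meta ≥ 2Φ(−Z_best).  The null sampler accepts a trait-correlation
matrix; the pipeline feeds it the empirical z correlation of
sub-significant SNPs (|z| < 2 in all traits), which captures sample
overlap and polygenic sharing.  Marginal variance inflation from
polygenicity is removed by a genomic-control correction before the subset
search: each trait's z is divided by sqrt(lambda_GC), with lambda_GC the
median z² over the 1-df chi-square median, floored at 1.  Without it the
unit-variance null is anticonservative in the extreme tail and spurious
loci appear near the genome-wide threshold; the correction shrinks true
signals by the same few percent, which is immaterial at the planted
effect sizes.

Clumping follows PLINK-1.9 greedy semantics exactly (p1 5e-8, p2 1e-5,
r² ≥ 0.1, 1000 kb; assigned SNPs can neither seed nor join later clumps);
pairs spanning different LD blocks have r² = 0 by construction.  Index
SNPs within 500 kb (inclusive) merge, leftmost pair first, rescanned to a
fixpoint so chained merges are deterministic.  The new index follows the
cascade: same gene → smaller p; p-values ≥ one order of magnitude apart
(ratio ≥ 10, strict on the "comparable" side) → smaller p; else genic
over intergenic; else more significant traits; else smaller p; else
smaller position.  A locus takes the gene containing its index SNP
(smallest span, then lexicographic id, if several overlap), else the
nearest gene within the locus bounds, else none — gene-less loci are
retained and reported.  A locus' trait set is the union of best subsets
over its meta-significant member SNPs, which is why recovered trait sets
can slightly exceed the planted subsets (a null trait occasionally rides
along at a true locus).

## Integration and enrichment

The three gene→disease maps are unioned with per-pair method provenance;
genes keep ≥ 2 diseases after the union.  The disease network connects
diseases sharing ≥ 1 gene (edge weight = shared-gene count); isolated
diseases are kept as nodes so connectivity fractions are checkable.
Enrichment is a one-sided hypergeometric upper tail per gene set with
Benjamini–Hochberg step-up adjustment (statsmodels), significant at
adjusted p < 0.05.  The background defaults to all genes in the
annotation — an explicit, reproducible substitute for web-service
defaults that cannot be pinned down; enrichment results are therefore
methodologically, not numerically, comparable to web-based runs.

## Numerical choices

* Imhof inversion: composite 10-point Gauss–Legendre panels half an
  oscillation period wide, truncation chosen by a two-term
  integration-by-parts tail bound; locally adapted panel widths in the
  noncentral case (the noncentrality's frequency contribution decays like
  1/(1+λ²u²)).
* p-values are floored at 1e-300; ACAT inputs clipped at 1 − 1e-15.
* LD regularization delta 1e-6, retried at 1e-4; condition number above
  1e12 triggers the retry, and failure raises with a diagnostic.
* Jackknife uses 20 contiguous SNP blocks (configurable); rg p-values are
  two-sided normal on rg/se.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds reproduce byte-identical
  fixture bundles.
* Test problem sizes (3,000-SNP fixture, 10⁴-SNP rg replicates, 2×10⁴
  null gene tests) were chosen as the smallest designs at which the
  checked properties are statistically identifiable.

## Known limitations

* LD-score regression at thousands of SNPs is underpowered; the fully
  connected cluster is only meaningful at real-data scale.
* The subset meta-analysis null assumes the supplied trait correlation
  and unit marginal variances; strong uncorrected polygenicity inflates
  the meta tail (visible as rare gene-less false loci).
* The evidence-score cluster filter, consequence table and gene sets are
  consumed as given; no attempt is made to validate them.
* The exhaustive subset search is exponential in retained traits and
  capped at `max_traits`; at hundreds of diseases a block-partitioned
  screening would be required.
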