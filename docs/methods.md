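# Methods

## Overview

`xwas` implements a summary-statistic association pipeline linking a trait to
genetically predicted molecular abundance (protein, transcript or splicing
level), followed by Bayesian colocalization and chemical gene-set enrichment.
Because the real inputs of such studies (large GWAS meta-analyses, brain
pQTL/eQTL weight panels, curated chemical–gene interaction sets) are
restricted-access or very large, the package ships a synthetic-data module
that generates all four input classes with the statistical structure the
analysis assumes, so every stage is testable end to end with no download.

## The association statistic

For a gene with cis-SNP weight vector `W`, per-SNP GWAS Z-scores `Z` and
SNP-correlation (LD) matrix `S` from a reference panel, the gene statistic is

    z = W'Z / sqrt(W'SW)

Under the null hypothesis that predicted abundance is unrelated to the trait,
`z ~ N(0, 1)`; the asymptotic P is two-sided. The statistic is invariant to
rescaling of `W` and to simultaneous allele flips of any SNP subset across
`W`, `Z` and `S`. `S` is ridge-stabilized (`S + 1e-6 I`) before the quadratic
form because finite-panel correlation matrices are near-singular; a gene with
`W'SW <= 1e-8` is skipped as degenerate.

### Permutation-based empirical P

The default null permutes the assignment of weights to SNPs within the locus
and recomputes `z`, conditioning on the observed GWAS signal and the LD.
This asks whether the *specific alignment* of weights with the GWAS signal is
better than chance — a gene can have an enormous asymptotic `|z|` purely
because it sits in a strongly associated region, and the permutation test
deflates exactly those cases. The empirical P uses the add-one estimator
`(1 + #{|z_perm| >= |z_obs|}) / (n_perm + 1)`, which is conservative and never
zero; its floor is `1/(n_perm + 1)`. A sign-flip mode (`mode="sign_flip"`) is
provided as a sensitivity check. Default `n_perm = 5000`; the pipeline and
tests use smaller values (200–500), which changes only the resolution of the
empirical P, not its calibration.

Two structural properties of this null matter for study design:

* For a locus whose fitted weights are a single spike (one nonzero entry),
  roughly `1/m` of permutations reland the spike on its own SNP and tie the
  observed statistic, so the empirical P cannot fall below about `1/m`
  regardless of effect size. Effectively single-causal genes are therefore
  hard to declare significant under this test.
* Exchangeable (e.g. i.i.d. random) weights give uniformly distributed
  empirical P under the null GWAS, which is the calibration property the
  acceptance suite checks.

## Weight training

Weights are trained on standardized dosages (mean 0, variance 1) against the
standardized trait:

* `top1` — the single best marginal SNP, weight = its marginal beta;
* `ridge_blup` — `(X'X + kappa I)^{-1} X'y` with the BLUP-motivated default
  `kappa = m (1 - h2) / h2` from the gene's estimated cis heritability;
* `elastic_net` — scikit-learn `ElasticNetCV` (l1_ratio 0.5, inner 3-fold CV);
* `spike_slab` — a small Gibbs sampler for a point-mass spike-and-slab prior
  with conjugate updates for the residual variance, slab variance and
  inclusion probability; posterior-mean weights. It is a surrogate with the
  sparse-plus-polygenic flavour of Bayesian sparse linear mixed models, not a
  re-implementation of the original MCMC software, and is excluded from the
  pipeline's default menu on runtime grounds (~2 s per gene with nested CV).

The model with the best K-fold cross-validated R² (default 5 folds, seeded
fold assignment) is selected; ties break by fixed precedence spike_slab >
elastic_net > ridge_blup > top1. A gene whose best cv_r2 is <= 0 is flagged
non-predictive and excluded downstream. Dosage standardization is computed on
the full sample (as weight-training pipelines in this field conventionally
do); the fold-level leakage this introduces is negligible at the sample sizes
used and does not affect model ranking in practice.

Cis heritability uses a Haseman–Elston moment estimator: off-diagonal trait
cross-products `y_i y_j` regressed on the cis genetic relatedness `K_ij`
(`K = XX'/m`). The slope estimates h2; a one-sided P comes from the
asymptotic normal of the no-intercept OLS slope. Under the null the
cross-products are pairwise uncorrelated, so the OLS standard error is
calibrated exactly where the "significantly heritable" filter operates.
Estimates are clipped to [0, 1] with the pre-clip value retained. The filter
threshold `alpha_h2` defaults to 0.01 (configurable); the heritability screen
of real weight panels is not defined more precisely by their distributors.

## Colocalization

Per-SNP Wakefield log approximate Bayes factors,
`log ABF = 1/2 log(1 - r) + r z^2 / 2` with `r = prior_var/(prior_var + v)`,
are combined over the five single-causal-variant hypotheses (H0 none, H1/H2
one trait only, H3 both traits distinct variants, H4 shared variant) with the
canonical priors `p1 = p2 = 1e-4`, `p12 = 1e-5`. Effect-size prior variances
default to `0.15²` for quantitative molecular traits and `0.2²` for the
(binary) GWAS trait. When no standard error is available the per-SNP sampling
variance is derived as `v = 1/(2 f (1 - f) n)`. All sums use log-sum-exp, so
`|z|` up to 40 cannot overflow; in a single-SNP region the H3 cross-term
cancels algebraically and PP3 is exactly 0. Colocalization is gated to genes
passing the association screen (default: permutation P < 0.05), mirroring how
such pipelines restrict coloc to significant genes. QTL summary statistics
for synthetic data are the per-SNP marginal regressions of the molecular
trait on dosage — the same way pQTL/eQTL inputs arise.

## Gene-set enrichment

Genes are ranked by the association statistic (default `|z|`, signed ranking
by flag) from largest to smallest, ties broken lexicographically by gene id.
For a set C of N_C genes in a universe of N, the enrichment score is the
maximum of the weighted Kolmogorov–Smirnov running sum

    ES = max_j [ sum_{hits i<=j} |GS_i|^H / N_R - sum_{misses i<=j} 1/(N - N_C) ]

with `N_R = sum_{hits} |GS_i|^H` and weight exponent `H = 1`. The sum ends at
0, so ES lies in [0, 1]; only the positive deviation is scored (one-sided, as
the formula is written). ES is invariant to positive rescaling of the
statistics. If all member statistics are zero, ES is defined as 0 and
flagged.

Two permutation nulls: `snp_shuffle` (faithful, expensive) permutes the
SNP-to-Z assignment of the GWAS, recomputes every gene's statistic, re-ranks
and rescores each set — preserving the gene-set structure and the weight
models while destroying the SNP-level association signal; `gene_shuffle`
(fast) permutes the gene-to-statistic assignment, equivalent to uniform
random membership of the same size. `NES = (ES - mean(ES_null)) / sd(ES_null)`
with the sample SD (n−1 denominator); the empirical P is add-one exceedance.
Default `n_perm = 20000`; the pipeline uses 500 with the same estimator. In
`gene_shuffle` mode each set gets an RNG substream derived from the master
seed by the set's rank in sorted-id order, so results are independent of
collection ordering; substreams can be disabled so duplicated sets reproduce
identical P values. In `snp_shuffle` mode all sets share each permutation's
re-ranked statistic vector (one GWAS shuffle is one null world for every set).

## Synthetic data

* **Reference panel.** Two haplotypes per individual are drawn from a latent
  AR(1) Gaussian with neighbour correlation `ld_decay` and thresholded at the
  per-SNP allele frequency (uniform in `maf_range`, default lower bound 0.05);
  dosage = sum of the two indicators. One knob controls adjacent-SNP LD;
  `ld_decay = 0` gives independent SNPs. One chromosome by default, 1-based
  positions at fixed spacing, alleles fixed to A/C with a1 the effect allele.
  Monomorphic draws are retried a bounded number of times, then fail loudly.
* **Molecular traits.** trait = sqrt(cis_h2) × standardized genetic score +
  sqrt(1 − cis_h2) × N(0,1) noise; the genetic score is a sparse combination
  of causal cis dosages. Per-causal effect sizes are N(0,1) by default; the
  pipeline uses equal-magnitude random-sign effects (`effect_dist =
  "rademacher"`) because Gaussian draws frequently produce one dominant
  causal SNP — an effectively single-causal architecture in which the
  weight-shuffle permutation null is degenerate (see above) — whereas
  equal-magnitude effects realize the intended polygenic cis model.
* **GWAS summary.** One Z vector per study drawn from
  `MVN(sum_g lambda_g S W_g, S)` with each mediated gene's true weight vector
  rescaled to `W'SW = 1`, so `lambda_g` is exactly the expected gene-level
  association Z — making effect recovery a sharp test. An exporter can flip
  the allele orientation of a random SNP subset (negating Z) to exercise
  harmonization.
* **Chemical gene sets.** Sets sample members with probability weight
  `exp(strength × (1 − rank percentile))` against a supplied ranking;
  strength 0 is uniform. The first `n_enriched` sets are enriched, the rest
  background.

What the generator does **not** emulate: realistic human allele-frequency
spectra and LD blocks, imputation error, case/control liability-scale
effects, covariate structure (age/sex/ancestry), trans-QTLs, and overlapping
cis windows between genes (the pipeline assigns disjoint SNP blocks). Passing
tests therefore demonstrate the statistical machinery is correct and
calibrated under the assumed model, not that any biological conclusion
transfers to real cohorts.

## Pipeline and study conditions

The driver simulates one GWAS and three cohorts (discovery proteome,
replication proteome, transcriptome) sharing the causal architecture but with
independent trait noise — emulating a discovery/replication design with a
transcriptome comparison. Defaults: 400 individuals, 200 genes × 12 SNPs,
`ld_decay 0.3`, cis_h2 0.5, 3 causal SNPs per gene, 3 mediated genes at
λ = 6, 500 association permutations, 500 GSEA permutations (snp_shuffle),
alpha 0.05 everywhere, heritability screen at 0.01. A full run takes about a
minute on one CPU and is byte-identical under a fixed seed (the manifest's
wall-clock field is the only non-deterministic output). All stage tables are
stamped with a hash of the canonical configuration.

Note that with a shared GWAS, the discovery and replication statistics of a
*null but heritable* gene are strongly correlated (both panels learn similar
weights), so the null intersection rate is ≈ alpha per gene, not alpha² —
replication across panels guards against panel-specific weight artifacts, not
against GWAS-level noise.

## Numerical choices

* Ridge `1e-6` on every LD matrix use; degeneracy threshold `1e-8` on `W'SW`.
* Add-one empirical P everywhere a permutation null is used.
* Sample SD (ddof 1) in NES; a numerically zero null SD leaves NES missing
  (NaN) while the empirical P is still reported.
* Ranking ties break lexicographically by gene id; CV folds, Gibbs chains and
  every generator are seeded; seeds derived from a master seed stay below 2^31.
* Genes with zero SNP overlap after harmonization, degenerate weight
  variance, or all-zero weights are skipped with logged reasons, never
  silently dropped.

## Known limitations

* Single-causal-variant colocalization only (no SuSiE-style decomposition).
* No conditional/joint multi-gene association, no weight imputation for
  missing SNPs (they are dropped), no multi-collection FDR for enrichment.
* The spike-and-slab surrogate uses short chains tuned for small cis loci
  (tens of SNPs); it is not intended for genome-wide fits.
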