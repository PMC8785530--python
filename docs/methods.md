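# Methods

`lactoqtl` implements a two-step non-additive genome scan for
quantitative lactation traits in a mixed-breed dairy population, plus
the surrounding machinery needed to exercise it end to end: a synthetic
population generator, genotype quality control, additive+dominance
GREML, and iterative conditional mapping.  This note records the models,
the defaults and why, and the choices made where the design was open.

## The association model

For each dense test variant the scan conceptually fits

    y = 1 mu + T b + M_alpha alpha + M_delta delta + e,

where `y` holds per-animal first-lactation yield deviations, `T` maps
animals to the variant's three genotype classes with effects
`b = (b0, b1, b2)`, `M_alpha` (dosage codes 0/1/2) and `M_delta`
(heterozygosity codes 0/1/0) hold all structure-panel SNPs with random
effects `alpha_j ~ N(0, sigma2_alpha)` and `delta_j ~ N(0,
sigma2_delta)`, and `e ~ N(0, R)` with `R = diag(sigma2_e / w_i)` —
`w_i` is the number of test-day records aggregated into animal *i*'s
yield deviation, so better-recorded animals carry more weight.

Fitting this per variant at scale is done in two steps:

1. **Structure adjustment.**  A BayesC0-style single-site Gibbs sampler
   fits the model without the `T b` term: every structure SNP's additive
   and dominance effect simultaneously, with common effect variances and
   scaled inverse chi-squared priors on `sigma2_alpha`, `sigma2_delta`,
   `sigma2_e`.  500 post-burn-in draws of all effects are retained.
   Convergence is monitored on the three variance chains with the Geweke
   diagnostic (the monitored scalar is a choice; the variance chains
   summarise the whole effect vector and mix slowest).
2. **LOSO phenotypes and class effects.**  The genome is tiled into
   10-Mb half-open segments (a 1-based position `p` belongs to tile
   `floor((p-1)/1e7)`).  For segment `s` and retained draw `t`, the
   adjusted phenotype is `y - mu_t -` (all sampled SNP contributions
   outside `s`); leaving the segment's own SNP effects in place keeps
   local QTL signal from being shrunk away by the adjustment.  For each
   test variant and each draw `t`, the weighted least-squares class
   means of the LOSO phenotype are computed and a draw is taken from
   their conditional normal, so the resulting chain's spread combines
   within-sample estimation error and between-sample adjustment
   uncertainty.

Chains are summarised as three contrasts: genotypic additive effect
`a = (b2 - b0)/2`, genotypic dominance effect `d = b1 - (b0 + b2)/2`,
and the standard-additive (dosage-slope) effect expressed as a contrast
of the class effects with weights derived from the class weight sums
(this equals the weighted regression of phenotype on dosage; the exact
definition of the standard-additive contrast was open and this is the
natural one).  `z = posterior mean / posterior SD` with two-sided
standard-normal p-values; Storey q-values on the dominance p control the
FDR per trait; loci pass calling at `q_d < 1e-3` and
`max(|a|, |d|) > 5%` of the phenotypic SD.  The dominance coefficient
`k = d/|a|` classifies the mechanism: `|k| <= 0.1` additive,
`0.1 < |k| < 0.7` partial dominance, `0.7 < |k| < 1.3` the recessive
window, `|k| >= 1.3` over-dominance (negative k is mirrored; bin edges
are configurable).  Variants with an empty homozygote or heterozygote
class have `a`/`d` undefined and are excluded from dominance calling but
keep their dosage-slope result.

**Storey q-values.** `pi0` is estimated on the lambda grid 0.05..0.95
with a cubic-polynomial smoother evaluated at the largest lambda — a
deliberate, simple stand-in for the spline smoother in the original
procedure; with fewer than 100 p-values `pi0` is pinned at 1.
`q_(i) = min_{j>=i} pi0 * m * p_(j) / j`, ties sharing a value.

**Priors.** "Standard priors" are not a published recipe, so the scaled
inverse chi-squared priors use df = 4 and scales chosen so the prior
mean splits the phenotypic variance 45/5/50 into additive / dominance /
residual, spread over the SNP panel; all overridable.  Burn-in and
thinning are package choices (defaults 1,000 and 10); only the retained
count of 500 is treated as fixed by the method.

## Quality control

Two cascades, thresholds applied as strict inequalities exactly as
stated: the structure panel drops variants with missing rate > 0.01,
MAF < 0.02, Hardy-Weinberg deviation > 0.15, or DR2 < 0.9, then greedily
LD-prunes pairs with R2 > 0.9 within 1 Mb keeping the higher-MAF member
(left-to-right by position; the pruning algorithm itself was not
specified).  The HWE statistic is the absolute difference between
observed and expected heterozygote frequency computed within breed
stratum (maximum over strata): 0.15 is far too large to be a p-value
threshold at these sample sizes, so a frequency-scale deviation is the
only consistent reading.  The sequence (test) panel drops variants with
hom-alt count <= 5 — below that no dominance contrast is estimable — or
DR2 < 0.7.  Every removed variant records exactly one first-failure
reason.  Missing genotypes are mean-imputed only at model-fitting time,
never during QC.

## GREML

Additive relationships use centred/scaled dosage codes
`(x - 2p)/sqrt(2pq)`; dominance relationships use the orthogonal coding
(hom-ref, het, hom-alt) -> `(-2p^2, 2pq, -2q^2)` scaled by `2pq`.  Both
have expected diagonal 1 under HWE and the codings are uncorrelated in
an HWE population, which is what lets additive and dominance variance be
separated.  Variance components are estimated by average-information
REML with (i) a minimum-norm AI step that tolerates a singular AI
matrix, (ii) components pinned at a small positive floor when their
gradient points outward (non-negativity by projection; a zero estimate
is a boundary solution, which does occur for dominance), and (iii) a
true EM-REML step — monotone in the restricted likelihood — whenever
the AI step decreases it.  Convergence is a restricted log-likelihood
change below 1e-6.  SEs come from the inverse AI matrix with the delta
method for the ratios h2 and delta2.  Record-count weights are not used
here (homoscedastic residual): the heritability analysis operates on
yield deviations as-is, and within-breed purebred subsets are the
intended input.

## Iterative conditional mapping

Conditioning subtracts, per retained draw, jointly fitted
genotype-class effects (WLS with an intercept; collinear indicator
columns dropped by pivoted QR) of all conditioned variants from the
LOSO phenotypes.  Each round re-scans the chromosome, recomputes
q-values over the scanned set, and conditions on the most significant
dominance call (or the next user-supplied candidate); iteration stops
when nothing passes both thresholds or a round cap (default 5) is hit,
with an oscillation guard if a variant re-enters.  Only the association
step is re-run between rounds; the genome-wide Gibbs adjustment is not
refitted (whether the original procedure refitted it is not stated; the
adjustment does not involve the conditioned classes, so refitting would
change nothing to first order).  Additive tags are selected by greedy
genotype-level forward selection on the dosage slope — candidates refit
jointly with selected tags as covariates on the posterior-mean LOSO
phenotype, stopping at FDR 1e-3 — a direct-genotype replacement for
summary-statistic conditional-and-joint analysis, chosen because the
genotypes are in hand and reference-panel LD approximations are then
unnecessary.

## The synthetic population

The generator emulates the *statistical structure* the analysis
assumes, not any real cattle population:

* **Two breed pools + crossbreds.**  Founder haplotypes per pool follow
  a latent Gaussian AR(1) along each chromosome (default rho 0.95
  between adjacent variants), giving tunable local LD; pool allele
  frequencies differ by `delta ~ N(0, divergence * sqrt(pi/2))` so the
  mean absolute pool difference targets the divergence parameter
  (default 0.1, a plausible between-breed differentiation for dairy
  breeds).  Animals draw two founder-mosaic gametes (Poisson crossovers
  at 1e-8/bp); crossbreds draw each gamete from pool A with probability
  beta in {0.25, 0.5, 0.75}.
* **Planted QTL** bypass the founder mosaic: each gamete carries the
  minor allele as an independent Bernoulli(MAF) draw, optionally
  restricted to one pool's gametes.  Genotype-class values are
  `(-a, d, +a)` about the homozygote midpoint, so a fully recessive
  deleterious minor allele has `d = -a` and `k = 1`.  Tag variants at a
  chosen allelic correlation can be planted for LD-decay experiments.
* **Phenotypes** are `y_i = g_i + u_add,i + u_dom,i + ebar_i`:
  polygenic values built from the structure SNPs (additive from centred
  dosages, dominance from the orthogonal codes), each rescaled to an
  exact target sample variance so heritability targets are realized by
  construction, and `ebar_i` the mean of `w_i` independent test-day
  residuals (`Var = sigma2_e / w_i`).  Record counts are 1 + Poisson(7)
  — roughly monthly herd tests over a lactation; the true distribution
  is unpublished, so it is a config default, not an inference.  DR2 is
  simulated independently of genotype (only filter behaviour is in
  scope, not imputation accuracy).

What the generator does **not** emulate: pedigree and selection
structure, genotyping error, multi-trait genetic correlations, fixed
breed means (phenotypes are emitted already adjusted for non-genetic
effects, as yield deviations are), or sequence-realistic LD between
planted QTL and the surrounding variants.  Passing tests therefore show
that the machinery recovers what it models — not that real imputed
sequence data would behave as cleanly.

A scale caveat worth stating: with a desk-scale structure panel
(hundreds of SNPs rather than ~31k), each panel SNP carries an
individually non-trivial share of the polygenic variance, and Bayesian
shrinkage leaves most of that variance in the adjusted phenotype.  Test
variants in LD with panel SNPs (or with a breed axis, under divergence)
then tag real background signal, inflating the dosage-slope scan.  This
is a property of the scaled-down study conditions, not of the method;
fixtures that probe calling logic therefore use a small, finely spread
polygenic background.

## Numerical choices

* Gibbs covariates are column-centred and held in float32 (memory-bound
  kernel); accumulations are float64.  Zero-variance SNP columns are
  pinned to zero effect.
* The class-effect scan materialises one LOSO segment at a time and
  batches variants through three indicator-matrix products.
* Geweke uses the first 10% vs the last 50% of the chain with
  Bartlett-windowed spectral variances (lag window sqrt(n)); constant
  chains return z = 0 with a degenerate flag.
* GRM construction mean-imputes missing dosages and excludes
  monomorphic variants with a warning.
* The covariance Cholesky in REML retries with escalating diagonal
  jitter before failing.
* Determinism: every stochastic component takes a seed; the pipeline
  derives per-stage seeds from the global seed and stage name, and
  reruns are byte-identical.

## Problem sizes used in the test and reproduction suites

The recovery studies run at sizes chosen so the whole suite completes
comfortably on one CPU: pipeline recovery of the planted recessive QTL
uses n = 20,000 animals (the expected ~18 minor-allele homozygotes at
MAF 0.03 are what the method needs to see) with 500 structure SNPs and
2,000 test variants over 10 seeded replicates; null calibration uses
n = 2,000 with 2,000 test variants over 8 replicates; GREML recovery
uses n = 2,000 with 5,000 SNPs; the LD-decay experiment uses n = 40,000
at MAF 0.3 where class means are precise enough to separate the R^2 and
R^4 laws.  Gibbs settings in these studies retain the full 500 draws
but shorten burn-in/thinning (200/1), which affects Monte-Carlo error
only.

A power note on the recessive-recovery conditions: at MAF 0.03 and
n = 20,000 the dominance z-statistic at the causal variant concentrates
around 5.0-5.4, while `q < 1e-3` over 2,000 tests requires roughly
|z| > 5.0.  The per-replicate pass probability is therefore materially
below 1, and the >= 90% replicate criterion is at the edge of what
these study conditions can deliver; the suite reports it honestly
rather than relaxing the conditions.

## Known limitations

* The Gibbs sampler is single-chain; between-chain diagnostics are not
  implemented.
* `pi0` smoothing by cubic polynomial can differ slightly from the
  spline-based original in the extreme tail of the p distribution.
* Conditioning assumes conditioned variants are genotyped in all
  animals (no missing-dosage handling in the conditioning design).
* Multi-allelic variants are rejected, not split.
* GREML at n much beyond ~10,000 animals would need out-of-core
  linear algebra; the implementation holds dense n x n matrices.
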