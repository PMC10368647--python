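# Methods

## The problem

A polygenic index (PGI) is a weighted sum of allele counts,
`PGI_i = sum_j w_j g_ij`, with weights estimated in a GWAS discovery
sample. Because the discovery sample is finite, the weights — and hence
the PGI — carry measurement error: `PGI = PGI* + nu`, where `PGI*` (the
additive SNP factor) is the best linear SNP predictor of the phenotype.
Regressing a standardized outcome on the standardized PGI therefore
attenuates the coefficient by `sigma_PGI* / sqrt(sigma_PGI*^2 +
sigma_nu^2)`; equivalently, the squared standardized coefficient equals
the realized R^2 rather than the SNP-based heritability `h2_SNP` that
bounds it. This package implements and benchmarks the two standard
corrections:

* **ORIV** (obviously-related instrumental variables). Split the discovery
  sample in two, build two PGIs whose measurement errors are independent,
  divide each standardized PGI by `sqrt(rhat)` where
  `rhat = corr(PGI1_st, PGI2_st)`, and run a stacked two-stage least
  squares in which each scaled PGI instruments the other. The scaling makes
  the 2SLS estimand the effect of one standard deviation of the *true*
  latent index; without it, IV overcorrects. The stacked system duplicates
  every observation (stack-specific intercepts, standard errors clustered
  on the individual; with family fixed effects, a family-by-stack effect
  and family-level clustering), and its point estimate equals the average
  of the two directed just-identified IV estimates.
* **PGI-RC** (repository correction). Multiply the OLS coefficient of the
  standardized PGI by `sqrt(h2_SNP / R^2)`, with `h2_SNP` estimated by
  GREML in the analysis sample. In the univariate standardized case
  `R^2 = beta_hat^2`, so the corrected point estimate is exactly
  `sqrt(h2_hat)`. Two standard errors are reported: the *default* scales
  the OLS standard error by the same factor; the *GREML-uncertainty*
  variant propagates the heritability estimation error,
  `se(h2_hat) / (2 sqrt(h2_hat))`. Runs with `h2_hat < 0.01` are flagged
  and dropped from scenario aggregates, since the uncertainty variant
  diverges there.

The useful closed forms: the expected out-of-sample R^2 of a PGI under
equal per-SNP contributions is `R^2 = h2^2 / (h2 + M / N_GWAS)`; the
first-stage F of the ORIV system for two standardized PGIs is
`F = rhat^2 (N - 2) / (1 - rhat^2)`, and the IV small-sample bias scales
as 1/F.

## The simulator

`pgicorr.simulate` is a forward-in-time family simulator of unlinked
diploid SNPs (a GNAMES-style design). One generation of N individuals is
paired into N/2 monogamous couples; every couple has exactly two children,
keeping the population size constant. Transmission is Mendelian and
unlinked: each parent passes one of their two alleles per locus uniformly
at random.

The phenotype of a child is

    Y = sqrt(h2) * G_st + sqrt(n2) * P_st + e

with `G_st` the standardized direct genetic factor (`sum_j beta_j g_ij`,
standardized to mean 0 / variance 1 within each generation), `P_st` the
standardized parental-nurture factor (`sum_j gamma_j (g^F_ij + g^M_ij)`,
zero for founders), and `e` Gaussian noise scaled so `Var(Y) = 1` in
expectation. Direct and nurture effects are drawn independently, which
yields the identity `h2_SNP = h2 + 0.5 n2`: the child's own genotype
carries the direct factor plus half of the nurture variance through
transmitted alleles. The per-generation standardization of the latent
factors keeps the "contemporary" heritability — and hence the target
coefficient — fixed even when assortative mating inflates the genetic
variance.

Key parameters (defaults are the study conditions):

| parameter | meaning | default |
|---|---|---|
| `n_snps` (M) | unlinked causal SNPs | 5000 in the study grid |
| `h2` | variance share of direct effects | 0.25 (0.2 with nurture) |
| `n2` | variance share of genetic nurture | 0 (0.1 in nurture scenarios) |
| `am_rho` | phenotypic correlation between mates | 0 |
| `rg_disc_pred`, `rg_disc_disc` | genetic correlation between partitions | 1 |
| `founder_maf_range` | founder allele frequencies, uniform | (0.1, 0.5) |
| `n_generations` | post-founder generations | 1; 10 when `am_rho > 0` |

Design choices where the design was genuinely open:

* **Assortative mating** is implemented by Gaussian-coupling rank
  matching: the generation is split at random into two pools, pool A is
  sorted by phenotype, pool B by `am_rho * Y + sqrt(1 - am_rho^2) * z`
  with z standard normal, and ranks are paired. This hits the target mate
  correlation without iterative tuning and reduces to random pairing at 0
  and exact phenotypic sorting at 1. Ten post-founder generations are the
  default under assortative mating so the genotypic correlation structure
  approaches equilibrium.
* **Imperfect genetic correlation** between partitions is realized by
  correlated per-SNP direct-effect vectors (a bivariate Gaussian draw);
  each partition's phenotypes use its own vector. Only one of the two
  genetic-correlation parameters may be below 1 at a time, matching how
  the scenarios vary them.
* **Genetic nurture under assortative mating** induces an emergent
  correlation between the direct and nurture factors. The noise variance
  is then set from the *realized* `corr(G_st, P_st)` so that `Var(Y) = 1`
  still holds in expectation; if the variance budget is infeasible the
  simulator raises a diagnostic error rather than silently rescaling.
* **Target coefficient.** Between families the target is the standardized
  coefficient of Y on the total latent additive SNP factor. Without
  assortative mating this is `sqrt(h2 + 0.5 n2)` in closed form (0.5 in
  every baseline and nurture scenario); with assortative mating and
  nurture combined it is computed by regressing Y on the realized latent
  factor in the prediction sample, which absorbs the emergent covariance.
  Within families the target is `sqrt(h2)`.
* **Founders** have no nurture term (no simulated parents); their noise
  share is `1 - h2`.

The final generation is partitioned at the family level into two GWAS
discovery samples and a prediction sample. GWASs use one sibling per
family, drawn uniformly at random, so the summary statistics are
between-family; the prediction sample keeps both siblings, enabling
family-fixed-effects estimation. Between-family regressions in the
scenario harness use both siblings with family-clustered standard errors
(a one-sibling switch exists).

## GWAS, meta-analysis, PGI

Each SNP is tested by simple OLS of the phenotype on the allele count
(classical standard errors, vectorized across SNPs); with unlinked SNPs
and no confounding, no covariates are needed. Monomorphic SNPs get zero
weight everywhere. The two discovery GWASs are combined by fixed-effects
inverse-variance meta-analysis (equal-N inputs make this identical to
sample-size weighting). A PGI is the genotype matrix times a weight
vector; all PGIs are standardized in the analysis (prediction) sample
with the N-1 sample standard deviation.

## GREML

The SNP-heritability input of the PGI-RC comes from a single-component
GREML: `y ~ N(mu 1, sigma_g^2 A + sigma_e^2 I)` with
`A = Z Z' / M` from column-standardized genotypes. Individuals with
pairwise relatedness above 0.05 are removed by greedy pruning (drop the
individual in the most above-cutoff pairs, ties to the lowest ID). With
sibling pairs and M = 5000 this removes one sibling per family plus the
incidental tail of the noise distribution of unrelated-pair relatedness —
the GREML sample is therefore substantially smaller than the prediction
sample, as reflected in the GREML-uncertainty confidence intervals. Note
the cutoff only behaves sensibly when `3 sigma = 3 / sqrt(M)` is safely
below it; at small M (unit-test scale) the one-sibling-per-family path
with a relaxed cutoff is the right tool.

The restricted likelihood is maximized by rotating the data into the
eigenbasis of A (one `eigh`), profiling out the mean and the total
variance analytically, and optimizing the single parameter
`h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)` on [0, 1] with a bounded
scalar search (tolerance 1e-6). The standard error is the inverse square
root of the numerical curvature of the profiled restricted log-likelihood
at the optimum; boundary estimates (within 1e-3 of 0 or 1) are flagged.
On small instances the optimum agrees with a dense-matrix grid search of
the restricted likelihood to 2e-3.

## Standard errors and inference

Cluster-robust covariances use the CR1 small-sample factor
`G/(G-1) * (N-1)/(N-K)`. Family fixed effects are absorbed by demeaning
(the projection identity), with K counting the absorbed means so the
standard errors match an explicit dummy fit. Between-family ORIV clusters
on the individual (each individual appears in both stacks); within-family
ORIV absorbs family-by-stack effects and clusters on the family, which is
what two-way clustering on individual and family reduces to when
individuals are nested in families. Within-family ORIV reuses the
between-family `rhat` for the scaling. Confidence intervals are
point +/- 1.96 se; scenario-level intervals are the mean estimate +/-
1.96 times the mean standard error, with the empirical SD of the
estimates and the RMSE against the scenario target reported alongside.

## What the simulations do and do not show

The generator reproduces the mechanisms the estimators are sensitive to —
finite-GWAS measurement error, sibling structure, genetic nurture,
assortative mating, imperfect genetic correlation — under idealized
conditions: unlinked SNPs with i.i.d. effects, no LD, no ascertainment,
no population stratification, Gaussian phenotypes, constant population
size, exactly two children per family, and no covariates. Passing
benchmarks here show the estimators behave as their theory predicts in
that regime; they do not certify performance under LD-aware weighting,
ancestry differences, or real-cohort ascertainment, and the empirical
sibling-cohort application is out of scope.

## Problem sizes

The bundled scenario runs use the study's design values (M = 5000,
GWAS sizes 2x2000 and 2x16,000, prediction samples 1000-16,000, 0.05
relatedness cutoff). Replication counts are desk-scale: 100 runs for the
small-GWAS cells, 20-40 for the large-GWAS and GREML-bearing cells (whose
per-run sampling noise is several times smaller than the asserted
tolerances), and 4-6 for the qualitative pattern checks. The kernels are
exact-equivalent between the numba and pure-numpy paths; the founder
binomial draw quantizes probabilities to 1/65536, far below sampling
noise at any simulated scale.

## Known limitations

* The GREML route holds the whole GRM and its eigendecomposition in
  memory, which is the right trade-off up to a few tens of thousands of
  individuals but not beyond.
* Under strong assortative mating the GREML estimate is biased upward by
  design (that bias is the phenomenon the PGI-RC comparison probes), so
  `reml_h2` output should not be read as an unbiased heritability there.
* The stacked 2SLS covers the just-identified two-PGI case only; more
  than two discovery samples would need a generalized stack.
* Scenario confidence intervals follow the mean-SE convention used in the
  study's tables; for a single replication the per-run interval is the
  honest object.
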