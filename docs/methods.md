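# Methods

## The model

HisCoM-PCA tests the association between a phenotype and a collection of
gene sets (pathways) in a single hierarchical GLM. The hierarchy has two
layers:

1. **SNP → gene.** The dosages of the SNPs assigned to a gene (gene body ±
   a 20 kb window by default) are centred, scaled to unit variance and
   decomposed by PCA. A small number of leading components represents the
   gene: either the first PC only (`first_pc`), or the minimal leading set
   whose cumulative variance proportion strictly exceeds 30% (`cumvar`).
2. **Gene → pathway → phenotype.** The selected PC scores `g_kti` combine
   through estimated weights `w_kti` into one latent component per pathway,
   which predicts the phenotype through a coefficient `beta_k`, alongside an
   intercept and unpenalised covariates:

   `eta_j = beta_0 + sum_k [sum_t sum_i g_ktij w_kti] beta_k + z_j' a`

   with a binomial (logit) or gaussian link. The phenotype is assumed
   independent across subjects given the predictor.

All pathways enter one joint fit, so the estimates account for gene sharing
and inter-pathway correlation rather than testing each set in isolation.
A gene belonging to several pathways contributes its PC columns to each of
those pathway blocks with pathway-specific weights.

Estimation maximises the penalized log-likelihood

`phi = sum_j log p(y_j; eta_j) - (1/2) lambda_g sum w^2 - (1/2) lambda_p sum beta^2`

The two ridge terms control multicollinearity between genes and between
pathways respectively; the intercept and covariate coefficients are never
penalised.

## The ALS estimator

`phi` is maximised by alternating least squares:

* **Pathway half-step.** With `w` fixed, the pathway scores
  `S_k = sum g w` are ordinary regressors; `(beta_0, beta, a)` solve a
  ridge GLM with penalty `lambda_p` on `beta` only.
* **Weight half-step.** With `beta` fixed, the predictor is linear in `w`
  with effective regressors `g * beta_k`; `(beta_0, w, a)` solve a ridge
  GLM with penalty `lambda_g` on `w` only.

Gaussian half-steps are closed-form solves of the penalised normal
equations; binomial half-steps use damped Newton (IRLS with step-halving on
`phi`), so the objective is non-decreasing across half-steps in both
families. During optimisation the gaussian likelihood is evaluated at unit
dispersion, which shares its maximiser with any fixed dispersion; the
residual mean square is estimated once at convergence and reported as the
fit's dispersion (the reported `penalized_loglik` uses it, matching the
profile OLS log-likelihood in the unpenalised single-block case).

Two reparameterisation details matter in practice:

* **Scale rebalancing.** The predictor sees only the product `w_k beta_k`,
  so the likelihood is flat along `(c w_k, beta_k / c)`; only the penalties
  curve that direction, and plain ALS crawls along the resulting shallow
  valley. After each weight half-step every block is rescaled with the
  `c` that minimises its penalty (leaving the predictor untouched and
  `phi` non-decreasing), after which
  `lambda_g ||w_k||^2 = lambda_p beta_k^2` per block. This cuts typical
  fits from hundreds of iterations to about five. No explicit
  unit-variance constraint is imposed on the latent components — the two
  penalties pin the scale split on their own.
* **Sign convention.** `(w_k, beta_k)` and `(-w_k, -beta_k)` are
  equivalent; after convergence the largest-|w| entry in each block is made
  positive. PCA components use the analogous largest-|loading|-positive
  rule, so the whole pipeline is bit-deterministic for a given seed.

Convergence is declared when the largest absolute parameter change over a
full iteration or the change in `phi` drops below `tol` (default `1e-5`,
cap 100 iterations — values chosen as typical for ALS/GSCA-style
estimators). Initialisation is deterministic by default: equal weights with
unit block norm (`w = 1/sqrt(P_k)`), `beta = 0`, null-model intercept; a
seeded random initialisation is available. Exact collinearity with a zero
penalty raises with advice to use `lambda > 0`.

## Inference

Significance comes from phenotype permutation: the phenotype vector is
shuffled uniformly (covariate rows stay put), the full model is refitted
from scratch with the identical configuration and deterministic
initialisation, and the observed `|beta_k|` is ranked among its permuted
replicates. Re-estimating the weights in every refit is essential —
reusing observed weights would bias the null anti-conservatively. p-values
use the add-one estimator `p = (1 + #{permuted >= observed}) / (B + 1)`,
which is positive and valid; under the null it is uniform on
`{1/(B+1), ..., 1}`, so rejection at `p <= alpha` has exact level `alpha`
whenever `alpha (B + 1)` is an integer (e.g. B = 99 at alpha = 0.05; the
simulation experiments use this rule). The statistic is the raw coefficient
magnitude rather than a studentised quantity: the permutation null
calibrates its scale, and the model does not expose a variance estimator.
Gene-level statistics are `max_i |w_kti beta_k|` over a gene's PCs within a
pathway (which reduces to the single-PC product in the `first_pc` case),
tested with the same permutation replicates. Benjamini–Hochberg q-values
are attached per table (pathway significance is conventionally read at
q < 0.1). A Freedman–Lane residual-permutation variant is available for
covariate-confounded gaussian designs; for binomial designs only plain
phenotype permutation is offered.

Permuted refits that fail to converge are counted and excluded; more than
5% failures abort the analysis.

## Penalty selection

`cv_select` scores a grid of `(lambda_g, lambda_p)` pairs (default
`{0.01, 0.1, 1, 10, 100, 1000}` per axis, log-spaced across under- to
over-penalisation) by k-fold (default 5) out-of-fold half-deviance —
the held-out negative log-likelihood, which treats both families
uniformly. Folds are a seeded shuffle, stratified by outcome for binomial
traits (a minority class smaller than k raises). Ties break toward the
heavier penalty (`lambda_g + lambda_p`, then `lambda_p`) for parsimony and
reproducibility. PC scores are computed once on all samples; cross-
validation refits only the model coefficients on training folds.

## Quality control

SNPs are removed when MAF <= 0.05 (boundary excluded), call rate < 95%, or
exact HWE p < 1e-6; samples are kept when their call rate is strictly
above 90%. Removal counts attribute each SNP to the first filter that
catches it (call rate → MAF → HWE), but the surviving set is
order-independent because all filters are evaluated on the original
matrix. The HWE test is the exact conditional test built from the stable
two-term recurrence (a chi-square variant is switchable); HWE uses all
retained samples by default, with a controls-only option. Sex-consistency
exclusions are accepted as a precomputed ID list rather than recomputed
from X-chromosome heterozygosity. Residual missing dosages are mean-imputed
per SNP — adequate upstream of PCA, which tolerates continuous dosages;
model-based genotype imputation is out of scope.

## The simulator

`simulate_dataset` emulates a mini-exome pathway-association design:
defaults of 697 individuals, 168 pathways, a 10-gene causal pathway with 9
causal genes, and a size-matched, gene-disjoint null pathway for type-I
tracking. Gene sizes (3–8 SNPs), non-causal pathway sizes (3–8 genes) and
MAFs (uniform on (0.05, 0.5]) are drawn per replicate. Within-gene LD uses
a one-parameter Gaussian copula (exchangeable latent correlation
`ld_rho = 0.3` by default, a moderate level chosen to stress the PCA
summarisation) thresholded to Hardy–Weinberg genotype frequencies; genes
are mutually independent. The continuous trait is additive in the
standardized causal dosages (one causal SNP per causal gene by default,
per-SNP effect 0.5, unit noise variance; `effect_size_for_r2` sizes
effects for a target heritability) and the binary trait is its median
split (ties to the lower class, prevalence within one sample of 1/2).
Genes are laid out 200 kb apart so the positional 20 kb mapping rule
reproduces the generator's truth table exactly.

What the generator does **not** emulate: realistic haplotype structure and
long-range LD, allele-frequency spectra with rare variants, population
stratification, relatedness, genotyping-error patterns, or gene-gene
interaction effects. Passing calibration and power checks on these
synthetic cohorts therefore demonstrates correctness of the machinery and
its operating characteristics under idealised LD — not performance on any
particular real cohort.

Experiments (`run_type1_experiment`, `run_power_experiment`) replay the
full per-replicate pipeline — per-gene PCA, PC selection, joint fit,
permutation test — tracking the null or causal pathway's p-value, with
per-replicate seeds spawned deterministically from one root seed.
Experiments fix the penalties (default `lambda_g = lambda_p = 1`) rather
than re-running cross-validation inside every replicate: permutation
validity holds for any fixed configuration, and this keeps a 200-replicate
× 100-permutation experiment to minutes. The default experiment scale in
the tests (20 pathways, B = 99, 100–200 replicates, n = 300–697) is a
deliberately scaled-down version of the full design (168 pathways,
B = 1000, 200 replicates), which remains available by passing the full
configuration.

## Numerical choices and edge cases

* Missing dosage sentinel is NaN (0 is a valid dosage).
* Counted allele for PLINK input is BIM A1, the PLINK convention; the
  orientation only flips PC signs, which the sign convention re-fixes.
* Constant SNP columns are dropped before PCA with a warning; an
  all-constant gene is dropped, and a pathway whose genes all drop is
  removed from the design (logged).
* A single-SNP gene's "PCA" is the standardized SNP itself.
* `cumvar` selection uses a strict `>` threshold (the minimal crossing
  set), and monomorphic SNPs get HWE p = 1 by convention.
* IRLS weights are floored at 1e-10; binomial step-halving allows up to 40
  halvings before accepting a zero step.
* BH q-values delegate to statsmodels' `fdr_bh`.

## Known limitations

* The permutation test is the only inference route; no asymptotic
  approximation is provided, so compute scales linearly in B.
* Mean imputation ignores LD information that model-based imputation would
  exploit.
* With `lambda_g = lambda_p = 0` the per-block scale split is
  unidentified; only the product `w beta` is meaningful (the single-block
  oracle tests check exactly that product).
* X-chromosome handling, multi-allelic sites, BGEN/VCF dosage input,
  LD pruning and relatedness filtering are out of scope; conditional /
  stepwise pathway selection is not implemented.
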