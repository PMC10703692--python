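# Methods

`txtwas` trains multivariate SNP models of transcript-isoform expression,
maps isoform- and gene-level trait associations from GWAS summary
statistics, and fine-maps correlated isoform signals. This note records the
models, the numerical choices, and what the synthetic-data studies do and do
not demonstrate.

## Model

For a gene with M isoforms measured in N samples, expression is modelled as

    Y = X B + E,        vec(E) ~ N(0, Omega^{-1} (x) I_N),

where X (N x P) holds column-standardized cis-window genotype dosages,
B (P x M) the SNP effects on each isoform, and Omega the precision matrix of
the correlated residuals. Total gene expression is treated as the sum of its
isoforms' abundances. Both X and Y are standardized to mean 0, variance 1,
so all weights live on the standardized scale.

Five estimator families compete for B:

* **mvenet** — multi-response elastic net whose L1 component is a group
  penalty on the rows of B (sklearn's multi-task elastic net). A SNP is
  selected for all isoforms or for none, which borrows strength when causal
  variants are shared across isoforms.
* **mrce** — multivariate lasso with covariance estimation: alternate an
  L1-penalized weighted regression for B given Omega (loss
  tr((Y-XB) Omega (Y-XB)')/n + lambda_B ||B||_1, solved by FISTA) with a
  graphical-lasso update of Omega on the residual covariance. Stops when the
  max-abs change in B falls below 1e-4 or after 100 outer iterations;
  non-convergence is flagged on the result, not raised.
* **joinet** — stacked generalization: per-isoform elastic nets produce
  out-of-fold predicted isoforms; a second per-isoform elastic net layer on
  the predicted matrix exploits inter-isoform correlation. The two linear
  maps collapse into one P x M coefficient matrix. The stage-2 penalty
  family is an unconstrained elastic net (non-negativity is not imposed).
* **spls** — sparse partial least squares in the active-set form: the
  dominant left singular direction of X'R (R the current residual) is
  soft-thresholded at eta times its largest loading, the surviving SNPs join
  the active set, and a dense PLS with k components is refit on the active
  predictors. (K, eta) are chosen by inner CV. Note that under a rank-1
  signal CV may legitimately keep K=2: an estimated direction carries an
  O(1/n) rotation error whose residual signal a second component recovers,
  so "one latent signal implies K=1" holds only in orthogonal designs.
* **univariate** — the per-isoform baseline: elastic net, ridge regression
  (the BLUP-in-a-mixed-model family, with the penalty — the noise-to-genetic
  variance ratio — chosen by efficient leave-one-out CV over a log-spaced
  grid rather than REML), and a sum-of-single-effects Bayesian regression
  (iterative Bayesian stepwise selection with L effects, fixed scaled prior
  variance 0.2*var(y), residual variance re-estimated each sweep, ELBO-based
  stopping at 1e-4 with a flag if the ELBO decreases). The CV-best of the
  three is kept per isoform.

## Model selection, filtering, stacking

All estimators for one gene are scored under a single shuffled 5-fold
assignment; per isoform the CV score is the squared Pearson correlation of
out-of-fold prediction with observation, adjusted as
1 - (1-R^2)(N-1)/(N-2). One method is selected per gene by the largest mean
adjusted R^2 across isoforms (a per-isoform selection mode exists behind a
flag); ties break by a fixed method order (mvenet, mrce, joinet, spls,
univariate) for reproducibility. Isoforms with CV R^2 <= 0.01 are dropped
(strict inequality survives), and a gene is testable iff one isoform
survives.

Two gene-level predictors accompany the isoform models: the usage-weighted
sum of predicted isoforms (the model-free aggregate implied by "a gene is
the sum of its isoforms"), and a stacking elastic net of observed gene
expression on the out-of-fold predicted isoforms, trained and scored on the
same folds. The univariate comparator for gene-level analysis fits the
best-of-three univariate family to total gene expression under the same
folds.

## Association testing

With individual-level GWAS genotypes, imputed expression is X w and the test
is the OLS slope z-statistic. With summary statistics, the weighted burden
statistic Z = w'z / sqrt(w' V w) is used with an LD reference V (in-sample
LD of the training panel in all simulations). Isoform p-values of one gene
combine by the Cauchy combination (ACAT): T = mean of tan((0.5 - p) pi),
p_gene = 0.5 - arctan(T)/pi, with p clipped to [1e-300, 1 - 1e-16] and the
tangent replaced by its leading term 1/(p pi) below 1e-16. Genes are
screened by Benjamini-Hochberg FDR (Bonferroni available); within screened
genes, isoforms are confirmed by Shaffer's modified sequentially rejective
Bonferroni procedure at the screening level. Because screening guarantees at
least one false null in the gene, the ordered thresholds divide alpha by
t-1, t-1, t-2, ..., 1 and rejection stops at the first failure.

The permutation test shuffles the SNP-weight vector of each tested isoform
independently (10,000 draws by default) and reports
(1 + #{|Z_perm| >= |Z_obs|}) / (1 + n_perm), never exactly zero. Weights are
permuted per isoform rather than jointly across a gene's isoforms; a joint
mode is a one-line change but per-isoform is the default because each
isoform's statistic is tested separately.

## Fine-mapping

Within a risk region (significant features within 1 Mb merge transitively),
the burden z-scores of t isoforms are modelled as z | c ~ N(0, S +
prior_var * S[:,c] S[c,:]) for a causal configuration c, with S the
LD-induced correlation of predicted expression, prior_var = 40 on the
z-score scale (the approximate non-centrality of a causal feature) and an
independent prior inclusion probability 1e-3 per isoform. All
configurations with |c| <= 3 (configurable; exhaustive for small t) plus the
null compete in the posterior; PIPs sum configuration posteriors. The
90%-credible set is the smallest PIP-descending prefix reaching 90% of the
normalized mass, ties broken by identifier. S is ridged by 1e-4 on the
diagonal if its smallest eigenvalue drops below 1e-8.

## Synthetic data

The generator reproduces the statistical structure of a cis-locus without
external reference data:

* **Genotypes.** Two latent AR(1) Gaussian haplotypes per sample are
  thresholded at the MAF quantile (MAF ~ U(0.05, 0.5) per SNP), giving
  0/1/2 counts whose latent correlation decays as rho^|j-k| (rho = 0.6 by
  default); columns are standardized. A haplotype-resampling mode reads a
  0/1 reference panel instead. Monomorphic columns are redrawn (bounded).
* **Effects.** Each isoform has c = ceil(p_causal P) causal SNPs;
  round-half-up p_shared * c of them come from a common shared set, the rest
  are isoform-private. Effect values are i.i.d. standard normal in either
  case — isoforms share causal variants, not effect sizes — which keeps the
  emergent heritability of the summed gene near the per-isoform target
  (shared effect *values* would instead inflate gene heritability several-
  fold, because independent noise averages across isoforms while a coherent
  genetic part does not).
* **Expression.** Per isoform, expression = genetic + shared + noise, each
  component rescaled to hit its variance target (h_g2, sigma_h,
  sigma_e2 = 1 - sigma_h - h_g2) exactly in-sample. The shared non-cis term
  is one latent N-vector times per-isoform Gaussian loadings. Gene
  expression is the usage-weighted sum of standardized isoforms (equal usage
  by default), standardized again; usage weights encode the "effect isoform
  carries fraction p_g of the gene" scenarios.
* **Traits.** A fresh GWAS panel with the same MAF/LD is drawn; the genetic
  score is built from the true standardized-scale effects under one of four
  scenarios (gene-only, one effect isoform, two isoforms with effect ratio
  p_e, null), rescaled so its variance share equals h_t2; summary statistics
  are per-SNP marginal OLS z-scores on standardized dosages, no covariates.

What this emulates: realistic LD decay, sparse and shared isoQTL
architectures, correlated non-genetic structure, and the null and causal
GWAS regimes. What it does not: real LD block structure from reference
haplotypes, allele-frequency/effect-size coupling, population structure,
trans effects, covariates, or quantification uncertainty from inferential
replicates — so passing tests show correctness of the statistical machinery
under the assumed generative model, not performance on real cohorts.

## Benchmark problem sizes

The simulation studies run at desk scale, chosen once as realistic
miniatures: loci carry 100 SNPs (150 for the prediction study, 500 where a
causal-entry correlation needs several causal SNPs), training panels have
n = 500, and the null-calibration study tests ~5,000 simulated GWAS panels
of 2,000-5,000 samples (the null distribution of marginal z-scores does not
depend on the GWAS sample size; power studies use larger panels). Large
sweeps use reduced hyperparameter grids (10 penalties, one mixing value,
3 inner folds) and select per gene among the multivariate elastic net,
MRCE at a fixed data-driven penalty, sparse PLS, and a univariate portfolio
restricted to its elastic-net member; the full grids and the full
best-of-three univariate fitter remain the defaults everywhere else,
including the gene-level univariate comparator.

## Known limitations

* The sparsity grid p_causal in {0.001, 0.01} collapses at desk-scale locus
  sizes (both give one causal SNP below 200 SNPs); the prediction benchmark
  therefore uses 150-SNP loci where the grid maps to c in {1, 2}. Gains from
  isoform-level modelling in fully shared architectures require several
  causal SNPs per isoform and are structurally near zero when c = 1 (every
  method's prediction is then proportional to the same dosage column).
* The precision matrix from MRCE is reported but not propagated into
  association testing.
* Fine-mapping enumerates configurations exhaustively; t above ~12 with
  max_causal = t is not intended.
* The empirical-Bayes test-statistic inflation analysis and
  conditional/joint multi-gene analyses are out of scope.
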