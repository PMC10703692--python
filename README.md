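# txtwas

Isoform-level transcriptome-wide association analysis: multivariate SNP
models of transcript-isoform expression, gene- and isoform-level trait
mapping from GWAS summary statistics, and Bayesian fine-mapping of
correlated isoform signals.

## Why isoform-level?

Standard TWAS imputes *total gene* expression from cis-window SNPs and tests
its association with a trait. Many genes express several transcript
isoforms whose genetic regulation differs; when only one isoform drives a
trait, the gene-level signal is diluted and the association can be missed.
`txtwas` instead models all isoforms of a gene jointly,

    Y = X B + E,    vec(E) ~ N(0, Omega^{-1} (x) I_N),

with Y the N x M matrix of (standardized) isoform expression, X the N x P
standardized cis-genotypes, and B the P x M SNP-effect matrix, exploiting
the correlation between isoforms to improve each isoform's prediction. Five
estimator families compete per gene under shared 5-fold cross-validation —
a multi-task (group-penalty) elastic net, multivariate lasso with
covariance estimation, stacked per-isoform elastic nets, sparse partial
least squares, and a per-isoform univariate baseline (elastic net /
ridge-BLUP / sum-of-single-effects regression) — and the method with the
largest mean CV adjusted R² wins. Models with CV R² > 0.01 are testable.

Trait mapping uses the weighted burden statistic
`Z = w'z / sqrt(w'Vw)` from GWAS z-scores z and an LD reference V, a
stepwise ladder — isoform p-values aggregated per gene by the Cauchy
combination test (ACAT), Benjamini–Hochberg screening across genes, then
Shaffer's sequentially rejective confirmation within screened genes — and a
conservative permutation test that shuffles SNP weights. At significant
loci, a Bayesian fine-mapper assigns posterior inclusion probabilities to
correlated isoforms and reports 90% credible sets.

A full synthetic-locus generator (AR(1)-LD genotypes, controlled isoform
heritability/sharing, GWAS traits under gene-level, one-isoform,
two-isoform and null scenarios) makes every stage testable end to end with
no external data.

## Worked example

```python
import numpy as np
from txtwas import (SimConfig, TraitConfig, simulate_locus, simulate_trait,
                    IsoformImputationModel, TraitAssociationScan, FitterConfig)

cfg = SimConfig(n_train=300, p_snps=60, m_isoforms=3, p_causal=0.05,
                h_g2=0.3, sigma_h=0.1, seed=7)
locus = simulate_locus(cfg)

res = IsoformImputationModel.from_locus(locus).fit(
    methods=["mvenet", "univariate"], cfg=FitterConfig.fast(7))
print(res.summary())

_, gwas = simulate_trait(locus, TraitConfig(scenario="one_isoform",
                                            h_t2=0.2, seed=1), n_gwas=5000)
scan = TraitAssociationScan([res.filter().to_weight_model()], gwas,
                            locus.genotypes.ld()).fit(n_perm=1000)
print(scan.summary())
```

prints

```
Isoform imputation results -- gene gene1
  samples: 300  SNPs: 60  isoforms: 3
  selected method: mvenet

  isoform      cv_adj_r2
  iso1            0.2241
  iso2            0.2754
  iso3            0.2261

  stacked gene CV adj R2: 0.2652
  TWAS baseline (susie) gene CV adj R2: 0.2779
Trait association scan: 1 genes, 3 isoforms
  screened genes (adjusted ACAT p < 0.05): 1
  confirmed isoforms (within-gene FWER): 3
```

The CV adjusted R² values are the out-of-fold squared correlation between
observed and SNP-predicted expression for each isoform (all well above the
0.01 testability cutoff at this simulated heritability of 0.3). The scan
then finds the gene's ACAT-combined p-value significant after FDR
adjustment and confirms all three isoforms at the within-gene family-wise
error level — expected here, because the simulated trait is driven by an
isoform whose causal SNPs are shared across all isoforms of the gene.

A command-line interface chains the same stages on files
(`txtwas simulate / train / associate / finemap / benchmark`); see
`txtwas --help`. The model and all defaults are documented in
`docs/methods.md`.

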