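# gspanel

Genomic prediction with SNP panel selection strategies, built for
aquaculture breeding programs (the motivating case is caviar yield, caviar
color and body weight in farmed sturgeon) but applicable to any diploid
population with SNP genotypes and quantitative phenotypes.

Whole-genome sequencing yields millions of markers, most of them redundant
or uninformative for any one trait. Breeding programs therefore want small
SNP panels that preserve — or improve — the accuracy of genomic estimated
breeding values (GEBVs). `gspanel` implements the whole experiment needed
to answer *which* panel to build:

* **QC & I/O** — VCF and PLINK-1 binary readers/writers; call-rate, MAF and
  exact Hardy–Weinberg filters; mean-dosage imputation.
* **Population structure** — VanRaden genomic relationship matrix
  `G = ZZ′ / 2Σpⱼ(1−pⱼ)`, PCA, windowed LD `r²`, LD pruning.
* **GWAS** — single-marker linear mixed model
  `y = 1μ + Pα + Zg + xb + e`, with top principal components as fixed
  effects and a polygenic term `g ~ N(0, Gσ²ₐ)`; REML variance components by
  spectral transform; EMMAX-style generalized-least-squares scan with Wald
  tests; per-SNP variance explained
  `PVE = 2β̂²pq / (2β̂²pq + se(β̂)²·2N·pq)`.
* **Panels** — three selection strategies at exact target densities:
  top-N by GWAS p-value, LD pruning with threshold search, and seeded
  random sampling as a control.
* **Prediction models** — GBLUP via AI-REML and the mixed-model equations;
  BayesA, BayesB, BayesCπ and Bayesian Lasso as single-site Gibbs samplers
  (numba-compiled, 18,000 cycles / 3,000 burn-in by default); grid-searched
  SVR, random forest, kernel ridge and XGBoost regressors.
* **Evaluation** — repeated 5-fold cross-validation (default 20 repeats)
  reporting accuracy (Pearson correlation of phenotype and GEBV), bias
  (slope of phenotype-on-GEBV regression), MSE and MAE, with strict
  training/validation separation for every trait-aware stage.

A synthetic-data module generates populations with the statistical
structure these analyses assume — full-sib families, tunable block-wise LD,
configurable MAF spectrum, and additive traits with chosen QTL count and
heritability — so the whole pipeline is testable end to end without access
to proprietary breeding data.

## Worked example

Simulate a 500-individual, 2000-SNP population from 50 full-sib families
with a 40-QTL, h²=0.4 trait, then compare 200-SNP panels from all three
strategies against full-marker GBLUP under 2×5-fold cross-validation:

```sh
cat > ex.yaml <<'EOF'
simulate:
  n_individuals: 500
  n_chromosomes: 5
  snps_per_chrom: 400
  n_families: 50
  n_qtl: 40
  h2: 0.4
cv:
  n_folds: 5
  n_repeats: 2
panels:
  strategies: [gwas, ld, random]
  densities: [200]
models:
  names: [GBLUP]
gwas:
  n_pcs: 5
EOF
gspanel simulate --config ex.yaml --seed 1 --out demo
gspanel crossval --geno demo/genotypes --pheno demo/phenotypes.tsv \
    --config ex.yaml --seed 1 --out demo_cv
```

which prints

```
trait strategy  density model  accuracy_mean  accuracy_sd  bias_mean  bias_sd  mse_mean  mae_mean  n_repeats
trait     full     2000 GBLUP       0.373664     0.011859   0.999500 0.011763  0.003034  0.043618          2
trait     gwas      200 GBLUP       0.424954     0.014954   0.658154 0.010661  0.003056  0.043623          2
trait       ld      200 GBLUP       0.274138     0.025071   1.033483 0.028461  0.003249  0.045273          2
trait   random      200 GBLUP       0.307973     0.002833   0.997053 0.024405  0.003163  0.044456          2
```

For this sparse trait the trait-targeted 200-SNP GWAS panel predicts more
accurately (0.42) than GBLUP on all 2000 markers (0.37), while LD-pruned
and random panels of the same size lose accuracy — the pattern that
motivates panel selection in the first place. The GWAS panel's bias slope
(0.66 < 1) shows its GEBVs are over-dispersed, a known cost of selecting
markers on the training data's own association signal. Accuracy SDs come
from the repeat-to-repeat spread.

The same stages are available as library functions (`gspanel.simulate_*`,
`apply_qc`, `compute_grm`, `assoc_scan`, `select_*`, `aireml`,
`gblup_predict`, `bayes_sample`, `tune_and_fit`, `run_experiment`) and as
individual subcommands (`simulate`, `qc`, `grm`, `pca`, `ld`, `gwas`,
`select`, `predict`, `crossval`, `report`), each writing a JSON manifest
that makes its outputs reproducible from the recorded seed.

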