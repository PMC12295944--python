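# Methods

This note documents the statistical machinery in `gspanel`, the defaults
it ships with, and what the synthetic populations used by the tests can
and cannot demonstrate.

## Synthetic populations

`simdata` emulates a farmed-sturgeon-like breeding population; it is a
statistical emulator, not a coalescent or forward genetic simulator.

**Genotypes.** Haplotypes are drawn per chromosome from a first-order
copying chain: locus *j* reuses the latent uniform variable of locus
*j−1* with probability `ld_rho`, otherwise draws a fresh one, and the
allele is the indicator `u < p_j` with `p_j` drawn from `maf_range`
(minor/major orientation randomized). This yields exact marginal allele
frequencies and adjacent-marker dosage r² that increases monotonically
with `ld_rho` (0 ⇒ independent loci). With `n_families > 0`, parent pairs
are simulated from the chain and each offspring receives one recombinant
gamete per parent, with a fixed per-interval haplotype-switch probability
of 0.01; sample IDs encode the family. Missing genotypes are masked in at
`missing_rate` after the population is formed.

**Traits.** `n_qtl` variants are drawn uniformly, effects are standard
normal, and the genetic and residual components are rescaled so the
realized sample heritability equals `h2` exactly before an affine map to
`trait_mean` and `trait_cv` (CV in percent; the default scale,
mean 0.193 / CV 29.4%, is a caviar-yield-like ratio trait). True breeding
values are returned on the phenotype scale for recovery tests. `h2`
defaults to 0.3 — heritabilities for these traits are not established, so
it is an explicit free parameter. The 1–4 ordinal color-score trait is
treated as continuous throughout, matching how such scores are analyzed
with these models in practice.

**What passing tests do not show.** The generator produces block-wise LD
with geometric decay, a single unstructured generation, no genotyping
error, no selection, and additive-only traits. Results on it validate the
*estimators* (calibration, recovery, orderings); they do not predict
absolute accuracies on real data, which depend on LD structure,
family composition and genetic architecture the emulator only sketches.

## QC and I/O

Variants are filtered by call rate ≥ 0.90, then MAF ≥ 0.05 (the boundary
value survives, since the exclusion rule is "less than 0.05"), then exact
Hardy–Weinberg p ≥ 1e-7, with per-criterion removal counts attributed in
that order (the order is a package decision; common practice varies and
rarely documents it). The HWE test is the conditional exact test summing
the probabilities of heterozygote counts no more probable than the one
observed, computed by the mode-anchored two-sided recurrence; the test
suite checks it exhaustively against direct enumeration for all genotype
tables with up to 60 individuals.

Missing dosages are filled with the per-variant observed mean. This is a
deliberate, documented simplification: phasing/LD-aware imputation is a
separate problem, and the synthetic data controls missingness. Mean
imputation preserves allele frequencies exactly but attenuates LD at
imputed entries; with the low missingness used here the effect is
negligible.

Coordinates are 1-based throughout (VCF/PLINK convention). PLINK-1 .bed
is SNP-major with A1 = ALT, so the 2-bit codes map to ALT dosage
{2, missing, 1, 0}; the magic bytes `6c 1b 01` are enforced on read.

## Population structure and LD

The GRM is VanRaden's first method on imputed dosages, monomorphic
markers excluded. PCA scores are eigenvectors of G scaled by √λ. LD r² is
the squared Pearson correlation of dosage vectors (composite LD, the
estimator PLINK applies to unphased genotypes); windows are counted in
SNPs (default 100, step 25), a choice the package fixes because kb-based
windows add a unit dependency without changing anything at simulated
marker spacing.

LD pruning is greedy and windowed: the currently highest-r² pair above
threshold loses its lower-MAF member (MAF tie: the later position is
dropped), repeated until no within-window pair exceeds the threshold.
The keep-rule is a determinism decision; the survivors satisfy the
postcondition by construction and are verified against a brute-force
all-pairs oracle in tests. Default threshold 0.2 — the conventional
redundancy cutoff for dense data.

## Mixed-model GWAS

The scan model is `y = 1μ + Pα + Zg + xb + e` with the top `n_pcs`
(default 10) principal components as fixed effects, `g ~ N(0, Gσ²ₐ)`,
`e ~ N(0, Iσ²ₑ)`. Variance components are estimated once under the null
by REML on the spectral transform of G (one eigendecomposition, then a
bounded 1-D optimization over log(σ²ₑ/σ²ₐ)), after which each marker is
tested by generalized least squares with the null covariance held fixed —
the EMMAX/GRAMMAR approximation. Exact per-marker variance re-estimation
(as GEMMA does) changes little at these scales and costs an optimization
per marker; the approximation is the default by design. The Wald
statistic `(β̂/se)²` is referred to χ²₁; markers collinear with the
covariates are flagged and given p = 1. Under a null trait the scan's
p-values are uniform (KS-checked) and type-I error at α = 0.01 falls in
[0.005, 0.02] in the validation suite.

Per-SNP variance explained uses the sampling-variance-corrected form
`PVE = 2β̂²pq / (2β̂²pq + se(β̂)²·2N·pq)`. Panel-level PVE, where
reported, is the sum of per-SNP values over the panel — a labeled
package decision, since joint refitting would give a different (smaller)
number in the presence of LD.

## Panel construction

All three strategies return exactly-density, duplicate-free,
position-sorted panels:

* **gwas** — smallest p first, ties broken by (chromosome, position);
* **ld** — binary search over the pruning threshold for the tightest
  value whose survivor set still reaches the density, then uniform
  positional thinning to the exact count (recorded in the provenance);
* **random** — seeded uniform sampling, the control arm.

Because top-N GWAS selection sees phenotypes, the CV harness defaults to
`within_fold` leakage mode: the scan is refit on the training samples of
every fold. A `whole_data` mode (one scan on everything, panels fixed
across folds) exists to mimic pipelines that select markers before
validation; reports record which mode produced them. Whether published
analyses of this design refit per fold is typically ambiguous, which is
exactly why both modes are exposed.

## GBLUP and AI-REML

`aireml` estimates (σ²ₐ, σ²ₑ) for `y = 1μ + g + e` by average-information
REML in the eigenbasis of G (every iteration O(n)): analytic score and AI
matrix, step-halving when an AI proposal leaves the parameter space or
degrades the likelihood, an EM-REML fallback step when halving fails, and
an explicit boundary close-out (σ²ₐ pinned to 0 with the residual closed
in one step) when the score still points outward at σ²ₐ < 1e-3·var(y) —
EM alone creeps toward such boundaries geometrically and would never meet
the 1e-6 log-likelihood tolerance within the 100-iteration cap.
Convergence tolerance 1e-6; G gets a 1e-8 diagonal jitter.

`gblup_predict` solves `(G_tt + λI)a = y_train − μ` with
λ = σ²ₑ/σ²ₐ and the GLS intercept, then projects
`GEBV = G[:, train]·a` for every individual. With `G = ZZ′/c` this
reproduces marker-effect ridge BLUP with λ_m = cλ exactly (validated to
1e-6), and σ²ₐ = 0 yields the complete-shrinkage limit (all GEBVs zero).

## Bayesian alphabet

All four marker-effect models share `y = 1μ + Σ Zᵢgᵢ + e` on
training-mean-centered dosages and run as single-site Gibbs samplers in a
single numba kernel; chains are bit-reproducible for a fixed seed.
Default 18,000 cycles, 3,000 burn-in, thinning 10 (memory bound;
posterior means are unaffected in expectation).

Priors:

* **BayesA** — gᵢ ~ N(0, σ²gᵢ), σ²gᵢ ~ scaled-inv-χ²(ν, S);
* **BayesB** — as BayesA with a fixed zero mass π = 0.95; inclusion
  indicators are sampled from the marginal likelihood with the effect
  integrated out;
* **BayesCπ** — common slab variance, π sampled (uniform prior ⇒ Beta
  conditional), slab variance given a scaled-inv-χ² hyperprior;
* **Bayesian Lasso** — Park–Casella: gᵢ ~ N(0, σ²ₑτᵢ²),
  τᵢ² exponential(λ²/2), 1/τᵢ² updated by its inverse-Gaussian
  conditional and λ² by its Gamma conditional (shape 1.0; rate set so the
  prior mean of λ² matches the REML-derived initialization).

ν = 4.2, and S is solved so the prior expected genetic variance matches
an AI-REML pre-estimate on the same markers:
S = σ̂²ₐ(ν−2) / (ν(1−π)c) with c = Σⱼ var(Zⱼ). These hyperparameter
choices are implementation defaults — the literature ties (ν, S) to the
trait's genetic architecture without giving values. σ²ₑ gets a weak
scaled-inv-χ²(4, ·) prior centered on the same pre-estimate. The sampler
exposes `fixed_sigma_e2` / `fixed_sigma_g2` validation hooks so the m = 1
conditional posterior can be compared against the closed-form ridge
estimate, which the test suite does to within 3 batch-means Monte-Carlo
standard errors at 15,000 saved draws.

Marker-effect samplers refuse inputs above 50,000 markers: at WGS scale
the per-cycle cost and chain length make them impractical, which is
precisely why panel selection exists; the full-marker baseline is GBLUP.

## Machine-learning models

SVR (RBF), random forest, kernel ridge (RBF) and XGBoost are tuned by
exhaustive grid search scored with mean Pearson correlation under
repeated 5-fold CV inside the training set (2 repeats by default), then
refit on the full training data. Default grids: SVR C ∈ {0.1, 1, 10},
γ ∈ {scale, 0.01}; RF trees ∈ {200, 500}, max-features ∈ {√m, 0.3}; KRR
α ∈ {0.1, 1, 10}, γ ∈ {1e-4, 1e-3}; XGB depth ∈ {3, 6}, η ∈ {0.05, 0.1},
rounds ∈ {200, 500}. All grids are caller-overridable; the tuning
criterion matches the evaluation metric on purpose. Everything is seeded,
so chosen hyperparameters and predictions are deterministic.

## Cross-validation harness

`make_folds` produces seeded partitions whose sizes differ by at most one
(971 individuals ⇒ 195/194/194/194/194); folds are plain random — family-
stratified CV would answer a different (also interesting) question and is
deliberately not the default. Metrics per validation fold: accuracy
= Pearson(y, GEBV) (not rescaled by √h²), bias = cov(y, ĝ)/var(ĝ)
(1 = unbiased), MSE and MAE of the GEBV as a phenotype predictor.
Constant GEBVs (e.g. a training fold whose REML estimate hits the σ²ₐ = 0
boundary) leave accuracy/bias undefined rather than fabricated; failed
fold-arms are flagged and excluded from summaries with an explicit count,
so a multi-hour factorial run survives isolated failures. The summary
aggregates fold means per repeat and reports mean ± SD over repeats.

## Sizes used by the validation suite

Statistical checks run at desk scale, chosen to keep Monte-Carlo error
well inside the asserted margins: REML recovery at n = 800, m = 2000 over
20 replicates; null-scan calibration over 5,000 markers; panel-strategy
comparisons at n = 500, m = 5,000 with 1,000-SNP panels over 10 seeded
experiments; model-architecture comparisons at n = 400 with shortened
chains (4,000 cycles / 1,000 burn-in) — posterior means for these
well-mixing regressions stabilize far earlier than the conservative
18,000-cycle default. `scripts/acceptance.py` re-runs the same
computations from a caller-supplied seed.

## Known limitations

* Mean-dosage imputation in place of LD-aware imputation (documented
  deviation; adequate for low, random missingness only).
* EMMAX-style fixed variance components in the scan slightly deflate test
  statistics for markers with very large effects.
* The LD panel's threshold search assumes survivor count is monotone in
  the threshold, which greedy windowed pruning satisfies in practice but
  does not guarantee in pathological LD configurations.
* No dominance or epistasis terms; no multi-trait models; no polyploid
  dosages (the segmental tetraploidy of real sturgeon genomes is handled
  upstream by diploidized calling and is out of scope here).
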