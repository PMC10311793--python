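# Methods

This note documents the models, algorithms, defaults, and numerical choices
implemented in `imagene`, and what the synthetic-data tests do and do not
establish about real data.

## The pipeline

The package assumes data are generated genotype → brain structure → disease,
and reverses that chain for analysis: a classifier maps imaging to diagnosis
purely to *construct* disease-relevant imaging phenotypes; a multivariate
Bayesian regression then maps genotype to those phenotypes, where
interpretability (posterior uncertainty, credible-interval selection) is
actually needed.  The three stages are independent and replaceable.

## Feature schema

The default processed-image table has 1860 columns: `aseg` (45 subcortical
regions) and `wmparc` (70 white-matter regions) each with six normalized-T1
intensity statistics (volume, mean, sd, min, max, range — "range" is stored
as its own column, not recomputed from max − min), plus the
Desikan-Killiany-Tourville (62 regions) and Desikan-Killiany (68 regions)
cortical atlases each with nine surface statistics (vertex count, surface
area, GM volume, thickness mean/sd, mean/Gaussian curvature, folding and
curvature indices).  Region *names* are site-specific and configurable;
only counts and statistic sets are fixed.  Matrices are features × subjects
internally, matching the regression notation X = [x₁ … x<sub>n</sub>].

## Neural-network classifier (feature extraction)

`NeuralNetClassifier` is a fully connected softmax classifier trained
full-batch by Adagrad.  Defaults: one hidden layer of 35 units, learning
rate 0.01, learning-rate decay 0, 350 epochs, summed multinomial
negative-log-likelihood loss, training restricted to NC/AD.  Choices the
reference configuration leaves open, resolved here as package defaults:

* **Hidden activation**: ReLU (modern default; monotone, cheap), configurable
  to tanh/identity.
* **Input standardization**: per-feature z-scoring with training-set
  statistics.  FreeSurfer-style features span orders of magnitude (vertex
  counts vs curvatures); unscaled inputs make first-order training unstable.
* **Biases** in every layer (the multi-class logistic analogy of the output
  layer implies an intercept).
* **Full-batch gradients** (no minibatch size is part of the reference
  configuration); with a fixed seed for initialization this makes training
  bit-reproducible.
* **Extracted features are post-activation** penultimate values (the layer's
  "neurons"); pre-activation export is available behind a flag.

Gradients are verified against central finite differences (1e-5 relative),
and the 0-hidden-layer configuration (convex softmax regression) is checked
for monotone loss decay.

## Covariate adjustment and screening

Each feature is independently regressed (OLS, intercept + age, sex,
education, APOE as ε4-dosage by default, total intracranial volume) and
replaced by its residuals.  The *adjusted* features feed both the screen and
the regression model, keeping all genetic stages consistent.  The screen fits
a simple linear regression of every adjusted feature on every SNP dosage,
takes the two-sided slope t-test p-value, ranks SNPs by their minimum
p-value across features (ties broken by SNP identifier for reproducibility),
and keeps the top k = 100.  Monomorphic SNPs get p = 1 with a warning.  No
multiplicity correction is applied: the screen orders SNPs; the multivariate
model arbitrates selection.

## Bayesian group-sparse multi-task regression

Likelihood x<sub>ℓ</sub> | W, σ² ~ N<sub>C</sub>(Wᵀg<sub>ℓ</sub>, σ²I) with
the product-multivariate-Laplace prior per gene block W^(q):

p(W^(q)) ∝ exp{−(λ₁/σ)‖W^(q)‖_F} ∏_{i∈π_q} exp{−(λ₂/σ)‖wⁱ‖₂}.

### Gibbs sampler

The prior is augmented with one latent scale τ²_q per gene and ω²_i per SNP.
The augmented joint is assembled from *unnormalized* Gaussian kernels — each
penalty contributes exp(−‖·‖²/(2σ²·scale)) with t^{−1/2}e^{−λ²t/2} mixing —
under which each latent integrates out in closed form
(∫ t^{−1/2} e^{−a/t−bt} dt = √(π/b) e^{−2√(ab)}) to exactly the Laplace
factor above.  (The superficially similar hierarchy with *normalized*
Gaussians and Gamma((m_qC+1)/2) mixing does **not** marginalize to this
prior; the distinction matters when validating the sampler.)  Full
conditionals:

* columns of W jointly Gaussian with shared precision (GGᵀ + D⁻¹)/σ²,
  D = diag((1/τ²_{q(i)} + 1/ω²_i)⁻¹), drawn via one Cholesky factorization
  per sweep (the factor is reused for all C columns and for the mean solve);
* 1/τ²_q ~ inverse-Gaussian(λ₁σ/‖W^(q)‖_F, λ₁²) and
  1/ω²_i ~ inverse-Gaussian(λ₂σ/‖wⁱ‖₂, λ₂²) (numpy `Generator.wald`);
  when a block/row norm falls below 1e-10 the inverse-Gaussian mean is
  capped at 1e10;
* σ² ~ inverse-gamma(shape (nC+SC)/2 (+a), rate ½‖X−WᵀG‖²_F + ½Σᵢ‖wⁱ‖²/dᵢ (+b)).

σ² carries an improper 1/σ² prior by default; a proper inverse-gamma(a, b)
prior is available and is used by the prior-preservation test, which needs a
proper joint.  Initialization is deterministic: W from unit-penalty ridge,
σ² from its residual variance, scales at 1.  Defaults: 10 000 sweeps, 5 000
burn-in.  Basic diagnostics (effective sample size via arviz, trace
summaries) are available on the sample store.

### Validation of the sampler

Two independent oracles in `imagene.validation`:

1. **Quadrature**: on S=2, C=1, n=8 with singleton groups, the exact
   (w₁, w₂, σ²) posterior (using the closed-form Laplace marginal above) is
   integrated on a 161×161×101 grid; the chain's posterior means agree within
   0.02 (measured ≈ 0.002 at 50 000 draws).
2. **Marginal-conditional ("getting it right") simulation**: alternating
   X ~ p(X|state) with single Gibbs sweeps leaves the prior invariant iff
   every conditional is consistent with the joint; with inverse-gamma(3, 2)
   on σ², the running means of W (0) and σ² (b/(a−1) = 1 — exact, since the
   σ^{−SC} prior normalization cancels when W is integrated) are checked
   within 3 effective-sample-size-adjusted Monte-Carlo standard errors over
   5 000 sweeps (after a 200-sweep warm-up from an approximate prior draw).

### Summaries, ranking and selection

Posterior mean, sd (n−1 denominator), standard score mean/max(sd, 1e-12),
and equal-tailed credible intervals from empirical quantiles.  The reference
analysis ranks SNPs "by the posterior standard score" without specifying how
C per-feature scores collapse to one per SNP; this package uses
**max |score| across features** and always reports the full per-feature
score matrix so users can re-rank.  A SNP is *selected* when at least one
feature's 95% interval excludes zero; the per-SNP count of such features is
reported.

### Penalty selection

K-fold (default 5) cross-validation over a (λ₁, λ₂) grid (default
{0.5, 1, 2, 5, 10}², a placeholder — fully user-configurable): short chains
(1 000/500) on training folds, held-out prediction by the posterior-mean
plug-in X̂ = W̄ᵀG, mean-squared-error objective, ties to the smaller λ₁+λ₂.

## Synthetic cohorts

The generator emulates: binomial(2, p) dosages with p uniform on a MAF range
(default 0.05–0.5); SNP→gene groups as contiguous near-equal blocks (real
gene sizes vary; contiguity makes counting oracles trivial); gene-sparse
coefficients (N(0, effect²) rows in causal genes, exact zeros elsewhere);
features X = WᵀG + N(0, noise²); covariates drawn *independently* of
genotype (so adjustment is a no-op in expectation — a testable property;
real covariates correlate with the phenotype); and labels from a logistic
model on a standardized score over the leading features, with a middle band
for MCI (the reference analysis never models MCI, only excludes it from
training) or an exact-composition mode that reproduces 145/256/142.

Defaults mirror the study conditions: 543 subjects, several hundred SNPs in
50 genes, 1860 features, effect size 0.5, noise sd 1.  Not emulated — hence
not established by any passing test here: linkage disequilibrium and the
multicollinearity it causes, population structure, genotyping missingness,
non-Gaussian feature distributions, and covariate–phenotype confounding.

## Evaluation harness

Repeated random sub-sampling validation: per split, 200 random training
subjects, the remainder (cohort − 200; 87 for a 287-subject NC/AD cohort —
the historical 200 + 73 split corresponds to a 273-subject cohort, so the
test size is left implicit rather than hard-coded) as test; an unpenalized
logistic model per feature set (iteration-capped, with a small-ridge
fallback on separation, logged); mean and sd of the 50 per-split accuracies
per set and a two-sided *paired* t-test on the per-split differences
(pairing uses the shared splits; identical sets report p = 1).  Splits
missing a class on either side are redrawn (≤ 100 attempts, logged).

## Null calibration and winner's curse

Under a global null, the screen's min-p follows the minimum-of-C-uniforms
law exactly (slope t-tests under Gaussian noise), verified by
Kolmogorov–Smirnov.  Because the screen *selects* the most-associated SNPs,
fixed small penalties downstream yield credible intervals that exclude zero
more often than nominal (~11–15% at λ = 1 in our null experiments — a
winner's curse).  Running the pipeline as specified, with λ cross-validation
before the regression, removes this: CV picks heavy shrinkage on null data
and the selection rate falls to ~1%.  Screened-then-modeled inference should
therefore always use the CV stage (or externally chosen, adequately large
penalties).

## Problem sizes used in tests

The automated checks run at reduced scale chosen to make Monte-Carlo bounds
sharp while keeping the suite quick: quadrature comparison at 50k draws;
getting-it-right at 5k sweeps (S=4, C=2, n=6); recovery at n=200, S=40,
Q=10 over 10 seeds; null calibration at S=200, n=500 (screen) and S=40,
n=200 (selection); end-to-end pipeline tests at n≈200–300, S≈150–500 with
shortened chains.  All are ordinary parameters of the public API.
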