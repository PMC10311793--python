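# imagene

An imaging-genetics analysis pipeline for relating genetic variants (SNPs) to
brain structure in a way that is informative about disease — built around the
idea that a classifier trained to predict diagnosis from neuroimaging yields
*disease-relevant imaging phenotypes* for genetic association.

The pipeline has three stages:

1. **Feature extraction.** A fully connected neural-network classifier `f` is
   trained to separate normal controls (NC) from Alzheimer's disease (AD)
   subjects using a processed imaging table **v\*** (by default the
   1860-feature FreeSurfer layout: `aseg` 45 regions × 6 intensity statistics,
   `wmparc` 70 × 6, Desikan-Killiany-Tourville 62 × 9 surface statistics,
   Desikan-Killiany 68 × 9).  The post-activation values of the second-to-last
   layer, **x**<sub>L−1</sub> (35 by default), are the extracted features —
   "one logistic regression away" from diagnosis, since the output layer is
   the softmax `o = softmax(B x_{L-1})` trained by multinomial negative
   log-likelihood.  Subjects with mild cognitive impairment (MCI) are excluded
   from training but receive extracted features.
2. **Screening.** Features are residualized on subject covariates (age, sex,
   education, APOE, total intracranial volume) by OLS; SNPs are restricted to
   a candidate panel, then ranked by the smallest slope p-value across all
   per-(SNP, feature) simple linear regressions, keeping the top k = 100.
3. **Bayesian group-sparse multi-task regression.**  With G the S × n dosage
   matrix and X the C × n adjusted features, the model is

   x<sub>ℓ</sub> | W, σ² ~ N<sub>C</sub>(Wᵀ g<sub>ℓ</sub>, σ² I<sub>C</sub>),  p(W<sup>(q)</sup>) ∝ exp{−(λ₁/σ)‖W<sup>(q)</sup>‖<sub>F</sub>} ∏<sub>i∈π<sub>q</sub></sub> exp{−(λ₂/σ)‖w<sup>i</sup>‖₂},

   the Bayesian analogue of the group-sparse multi-task objective
   ‖WᵀG − X‖²<sub>F</sub> + γ₁‖W‖<sub>G2,1</sub> + γ₂‖W‖<sub>2,1</sub>, with
   sparsity at the gene level (groups π<sub>q</sub>) and the SNP level
   (rows w<sup>i</sup>) simultaneously.  A Gaussian-scale-mixture Gibbs
   sampler (written from scratch; see `docs/methods.md`) provides posterior
   means, standard deviations, the **posterior standard score** mean/sd used
   to rank SNPs, and 95% credible intervals whose exclusion of zero defines
   SNP selection.  λ₁, λ₂ are chosen by K-fold cross-validation on held-out
   prediction error.

A synthetic-cohort generator reproduces the statistical structure the
pipeline assumes (binomial dosages with gene grouping, gene-sparse true
coefficients, Gaussian features X = WᵀG + E, independent covariates, and
diagnosis labels driven by a feature subset, including the study composition
145 NC / 256 MCI / 142 AD = 543 with 287 NC+AD), so everything runs and is
tested fully offline.

## Worked example

```python
import numpy as np
from imagene import (SyntheticConfig, generate_cohort, run_pipeline_data,
                     TrainConfig, BGSMTRConfig, evaluate_feature_sets, EvalConfig)
from imagene.synthetic import DEFAULT_COMPOSITION

cfg = SyntheticConfig(n_subjects=543, n_snps=500, n_genes=50, n_features=200,
                      n_causal_genes=5, effect_size=0.5, noise_sd=1.0,
                      n_disease_features=10, label_counts=DEFAULT_COMPOSITION, seed=7)
cohort = generate_cohort(cfg)

result = run_pipeline_data(
    cohort.genotype, cohort.partition, cohort.features,
    cohort.covariates, cohort.labels, screen_k=100,
    train_config=TrainConfig(),            # 35 hidden units, Adagrad 0.01, 350 epochs
    bgsmtr_config=BGSMTRConfig(n_iter=2000, burn_in=1000, seed=7),
)
```

This trains the classifier on the 287 NC/AD subjects, extracts 35 features
for all 543, adjusts them for covariates, screens 500 SNPs down to 100, and
runs the Gibbs sampler.  The posterior summary, ranked by maximum absolute
standard score across the 35 features, starts:

```
  snp_id     gene  rank  max_abs_score  n_selected_features
rs000408 gene_041     1      24.309237                   33
rs000362 gene_037     2      16.008382                   27
rs000123 gene_013     3      15.565439                   25
rs000409 gene_041     4      14.625883                   22
rs000410 gene_041     5      13.928145                   28
```

All of the top 20 SNPs fall in the 5 truly causal genes
(`n_selected_features` counts, per SNP, the extracted features whose 95%
credible interval excludes zero).  Comparing feature sets by 50 repetitions
of random sub-sampling validation (200 training subjects per split, logistic
classifier, paired t-test on per-split accuracy differences):

```
extracted: 1.00000 (sd 0.00000)
raw:       0.84138 (sd 0.03349)
paired p:  1.98e-35
```

i.e. on this synthetic cohort the network-extracted features predict
diagnosis better than the raw feature table, mirroring the qualitative
finding the pipeline is designed around.

The same stages are available from the shell:

```bash
imagene simulate --seed 1 --outdir data/
imagene run-all --config pipeline.yaml --outdir run/
imagene evaluate --features-a run/extracted_features.tsv \
                 --features-b data/features.tsv --labels data/labels.tsv
```

## Scope

Image processing itself (FreeSurfer segmentation/parcellation/QC) is out of
scope: the package models the processed table's schema only.  No linkage
disequilibrium or population structure is simulated, and spike-and-slab /
reduced-rank / spatial model variants are not implemented.
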