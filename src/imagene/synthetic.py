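"""Synthetic cohort generator for the imaging-genetics pipeline.

Emulates, at configurable scale, the statistical structure the pipeline
assumes: independent biallelic SNP dosages with realistic minor-allele
frequencies and SNPs grouped into genes; a gene-sparse coefficient matrix
linking genotype to imaging features; Gaussian imaging features
``X = W' G + E``; demographic covariates drawn independently of genotype;
and a three-class diagnosis (NC / MCI / AD) driven by a subset of the
imaging features, following the premise that genotype shapes brain structure
which in turn shapes disease.

The default configuration mirrors the study conditions this package targets:
543 subjects with a 145 / 256 / 142 NC / MCI / AD composition, several
hundred candidate SNPs grouped into genes, and an 1860-column imaging table
(see :mod:`imagene.schema`).  Linkage disequilibrium, population structure
and missingness mechanisms are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, GroupPartition
from .schema import FeatureMatrix

__all__ = [
    "SyntheticConfig",
    "Cohort",
    "generate_genotypes",
    "generate_coefficients",
    "generate_features",
    "generate_labels",
    "generate_covariates",
    "generate_cohort",
    "DEFAULT_COMPOSITION",
]

#: The study cohort composition: (NC, MCI, AD) counts summing to 543.
DEFAULT_COMPOSITION = (145, 256, 142)

LABELS = ("NC", "MCI", "AD")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``effect_size`` is the standard deviation of nonzero coefficient entries,
    ``noise_sd`` the residual standard deviation of the imaging features,
    and ``n_disease_features`` the number of leading imaging features that
    drive diagnosis.  ``label_counts``, when given, fixes the exact
    NC/MCI/AD composition by ranking the disease score; otherwise labels are
    thresholded at ``+-mci_band`` on the noisy score (``mci_band = 0`` yields
    a two-class NC/AD cohort).
    """

    n_subjects: int = 543
    n_snps: int = 500
    n_genes: int = 50
    n_features: int = 1860
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_genes: int = 5
    effect_size: float = 0.5
    noise_sd: float = 1.0
    n_disease_features: int = 10
    seed: int = 0
    mci_band: float = 1.0
    label_scale: float = 3.0
    label_counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_snps, self.n_genes, self.n_features) <= 0:
            raise ValueError("counts must be positive")
        if self.n_genes > self.n_snps:
            raise ValueError("n_genes may not exceed n_snps")
        if not (0 <= self.n_causal_genes <= self.n_genes):
            raise ValueError("n_causal_genes must lie in [0, n_genes]")
        if not (0 <= self.n_disease_features <= self.n_features):
            raise ValueError("n_disease_features must lie in [0, n_features]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")
        if self.label_counts is not None and sum(self.label_counts) != self.n_subjects:
            raise ValueError("label_counts must sum to n_subjects")


@dataclass
class Cohort:
    """All components of one synthetic study, sharing subject order."""

    genotype: GenotypeMatrix
    partition: GroupPartition
    true_coefficients: np.ndarray  # S x C
    causal_genes: np.ndarray  # indices of causal groups
    features: FeatureMatrix
    covariates: pd.DataFrame
    labels: np.ndarray  # values in {"NC","MCI","AD"}

    @property
    def n_subjects(self) -> int:
        return self.genotype.n_subjects

    def nc_ad_mask(self) -> np.ndarray:
        """Boolean mask of the NC/AD (classifier-training) subjects."""
        return np.isin(self.labels, ["NC", "AD"])


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_genotypes(config: SyntheticConfig) -> tuple[GenotypeMatrix, GroupPartition]:
    """Draw S x n binomial(2, p_s) dosages and a contiguous gene partition.

    Per-SNP minor-allele frequencies are uniform on ``maf_range``; SNPs are
    assigned to genes in contiguous, near-equal blocks.
    """
    rng = _rng(config, 0)
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    values = rng.binomial(2, maf[:, None], size=(config.n_snps, config.n_subjects))
    snp_ids = [f"rs{i + 1:06d}" for i in range(config.n_snps)]
    subject_ids = [f"subj_{j + 1:04d}" for j in range(config.n_subjects)]
    blocks = np.array_split(np.arange(config.n_snps), config.n_genes)
    partition = GroupPartition(blocks, [f"gene_{q + 1:03d}" for q in range(config.n_genes)])
    return GenotypeMatrix(values.astype(np.int8), snp_ids, subject_ids), partition


def generate_coefficients(
    config: SyntheticConfig, partition: GroupPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-sparse S x C coefficient matrix and the causal-gene indices.

    Rows in ``n_causal_genes`` randomly chosen groups are filled with
    N(0, effect_size^2) entries; all other rows are exactly zero.
    """
    if partition.n_groups != config.n_genes:
        raise ValueError("partition group count does not match config.n_genes")
    rng = _rng(config, 1)
    W = np.zeros((partition.n_items, config.n_features))
    causal = np.sort(rng.choice(config.n_genes, size=config.n_causal_genes, replace=False))
    for q in causal:
        idx = partition.groups[q]
        W[idx, :] = rng.normal(0.0, config.effect_size, size=(len(idx), config.n_features))
    return W, causal


def generate_features(
    genotype: GenotypeMatrix, W: np.ndarray, noise_sd: float, seed: int
) -> FeatureMatrix:
    """Imaging features ``X = W' G + E`` with i.i.d. N(0, noise_sd^2) noise."""
    G = genotype.dosages()
    W = np.asarray(W, dtype=float)
    if W.shape[0] != G.shape[0]:
        raise ValueError(f"W has {W.shape[0]} rows but genotype has {G.shape[0]} SNPs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    X = W.T @ G
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    ids = [f"feature_{j + 1}" for j in range(W.shape[1])]
    return FeatureMatrix(X, ids, list(genotype.subject_ids))


def generate_labels(features: FeatureMatrix, config: SyntheticConfig) -> np.ndarray:
    """Diagnoses driven by a linear score over the leading imaging features.

    The score is the standardized mean of the first ``n_disease_features``
    rows, scaled by ``label_scale``, plus standard-logistic noise.  Subjects
    above ``mci_band`` are AD, below ``-mci_band`` NC, and in between MCI.
    With ``label_counts`` set, the noisy score is rank-ordered instead and the
    exact composition is assigned (lowest scores NC, highest AD).
    """
    rng = _rng(config, 3)
    d = config.n_disease_features
    if d > features.n_features:
        raise ValueError("n_disease_features exceeds available features")
    if d > 0:
        score = features.values[:d].mean(axis=0)
        sd = score.std()
        score = (score - score.mean()) / (sd if sd > 0 else 1.0)
    else:
        score = np.zeros(features.n_subjects)
    z = config.label_scale * score + rng.logistic(size=features.n_subjects)
    if config.label_counts is not None:
        n_nc, n_mci, n_ad = config.label_counts
        order = np.argsort(z, kind="stable")
        labels = np.empty(features.n_subjects, dtype=object)
        labels[order[:n_nc]] = "NC"
        labels[order[n_nc:n_nc + n_mci]] = "MCI"
        labels[order[n_nc + n_mci:]] = "AD"
        return labels.astype(str)
    labels = np.where(z > config.mci_band, "AD", np.where(z < -config.mci_band, "NC", "MCI"))
    return labels.astype(str)


def generate_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """Age, sex, education, APOE e4 dosage and total intracranial volume.

    Drawn independently of genotype and features, so covariate adjustment is
    a no-op in expectation on synthetic data (a testable property); real
    covariates of course correlate with the phenotype.
    """
    rng = _rng(config, 4)
    n = config.n_subjects
    return pd.DataFrame(
        {
            "age": rng.normal(75.0, 6.0, n),
            "sex": rng.integers(0, 2, n),
            "education": np.clip(rng.normal(16.0, 2.5, n), 6, 20),
            "apoe": rng.binomial(2, 0.25, n),
            "icv": rng.normal(1.5e6, 1.5e5, n),
        },
        index=pd.Index([f"subj_{j + 1:04d}" for j in range(n)], name="subject_id"),
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort; deterministic given ``config`` (incl. seed)."""
    genotype, partition = generate_genotypes(config)
    W, causal = generate_coefficients(config, partition)
    features = generate_features(genotype, W, config.noise_sd, config.seed)
    labels = generate_labels(features, config)
    covariates = generate_covariates(config)
    return Cohort(genotype, partition, W, causal, features, covariates, labels)
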