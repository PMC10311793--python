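"""Covariate adjustment and multi-stage SNP screening.

Before genetic association, every imaging feature is residualized on subject
covariates (age, sex, education, APOE genotype, total intracranial volume) by
ordinary least squares; the residuals are the adjusted imaging responses.
SNPs are then reduced in two steps: restriction to a candidate list supplied
by the user (e.g. an expert-curated disease panel), followed by a univariate
screen -- a simple linear regression of every adjusted feature on every SNP
dosage -- ranking SNPs by their smallest slope p-value across features and
keeping the top k (default 100).  No multiplicity correction is applied at
this stage: the screen only orders SNPs, and the multivariate Bayesian model
downstream is the arbiter of selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .genotype import GenotypeMatrix
from .schema import FeatureMatrix

__all__ = [
    "DEFAULT_COVARIATES",
    "CovariateAdjuster",
    "adjust_for_covariates",
    "encode_apoe",
    "filter_candidates",
    "ScreenResult",
    "univariate_screen",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "education", "apoe", "icv")


def encode_apoe(apoe, scheme: str = "dosage") -> pd.DataFrame:
    """Encode APOE as e4-allele count (default) or categorical dummies."""
    s = pd.Series(apoe)
    if scheme == "dosage":
        return pd.DataFrame({"apoe": s.astype(float)})
    if scheme == "dummies":
        return pd.get_dummies(s.astype("category"), prefix="apoe", drop_first=True).astype(float)
    raise ValueError(f"unknown APOE encoding {scheme!r}")


class CovariateAdjuster(TransformerMixin, BaseEstimator):
    """OLS residualization transformer.

    Fit on the covariate table (n_subjects x n_covariates); ``transform``
    maps any response matrix (n_subjects x n_features) to the residuals of
    each column regressed on an intercept plus all covariates.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        D = X.to_numpy(dtype=float)
        names = list(X.columns)
        if self.add_intercept:
            D = np.column_stack([np.ones(len(D)), D])
            names = ["intercept"] + names
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            # identify offending columns via the pivoted QR diagonal
            _, R, piv = _qr_pivoted(D)
            bad = [names[j] for j in piv[rank:]]
            raise ValueError(f"covariate design is rank-deficient; collinear columns: {bad}")
        self.design_ = D
        # hat projector via least squares; reused for every response column
        self.pinv_ = np.linalg.pinv(D)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, Y) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        Y = np.atleast_2d(Y.T).T  # (n, C)
        if Y.shape[0] != self.design_.shape[0]:
            raise ValueError("response and covariates cover different subject counts")
        resid = Y - self.design_ @ (self.pinv_ @ Y)
        return resid.ravel() if squeeze else resid


def _qr_pivoted(D):
    from scipy.linalg import qr

    Q, R, piv = qr(D, mode="economic", pivoting=True)
    return Q, R, piv


def adjust_for_covariates(
    features: FeatureMatrix, covariates: pd.DataFrame, columns=DEFAULT_COVARIATES
) -> FeatureMatrix:
    """Residualize every imaging feature on the covariates.

    ``covariates`` is indexed by subject; rows are aligned to the feature
    matrix's subject order and must be complete.
    """
    cov = pd.DataFrame(covariates)
    if not set(features.subject_ids).issubset(set(map(str, cov.index))):
        missing = [s for s in features.subject_ids if s not in set(map(str, cov.index))][:5]
        raise ValueError(f"covariate rows missing for subjects {missing}")
    cov = cov.loc[[s for s in features.subject_ids]]
    use = [c for c in columns if c in cov.columns]
    absent = [c for c in columns if c not in cov.columns]
    if absent:
        raise ValueError(f"covariate table lacks columns {absent}")
    if cov[use].isna().any().any():
        raise ValueError("covariate table contains missing values")
    adj = CovariateAdjuster().fit(cov[use])
    resid = adj.transform(features.values.T).T
    return FeatureMatrix(resid, list(features.feature_ids), list(features.subject_ids))


def filter_candidates(genotype: GenotypeMatrix, candidate_ids) -> GenotypeMatrix:
    """Restrict the genotype matrix to a candidate SNP list.

    Original SNP order is preserved; unmatched candidate ids are counted and
    logged.  An empty intersection is an error.
    """
    candidates = [str(c) for c in candidate_ids]
    if not candidates:
        raise ValueError("candidate_ids is empty")
    wanted = set(candidates)
    keep = [i for i, s in enumerate(genotype.snp_ids) if s in wanted]
    unmatched = len(wanted - set(genotype.snp_ids))
    if unmatched:
        logger.warning("%d candidate ids not present in genotype matrix", unmatched)
    if not keep:
        raise ValueError("no candidate SNP found in the genotype matrix")
    return genotype.subset_snps(keep)


@dataclass
class ScreenResult:
    """Univariate screening output: per-pair p-values and the top-k SNP set."""

    pvalues: np.ndarray  # S x C
    min_p: np.ndarray  # length S
    snp_ids: list[str]
    ranked_snp_ids: list[str]
    kept_snp_ids: list[str]

    def kept_indices(self) -> np.ndarray:
        """Row indices of kept SNPs, in original genotype order."""
        kept = set(self.kept_snp_ids)
        return np.array([i for i, s in enumerate(self.snp_ids) if s in kept], dtype=int)

    def to_frame(self, gene_of: dict[str, str] | None = None) -> pd.DataFrame:
        rank = {s: r + 1 for r, s in enumerate(self.ranked_snp_ids)}
        kept = set(self.kept_snp_ids)
        df = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "min_p": self.min_p,
                "rank": [rank[s] for s in self.snp_ids],
                "kept": [s in kept for s in self.snp_ids],
            }
        )
        if gene_of:
            df.insert(1, "gene", [gene_of.get(s, "") for s in self.snp_ids])
        return df.sort_values("rank").reset_index(drop=True)

    def write(self, path, gene_of=None) -> None:
        self.to_frame(gene_of).to_csv(path, sep="\t", index=False)


def univariate_screen(
    adjusted: FeatureMatrix, genotype: GenotypeMatrix, k: int = 100
) -> ScreenResult:
    """Simple-linear-regression screen of every (SNP, feature) pair.

    For each pair, the feature is regressed on an intercept plus the SNP
    dosage and the two-sided t-test p-value of the slope is recorded.  SNPs
    are ranked by their minimum p-value across features (ties broken by SNP
    identifier) and the top ``min(k, S)`` are kept.  Monomorphic SNPs get
    p = 1 with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if list(adjusted.subject_ids) != list(genotype.subject_ids):
        raise ValueError("feature and genotype matrices must share subject order")
    G = genotype.dosages()  # S x n
    Y = adjusted.values  # C x n
    S, n = G.shape
    C = Y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a slope t-test")
    Gc = G - G.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Sxx = np.einsum("sn,sn->s", Gc, Gc)
    Syy = np.einsum("cn,cn->c", Yc, Yc)
    Sxy = Gc @ Yc.T  # S x C
    mono = Sxx <= 0
    if mono.any():
        warnings.warn(
            f"{int(mono.sum())} monomorphic SNP(s) after filtering; p-values set to 1",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = np.maximum(Syy[None, :] - Sxy**2 / np.where(mono, np.nan, Sxx)[:, None], 0.0)
        sigma2 = sse / (n - 2)
        t = Sxy / np.sqrt(sigma2 * Sxx[:, None])
        t = np.where(np.isfinite(t), t, np.inf * np.sign(Sxy))  # exact fit -> p = 0
        pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals[mono, :] = 1.0
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    min_p = pvals.min(axis=1)
    order = np.lexsort((np.asarray(genotype.snp_ids), min_p))
    ranked = [genotype.snp_ids[i] for i in order]
    kept = ranked[: min(k, S)]
    return ScreenResult(pvals, min_p, list(genotype.snp_ids), ranked, kept)
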