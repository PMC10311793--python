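"""Sampler-validation utilities: deterministic oracles for the Gibbs sampler.

These functions exist so the Markov chain Monte Carlo machinery can be
checked against computations that do not share its code path:

* :func:`quadrature_posterior_mean` integrates the model's exact (W, sigma^2)
  posterior on a tiny instance (2 SNPs, 1 feature) by deterministic grid
  quadrature.  The latent scales of the Gibbs augmentation integrate out in
  closed form to the product-Laplace prior (see :mod:`imagene.bgsmtr`), so
  the oracle shares no machinery with the sampler; its posterior means must
  agree with the chain's.
* :func:`getting_it_right` is the marginal-conditional ("successive
  conditional") simulator: alternating data regeneration with single Gibbs
  transitions leaves the prior invariant if and only if every full
  conditional is consistent with the augmented joint; prior means of W and
  sigma^2 must be preserved within Monte-Carlo error.
* :func:`causal_recovery_auc` measures, on synthetic data with known causal
  genes, how well the posterior standard score separates causal from null
  SNP rows.
* :func:`null_min_p_pvalue` and :func:`null_ci_selection_rate` check the
  screening and selection stages under a global null.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .bgsmtr import (
    BGSMTRConfig,
    MCMCState,
    gibbs_step,
    run_gibbs,
    summarize_posterior,
)
from .genotype import GroupPartition
from .screening import univariate_screen
from .synthetic import SyntheticConfig, generate_cohort

__all__ = [
    "quadrature_posterior_mean",
    "getting_it_right",
    "causal_recovery_auc",
    "null_min_p_pvalue",
    "null_ci_selection_rate",
]


def quadrature_posterior_mean(
    G: np.ndarray,
    x: np.ndarray,
    lambda1: float,
    lambda2: float,
    w_half_width: float = 3.0,
    n_w: int = 161,
    n_s2: int = 101,
) -> np.ndarray:
    """Posterior mean of (w1, w2) by deterministic grid quadrature (S=2, C=1).

    Both SNPs form their own group, so the exact joint density is, up to a
    constant,

        sigma^{-n} exp(-RSS/(2 sigma^2))
        * sigma^{-2} exp(-(lambda1 + lambda2)(|w1| + |w2|)/sigma) / sigma^2,

    the last factor being the improper 1/sigma^2 prior.  sigma^2 is handled
    on a truncated log-spaced grid wide enough that posterior mass at the
    edges is negligible.
    """
    G = np.asarray(G, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if G.shape[0] != 2:
        raise ValueError("the quadrature oracle handles exactly 2 SNPs")
    n = len(x)
    ols, *_ = np.linalg.lstsq(G.T, x, rcond=None)
    s2_hat = max(np.mean((x - G.T @ ols) ** 2), 1e-3)

    w1 = np.linspace(ols[0] - w_half_width, ols[0] + w_half_width, n_w)
    w2 = np.linspace(ols[1] - w_half_width, ols[1] + w_half_width, n_w)
    s2 = np.exp(np.linspace(np.log(s2_hat / 50.0), np.log(s2_hat * 50.0), n_s2))

    # residual sum of squares is quadratic in (w1, w2): expand once
    GG = G @ G.T
    Gx = G @ x
    xx = x @ x
    W1, W2 = np.meshgrid(w1, w2, indexing="ij")
    rss = (
        xx
        - 2.0 * (W1 * Gx[0] + W2 * Gx[1])
        + W1**2 * GG[0, 0] + 2.0 * W1 * W2 * GG[0, 1] + W2**2 * GG[1, 1]
    )

    sigma = np.sqrt(s2)
    lam = lambda1 + lambda2
    log_post = (
        -((n + 2) / 2.0) * np.log(s2)[None, None, :]  # likelihood + prior normalization
        - rss[:, :, None] / (2.0 * s2)[None, None, :]
        - lam * (np.abs(W1) + np.abs(W2))[:, :, None] / sigma[None, None, :]
        - np.log(s2)[None, None, :]  # improper 1/sigma^2 prior
    )
    log_post -= log_post.max()
    post = np.exp(log_post)
    # trapezoid weights in each dimension (s2 on its own nonuniform grid)
    def trap_w(g):
        w = np.empty_like(g)
        w[1:-1] = (g[2:] - g[:-2]) / 2.0
        w[0] = (g[1] - g[0]) / 2.0
        w[-1] = (g[-1] - g[-2]) / 2.0
        return w

    wts = trap_w(w1)[:, None, None] * trap_w(w2)[None, :, None] * trap_w(s2)[None, None, :]
    Z = np.sum(post * wts)
    ew1 = np.sum(W1[:, :, None] * post * wts) / Z
    ew2 = np.sum(W2[:, :, None] * post * wts) / Z
    return np.array([ew1, ew2])


def _sample_prior_state(
    partition: GroupPartition, C: int, config: BGSMTRConfig, rng: np.random.Generator
) -> MCMCState:
    """Overdispersed prior-shaped start for the marginal-conditional chain.

    The chain's stationary law is the model prior regardless of the start;
    a short warm-up is discarded to wash out the initializer.
    """
    if config.sigma2_prior is None:
        raise ValueError("a proper inverse-gamma sigma^2 prior is required")
    a, b = config.sigma2_prior
    sigma2 = float(b / rng.gamma(a, 1.0))
    m = partition.sizes
    tau2 = rng.gamma((m * C + 1) / 2.0, 2.0 / config.lambda1**2)
    S = partition.n_items
    omega2 = rng.gamma((C + 1) / 2.0, 2.0 / config.lambda2**2, size=S)
    d = 1.0 / (1.0 / tau2[partition.labels()] + 1.0 / omega2)
    W = rng.standard_normal((S, C)) * np.sqrt(sigma2 * d)[:, None]
    return MCMCState(W, sigma2, tau2, omega2)


def getting_it_right(
    S: int = 4,
    C: int = 2,
    n: int = 6,
    lambda1: float = 2.0,
    lambda2: float = 2.0,
    sigma2_prior: tuple[float, float] = (3.0, 2.0),
    n_sweeps: int = 5_000,
    n_groups: int = 2,
    seed: int = 0,
) -> dict:
    """Marginal-conditional simulator for the Gibbs full conditionals.

    Alternates data regeneration ``X ~ p(X | state)`` with one Gibbs
    transition; if the conditionals are correct the chain of states is
    stationary under the prior, so the running means of W entries and
    sigma^2 must match their prior expectations (0 and b/(a-1)) within
    Monte-Carlo error.  Returns the maximum |z| over W entries and the
    sigma^2 z-score, with effective-sample-size-adjusted standard errors.
    """
    import arviz as az

    rng = np.random.default_rng(seed)
    config = BGSMTRConfig(
        lambda1=lambda1, lambda2=lambda2, n_iter=2, burn_in=1,
        seed=seed, sigma2_prior=sigma2_prior,
    )
    blocks = np.array_split(np.arange(S), n_groups)
    partition = GroupPartition(list(blocks), [f"g{q}" for q in range(n_groups)])
    labels = partition.labels()
    G = rng.binomial(2, 0.3, size=(S, n)).astype(float)
    GGt = G @ G.T

    state = _sample_prior_state(partition, C, config, rng)
    warmup = min(200, n_sweeps // 10)
    W_draws = np.empty((n_sweeps, S, C))
    s2_draws = np.empty(n_sweeps)
    for m in range(warmup + n_sweeps):
        X = state.W.T @ G + np.sqrt(state.sigma2) * rng.standard_normal((C, n))
        state = gibbs_step(state, G, X, labels, partition.groups, config, rng, GGt, G @ X.T)
        if m >= warmup:
            W_draws[m - warmup] = state.W
            s2_draws[m - warmup] = np.minimum(state.sigma2, 1e12)

    a, b = sigma2_prior
    prior_s2_mean = b / (a - 1.0)
    z_scores = []
    flat = W_draws.reshape(n_sweeps, -1)
    for j in range(flat.shape[1]):
        draws = flat[:, j]
        ess = max(float(az.ess(draws[None, :])), 2.0)
        se = draws.std(ddof=1) / np.sqrt(ess)
        z_scores.append(abs(draws.mean() - 0.0) / se)
    ess_s2 = max(float(az.ess(s2_draws[None, :])), 2.0)
    se_s2 = s2_draws.std(ddof=1) / np.sqrt(ess_s2)
    z_s2 = abs(s2_draws.mean() - prior_s2_mean) / se_s2
    pooled = flat.mean(axis=1)  # per-sweep mean over all W entries
    ess_p = max(float(az.ess(pooled[None, :])), 2.0)
    z_pooled = abs(pooled.mean()) / (pooled.std(ddof=1) / np.sqrt(ess_p))
    return {
        "z_W_pooled": float(z_pooled),
        "max_abs_z_W": float(np.max(z_scores)),
        "z_sigma2": float(z_s2),
        "sigma2_mean": float(s2_draws.mean()),
        "sigma2_prior_mean": float(prior_s2_mean),
        "n_sweeps": n_sweeps,
    }


def causal_recovery_auc(
    seed: int,
    n_subjects: int = 200,
    n_snps: int = 40,
    n_genes: int = 10,
    n_causal_genes: int = 3,
    n_features: int = 5,
    effect_size: float = 0.5,
    noise_sd: float = 1.0,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    n_iter: int = 3_000,
    burn_in: int = 1_000,
) -> float:
    """Area under the causal-vs-null ranking by max |posterior standard score|."""
    from sklearn.metrics import roc_auc_score

    cfg = SyntheticConfig(
        n_subjects=n_subjects, n_snps=n_snps, n_genes=n_genes,
        n_features=n_features, n_causal_genes=n_causal_genes,
        effect_size=effect_size, noise_sd=noise_sd, seed=seed,
        n_disease_features=min(n_features, 3),
    )
    cohort = generate_cohort(cfg)
    bcfg = BGSMTRConfig(
        lambda1=lambda1, lambda2=lambda2, n_iter=n_iter, burn_in=burn_in, seed=seed
    )
    samples = run_gibbs(
        cohort.genotype.dosages(), cohort.features.values, cohort.partition, bcfg,
        snp_ids=cohort.genotype.snp_ids,
    )
    summary = summarize_posterior(samples)
    truth = (np.abs(cohort.true_coefficients).sum(axis=1) > 0).astype(int)
    return float(roc_auc_score(truth, summary.max_abs_score()))


def null_min_p_pvalue(seed: int, n_snps: int = 200, n_subjects: int = 500, n_features: int = 5) -> float:
    """KS p-value of the null screen's min-p against the min-of-C-uniforms law."""
    cfg = SyntheticConfig(
        n_subjects=n_subjects, n_snps=n_snps, n_genes=max(n_snps // 10, 1),
        n_features=n_features, n_causal_genes=0, effect_size=0.0,
        n_disease_features=0, seed=seed,
    )
    cohort = generate_cohort(cfg)
    result = univariate_screen(cohort.features, cohort.genotype, k=n_snps)
    C = n_features
    ks = stats.kstest(result.min_p, lambda p: 1.0 - (1.0 - p) ** C)
    return float(ks.pvalue)


def null_ci_selection_rate(
    seed: int,
    n_subjects: int = 200,
    n_snps: int = 40,
    n_features: int = 5,
    level: float = 0.95,
    n_iter: int = 3_000,
    burn_in: int = 1_000,
) -> float:
    """Fraction of coefficients whose credible interval excludes zero under the null."""
    cfg = SyntheticConfig(
        n_subjects=n_subjects, n_snps=n_snps, n_genes=max(n_snps // 4, 1),
        n_features=n_features, n_causal_genes=0, effect_size=0.0,
        n_disease_features=0, seed=seed,
    )
    cohort = generate_cohort(cfg)
    bcfg = BGSMTRConfig(n_iter=n_iter, burn_in=burn_in, seed=seed)
    samples = run_gibbs(
        cohort.genotype.dosages(), cohort.features.values, cohort.partition, bcfg
    )
    summary = summarize_posterior(samples, level=level)
    return float(np.mean(summary.n_selected_features / cohort.features.n_features))
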