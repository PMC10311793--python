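import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.base import clone

from imagene.bgsmtr import (
    BGSMTRConfig,
    BayesianGroupSparseRegression,
    GibbsSamples,
    cv_select_lambdas,
    group_l21_norm,
    l21_norm,
    log_unnormalized_posterior,
    run_gibbs,
    select_snps_by_ci,
    summarize_posterior,
)
from imagene.genotype import GroupPartition
from imagene.synthetic import SyntheticConfig, generate_cohort


def _singleton_partition(S):
    return GroupPartition([np.array([i]) for i in range(S)], [f"g{i}" for i in range(S)])


def _naive_group_l21(W, partition):
    """Loop-based double-sum oracle."""
    total = 0.0
    for g in partition.groups:
        acc = 0.0
        for i in g:
            for j in range(W.shape[1]):
                acc += W[i, j] ** 2
        total += np.sqrt(acc)
    return total


def _naive_l21(W):
    total = 0.0
    for i in range(W.shape[0]):
        acc = 0.0
        for j in range(W.shape[1]):
            acc += W[i, j] ** 2
        total += np.sqrt(acc)
    return total


class TestNorms:
    def test_zero_matrix(self):
        W = np.zeros((4, 3))
        part = _singleton_partition(4)
        assert group_l21_norm(W, part) == 0.0
        assert l21_norm(W) == 0.0

    def test_single_group_is_frobenius(self):
        W = np.array([[3.0, 4.0]])
        part = GroupPartition([np.array([0])], ["g"])
        assert group_l21_norm(W, part) == pytest.approx(5.0)

    def test_printed_two_row_example(self):
        W = np.array([[1.0, 2.0], [2.0, 4.0]])
        part = _singleton_partition(2)
        expected = np.sqrt(5.0) + np.sqrt(20.0)
        assert group_l21_norm(W, part) == pytest.approx(expected, abs=1e-12)
        assert l21_norm(W) == pytest.approx(expected, abs=1e-12)

    def test_agree_with_naive_double_sum_on_random_matrices(self):
        """100 random matrices, random partitions: vectorized == loop oracle to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            S = rng.integers(1, 12)
            C = rng.integers(1, 6)
            W = rng.normal(scale=3.0, size=(S, C))
            n_groups = rng.integers(1, S + 1)
            blocks = np.array_split(rng.permutation(S), n_groups)
            blocks = [b for b in blocks if len(b)]
            part = GroupPartition(blocks, [f"g{q}" for q in range(len(blocks))])
            assert group_l21_norm(W, part) == pytest.approx(
                _naive_group_l21(W, part), abs=1e-10
            )
            assert l21_norm(W) == pytest.approx(_naive_l21(W), abs=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(arrays(np.float64, (6, 3), elements=st.floats(-50, 50)))
    def test_norm_inequality_chain(self, W):
        """group l2,1 <= l2,1 <= sqrt(S) * Frobenius for any W and partition."""
        part = GroupPartition([np.arange(3), np.arange(3, 6)], ["a", "b"])
        fro = np.sqrt(np.sum(W**2))
        assert group_l21_norm(W, part) <= l21_norm(W) + 1e-9
        assert l21_norm(W) <= np.sqrt(6) * fro + 1e-9


class TestLogPosterior:
    def _instance(self, seed=0):
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 3, size=(3, 4)).astype(float)
        X = rng.normal(size=(2, 4))
        W = rng.normal(size=(3, 2))
        part = GroupPartition([np.array([0, 1]), np.array([2])], ["a", "b"])
        cfg = BGSMTRConfig(lambda1=1.3, lambda2=0.7)
        return W, G, X, part, cfg

    def test_zero_everything_is_zero(self):
        W = np.zeros((3, 2))
        G = np.ones((3, 4))
        X = np.zeros((2, 4))
        part = GroupPartition([np.arange(3)], ["a"])
        cfg = BGSMTRConfig()
        assert log_unnormalized_posterior(W, 1.0, G, X, part, cfg) == pytest.approx(0.0)

    def test_matches_naive_termwise_summation(self):
        """Brute-force loops over subjects, SNPs and features reproduce the value."""
        W, G, X, part, cfg = self._instance(3)
        s2 = 1.7
        n, C, S = 4, 2, 3
        rss = 0.0
        for l in range(n):
            for j in range(C):
                pred = sum(W[i, j] * G[i, l] for i in range(S))
                rss += (X[j, l] - pred) ** 2
        val = -((n + S) * C / 2) * np.log(s2) - rss / (2 * s2)
        val -= cfg.lambda1 / np.sqrt(s2) * _naive_group_l21(W, part)
        val -= cfg.lambda2 / np.sqrt(s2) * _naive_l21(W)
        val -= np.log(s2)
        assert log_unnormalized_posterior(W, s2, G, X, part, cfg) == pytest.approx(
            val, abs=1e-10
        )

    def test_residual_scaling_identity(self):
        """Doubling residuals at sigma^2=1 lowers the value by 3/2 ||R||_F^2."""
        W, G, X, part, cfg = self._instance(5)
        R = X - W.T @ G
        base = log_unnormalized_posterior(W, 1.0, G, X, part, cfg)
        doubled = log_unnormalized_posterior(W, 1.0, G, W.T @ G + 2 * R, part, cfg)
        assert doubled - base == pytest.approx(-1.5 * np.sum(R**2), rel=1e-10)

    def test_nonpositive_sigma2_rejected(self):
        W, G, X, part, cfg = self._instance()
        with pytest.raises(ValueError, match="sigma2"):
            log_unnormalized_posterior(W, 0.0, G, X, part, cfg)


class TestGibbs:
    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, size=(5, 20)).astype(float)
        X = rng.normal(size=(2, 20))
        part = GroupPartition([np.arange(2), np.arange(2, 5)], ["a", "b"])
        cfg = BGSMTRConfig(n_iter=300, burn_in=100, seed=9)
        s1 = run_gibbs(G, X, part, cfg)
        s2 = run_gibbs(G, X, part, cfg)
        np.testing.assert_array_equal(s1.W, s2.W)
        np.testing.assert_array_equal(s1.sigma2, s2.sigma2)

    def test_burn_in_config_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            BGSMTRConfig(n_iter=100, burn_in=100)

    def test_posterior_mean_matches_quadrature(self):
        """S=2, C=1, n=8: the chain agrees with deterministic grid quadrature."""
        from imagene.validation import quadrature_posterior_mean

        rng = np.random.default_rng(7)
        G = rng.binomial(2, 0.4, size=(2, 8)).astype(float)
        x = np.array([0.8, -0.5]) @ G + rng.normal(0, 0.7, 8)
        part = _singleton_partition(2)
        cfg = BGSMTRConfig(lambda1=1.0, lambda2=1.0, n_iter=35_000, burn_in=5_000, seed=3)
        samples = run_gibbs(G, x[None, :], part, cfg)
        mcmc_mean = samples.W.mean(axis=0).ravel()
        quad_mean = quadrature_posterior_mean(G, x, 1.0, 1.0)
        np.testing.assert_allclose(mcmc_mean, quad_mean, atol=0.02)

    def test_shrinkage_contrast_on_sparse_truth(self):
        """Null gene rows shrink far below causal rows with strong effects."""
        cfg = SyntheticConfig(
            n_subjects=150, n_snps=30, n_genes=10, n_features=4, n_causal_genes=3,
            effect_size=1.0, noise_sd=1.0, n_disease_features=2, seed=4,
        )
        cohort = generate_cohort(cfg)
        bcfg = BGSMTRConfig(n_iter=1500, burn_in=500, seed=4)
        samples = run_gibbs(
            cohort.genotype.dosages(), cohort.features.values, cohort.partition, bcfg
        )
        post_mean = np.abs(samples.W.mean(axis=0)).mean(axis=1)
        causal_rows = np.abs(cohort.true_coefficients).sum(axis=1) > 0
        assert post_mean[~causal_rows].mean() < post_mean[causal_rows].mean() / 3.0

    def test_getting_it_right_prior_preserved(self):
        """Successive-conditional simulation holds prior means of W and sigma^2."""
        from imagene.validation import getting_it_right

        res = getting_it_right(n_sweeps=4000, seed=5)
        assert res["z_W_pooled"] <= 3.0
        assert res["z_sigma2"] <= 3.0

    def test_posterior_concentrates_with_more_data(self):
        """Doubling n does not increase the median absolute estimation error."""
        errs = {100: [], 200: []}
        for seed in range(10):
            for n in (100, 200):
                cfg = SyntheticConfig(
                    n_subjects=n, n_snps=12, n_genes=4, n_features=3, n_causal_genes=2,
                    effect_size=0.8, noise_sd=1.0, n_disease_features=1, seed=seed,
                )
                cohort = generate_cohort(cfg)
                bcfg = BGSMTRConfig(n_iter=800, burn_in=300, seed=seed)
                samples = run_gibbs(
                    cohort.genotype.dosages(), cohort.features.values, cohort.partition, bcfg
                )
                err = np.median(np.abs(samples.W.mean(axis=0) - cohort.true_coefficients))
                errs[n].append(err)
        assert np.median(errs[200]) <= np.median(errs[100])


class TestSummaries:
    def _constant_store(self, value, n_draws=200, S=2, C=2):
        W = np.full((n_draws, S, C), value)
        return GibbsSamples(W, np.ones(n_draws), [f"rs{i}" for i in range(S)], BGSMTRConfig())

    def test_constant_draws_degenerate_summary(self):
        summary = summarize_posterior(self._constant_store(1.0))
        assert np.all(summary.mean == 1.0) and np.all(summary.sd == 0.0)
        assert np.all(summary.standard_score == pytest.approx(1e12))
        assert np.all(summary.ci_lower == 1.0) and np.all(summary.ci_upper == 1.0)

    def test_symmetric_draws_zero_score(self):
        W = np.concatenate([np.full((100, 1, 1), 0.5), np.full((100, 1, 1), -0.5)])
        store = GibbsSamples(W, np.ones(200), ["rs1"], BGSMTRConfig())
        summary = summarize_posterior(store)
        assert summary.mean[0, 0] == pytest.approx(0.0)
        assert summary.standard_score[0, 0] == pytest.approx(0.0)

    def test_standard_normal_draws_ci_endpoints(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((1000, 1, 1))
        store = GibbsSamples(W, np.ones(1000), ["rs1"], BGSMTRConfig())
        summary = summarize_posterior(store)
        assert summary.ci_lower[0, 0] == pytest.approx(-1.96, abs=0.15)
        assert summary.ci_upper[0, 0] == pytest.approx(1.96, abs=0.15)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(self._constant_store(0.0, n_draws=50))

    def test_ci_selection_counts(self):
        rng = np.random.default_rng(2)
        W = rng.normal(0, 0.01, size=(500, 3, 4))
        W[:, 1, :3] += 5.0  # 3 coefficients of SNP 2 bounded away from zero
        store = GibbsSamples(W, np.ones(500), ["rs1", "rs2", "rs3"], BGSMTRConfig())
        summary = summarize_posterior(store)
        table = select_snps_by_ci(summary)
        assert table.loc[table.snp_id == "rs2", "n_selected_features"].item() == 3
        assert not table.loc[table.snp_id == "rs1", "selected"].item()

    def test_all_zero_posterior_selects_nothing(self):
        rng = np.random.default_rng(3)
        W = rng.normal(0, 1.0, size=(500, 2, 2))
        store = GibbsSamples(W, np.ones(500), ["rs1", "rs2"], BGSMTRConfig())
        table = select_snps_by_ci(summarize_posterior(store))
        assert not table["selected"].any()


class TestCrossValidation:
    def test_single_pair_grid_returned(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(6, 40)).astype(float)
        X = rng.normal(size=(2, 40))
        part = GroupPartition([np.arange(3), np.arange(3, 6)], ["a", "b"])
        cfg = BGSMTRConfig(lambda_grid=((2.0, 3.0),), cv_folds=4,
                           cv_n_iter=200, cv_burn_in=100)
        best, table = cv_select_lambdas(G, X, part, cfg)
        assert best == (2.0, 3.0) and len(table) == 1

    def test_fold_assignment_deterministic(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(6, 40)).astype(float)
        X = rng.normal(size=(2, 40))
        part = GroupPartition([np.arange(6)], ["a"])
        cfg = BGSMTRConfig(lambda_grid=((0.5, 0.5), (5.0, 5.0)), cv_folds=4,
                           cv_n_iter=200, cv_burn_in=100, seed=11)
        b1, t1 = cv_select_lambdas(G, X, part, cfg)
        b2, t2 = cv_select_lambdas(G, X, part, cfg)
        assert b1 == b2
        assert t1.equals(t2)

    def test_shrinkage_dominates_on_pure_noise(self):
        """With W=0 truth, heavier penalties never lose in held-out MSE on average."""
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            G = rng.integers(0, 3, size=(20, 60)).astype(float)
            X = rng.normal(size=(2, 60))
            part = GroupPartition(list(np.array_split(np.arange(20), 5)),
                                  [f"g{q}" for q in range(5)])
            cfg = BGSMTRConfig(lambda_grid=((0.5, 0.5), (10.0, 10.0)), cv_folds=3,
                               cv_n_iter=300, cv_burn_in=100, seed=seed)
            _, table = cv_select_lambdas(G, X, part, cfg)
            small = table.loc[table.lambda1 == 0.5, "cv_mse"].item()
            large = table.loc[table.lambda1 == 10.0, "cv_mse"].item()
            diffs.append(large - small)
        assert np.mean(diffs) <= 0.0

    def test_too_small_folds_rejected(self):
        G = np.zeros((2, 6))
        X = np.zeros((1, 6))
        part = _singleton_partition(2)
        cfg = BGSMTRConfig(cv_folds=5)
        with pytest.raises(ValueError, match="fold"):
            cv_select_lambdas(G, X, part, cfg)


class TestEstimator:
    def test_fit_predict_shapes_and_clone(self, small_cohort):
        X = small_cohort.genotype.dosages().T[:, :10]
        y = small_cohort.features.values.T[:, :3]
        est = BayesianGroupSparseRegression(
            n_iter=400, burn_in=200, groups=["g1"] * 5 + ["g2"] * 5, random_state=0
        )
        est.fit(X, y)
        assert est.coef_.shape == (10, 3)
        assert est.predict(X).shape == (120, 3)
        assert est.summary_.mean.shape == (10, 3)
        cloned = clone(est)
        assert cloned.get_params()["n_iter"] == 400
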