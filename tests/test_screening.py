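import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imagene.genotype import GenotypeMatrix
from imagene.schema import FeatureMatrix
from imagene.screening import (
    CovariateAdjuster,
    adjust_for_covariates,
    encode_apoe,
    filter_candidates,
    univariate_screen,
)


def _fm(values, prefix="f"):
    values = np.atleast_2d(values)
    return FeatureMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


def _geno(values):
    values = np.atleast_2d(values)
    return GenotypeMatrix(
        values,
        [f"rs{i:03d}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


class TestCovariateAdjustment:
    def test_feature_equal_to_covariate_residuals_vanish(self, rng):
        n = 40
        cov = pd.DataFrame(
            {"age": rng.normal(70, 5, n), "sex": rng.integers(0, 2, n),
             "education": rng.normal(16, 2, n), "apoe": rng.binomial(2, 0.3, n),
             "icv": rng.normal(1.5e6, 1e5, n)},
            index=[f"s{j}" for j in range(n)],
        )
        fm = _fm(cov["age"].to_numpy())
        out = adjust_for_covariates(fm, cov)
        # tolerance relative to the feature scale (the design includes ICV ~ 1.5e6)
        assert np.max(np.abs(out.values)) < 1e-10 * np.abs(fm.values).max()

    def test_hand_solved_single_covariate(self):
        """4 subjects, one covariate: residuals from the 2x2 normal equations."""
        z = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        # by hand: Sxx=5, Sxy=3 -> slope 0.6; intercept 2.5 - 0.6*2.5 = 1.0
        expected = y - (1.0 + 0.6 * z)
        adj = CovariateAdjuster().fit(pd.DataFrame({"z": z}))
        np.testing.assert_allclose(adj.transform(y), expected, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 60
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        Y = rng.normal(size=(n, 5)) * 10 + 3
        adj = CovariateAdjuster().fit(cov)
        R = adj.transform(Y)
        inner = adj.design_.T @ R
        assert np.max(np.abs(inner)) < 1e-8 * n * np.abs(Y).max()

    def test_independent_noise_covariates_keep_variance(self, rng):
        n = 2000
        cov = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = rng.normal(size=n) * 3.0
        r = CovariateAdjuster().fit(cov).transform(y)
        ratio = r.var() / y.var()
        assert 0.9 <= ratio <= 1.0

    def test_collinear_covariates_named(self, rng):
        n = 30
        a = rng.normal(size=n)
        cov = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=n)})
        with pytest.raises(ValueError, match="collinear"):
            CovariateAdjuster().fit(cov)

    def test_missing_covariate_column_rejected(self, small_cohort):
        cov = small_cohort.covariates.drop(columns=["apoe"])
        with pytest.raises(ValueError, match="apoe"):
            adjust_for_covariates(small_cohort.features, cov)

    def test_apoe_encodings(self):
        dosage = encode_apoe([0, 1, 2])
        assert list(dosage["apoe"]) == [0.0, 1.0, 2.0]
        dummies = encode_apoe([0, 1, 2], scheme="dummies")
        assert dummies.shape == (3, 2)


class TestCandidateFilter:
    def test_full_list_is_identity(self, small_cohort):
        out = filter_candidates(small_cohort.genotype, small_cohort.genotype.snp_ids)
        np.testing.assert_array_equal(out.values, small_cohort.genotype.values)

    def test_partial_match_with_warning_count(self, caplog):
        geno = _geno(np.zeros((4, 3), dtype=int))
        import logging

        with caplog.at_level(logging.WARNING, logger="imagene.screening"):
            out = filter_candidates(geno, ["rs000", "rs002", "rs003", "nope1", "nope2"])
        assert out.n_snps == 3
        assert out.snp_ids == ["rs000", "rs002", "rs003"]  # original order
        assert "2 candidate ids" in caplog.text

    def test_empty_intersection_rejected(self):
        geno = _geno(np.zeros((2, 3), dtype=int))
        with pytest.raises(ValueError, match="no candidate"):
            filter_candidates(geno, ["absent"])

    def test_485_candidate_panel(self, rng):
        values = rng.integers(0, 3, size=(1000, 5))
        geno = _geno(values)
        panel = [f"rs{i:03d}" for i in range(485)]
        out = filter_candidates(geno, panel)
        assert out.n_snps == 485


class TestUnivariateScreen:
    def test_perfect_association_ranks_first(self, rng):
        G = rng.integers(0, 3, size=(10, 30))
        Y = rng.normal(size=(3, 30))
        Y[0] = 2.0 * G[4]  # feature exactly proportional to SNP 5's dosage
        res = univariate_screen(_fm(Y), _geno(G), k=3)
        assert res.ranked_snp_ids[0] == "rs004"
        assert res.min_p[4] < 1e-12

    def test_pvalues_match_linregress(self, rng):
        G = rng.integers(0, 3, size=(6, 25)).astype(float)
        Y = rng.normal(size=(4, 25))
        res = univariate_screen(_fm(Y), _geno(G), k=6)
        for s in range(6):
            for c in range(4):
                expected = stats.linregress(G[s], Y[c]).pvalue
                np.testing.assert_allclose(res.pvalues[s, c], expected, rtol=1e-9)

    def test_hand_computed_single_pair(self):
        """n=5 printed dosages/values: p from the closed-form slope t statistic."""
        g = np.array([0.0, 1.0, 1.0, 2.0, 2.0])
        y = np.array([0.5, 1.0, 2.0, 2.0, 3.5])
        # by hand: Sxx=10-5*1.44=2.8, Sxy=14-5*1.2*1.8=3.2, Syy=21.5-5*1.8^2=5.3
        sxx, sxy, syy = 2.8, 3.2, 5.3
        slope = sxy / sxx
        se = np.sqrt((syy - sxy**2 / sxx) / 3.0 / sxx)
        p_hand = 2 * stats.t.sf(abs(slope / se), df=3)
        res = univariate_screen(_fm(y), _geno(g), k=1)
        np.testing.assert_allclose(res.pvalues[0, 0], p_hand, rtol=1e-12)

    def test_monomorphic_snp_warned_and_p_one(self, rng):
        G = rng.integers(0, 3, size=(3, 20))
        G[1] = 1  # constant dosage
        Y = rng.normal(size=(2, 20))
        with pytest.warns(RuntimeWarning, match="monomorphic"):
            res = univariate_screen(_fm(Y), _geno(G), k=3)
        assert np.all(res.pvalues[1] == 1.0)

    def test_invariant_to_feature_order_and_affine_rescale(self, rng):
        G = rng.integers(0, 3, size=(8, 40))
        Y = rng.normal(size=(5, 40))
        base = univariate_screen(_fm(Y), _geno(G), k=8)
        scaled = Y[::-1] * 7.0 - 3.0
        other = univariate_screen(_fm(scaled), _geno(G), k=8)
        assert base.ranked_snp_ids == other.ranked_snp_ids
        np.testing.assert_allclose(np.sort(base.min_p), np.sort(other.min_p), rtol=1e-9)

    def test_k_larger_than_s_keeps_all_and_no_rng(self, rng):
        G = rng.integers(0, 3, size=(5, 20))
        Y = rng.normal(size=(2, 20))
        r1 = univariate_screen(_fm(Y), _geno(G), k=50)
        r2 = univariate_screen(_fm(Y), _geno(G), k=50)
        assert len(r1.kept_snp_ids) == 5
        assert r1.ranked_snp_ids == r2.ranked_snp_ids

    def test_ties_break_lexicographically(self):
        G = np.zeros((2, 10))
        G[0] = G[1] = np.arange(10) % 3
        Y = np.ones((1, 10)) + np.arange(10) * 0.1
        res = univariate_screen(_fm(Y), _geno(G), k=2)
        assert res.ranked_snp_ids == ["rs000", "rs001"]  # identical p, id order

    def test_null_min_p_follows_min_of_uniforms(self):
        """Independent noise: min over C of per-feature p-values ~ Beta-type law."""
        from imagene.validation import null_min_p_pvalue

        assert null_min_p_pvalue(seed=0, n_snps=150, n_subjects=300, n_features=4) > 0.01

    def test_screen_result_table_roundtrip(self, tmp_path, rng):
        G = rng.integers(0, 3, size=(6, 30))
        Y = rng.normal(size=(3, 30))
        res = univariate_screen(_fm(Y), _geno(G), k=4)
        path = tmp_path / "screen.tsv"
        res.write(path)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == 6 and back["kept"].sum() == 4
        assert list(back.sort_values("rank")["snp_id"])[:4] == res.kept_snp_ids
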