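"""Tests for the genotype/LD/phenotype generators and case presets."""

import numpy as np
import pytest

from bgblup import (LdBlockSpec, case_config, case_study, make_phenotypes,
                    ols_effects, sample_binary_genotypes, sample_ld_genotypes)
from bgblup.exceptions import EstimabilityError, ParameterError
from bgblup.evaluate import ols_fit


class TestBinaryGenotypes:
    def test_column_frequencies_match_binomial_sampling(self):
        M = sample_binary_genotypes(500, 200, freq=0.5, seed=1)
        se = np.sqrt(0.25 / 500)
        within = np.abs(M.values.mean(axis=0) - 0.5) <= 3 * se
        assert within.mean() >= 0.95

    def test_extreme_frequency_gives_constant_column(self):
        for seed in range(5):
            M = sample_binary_genotypes(4, 1, freq=0.999999, seed=seed)
            assert np.all(M.values == 1.0)

    def test_off_block_columns_nearly_uncorrelated(self):
        M = sample_binary_genotypes(2000, 10, freq=0.5, seed=3)
        c = np.corrcoef(M.values.T)
        off = c[np.triu_indices(10, k=1)]
        assert np.max(np.abs(off)) < 0.1

    @pytest.mark.parametrize("kw", [{"freq": 0.0}, {"freq": 1.0},
                                    {"n": 0}, {"p": 0}])
    def test_invalid_parameters_rejected(self, kw):
        args = {"n": 5, "p": 5, "freq": 0.5, **kw}
        with pytest.raises(ParameterError):
            sample_binary_genotypes(**args)


class TestLdGenerator:
    def test_intraclass_correlation_matches_closed_form(self):
        # Monte-Carlo oracle: the beta-binomial intraclass correlation is
        # 1/(a+b+1); average realized within-block correlation over
        # replicates must sit within 3 MC standard errors of it.
        for a, b in [(0.5, 0.5), (1.0, 1.0)]:
            spec = LdBlockSpec(n_qtl_total=8, n_markers_total=0,
                               qtl_ld_block=(0, 8), marker_ld_block=(0, 0),
                               beta_a=a, beta_b=b)
            target = 1.0 / (a + b + 1.0)
            vals = []
            for rep in range(30):
                Q, _ = sample_ld_genotypes(300, spec, seed=1000 + rep)
                c = np.corrcoef(Q.values.T)
                vals.append(c[np.triu_indices(8, k=1)].mean())
            vals = np.asarray(vals)
            mcse = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - target) < 3 * mcse + 0.01

    def test_large_beta_parameters_remove_correlation(self):
        spec = LdBlockSpec(n_qtl_total=6, n_markers_total=0,
                           qtl_ld_block=(0, 6), marker_ld_block=(0, 0),
                           beta_a=500.0, beta_b=500.0)
        Q, _ = sample_ld_genotypes(2000, spec, seed=2)
        c = np.corrcoef(Q.values.T)
        assert np.max(np.abs(c[np.triu_indices(6, k=1)])) < 0.05

    def test_block_and_nonblock_columns_independent(self):
        spec = LdBlockSpec(n_qtl_total=20, n_markers_total=40,
                           qtl_ld_block=(0, 10), marker_ld_block=(0, 20))
        Q, X = sample_ld_genotypes(4000, spec, seed=5)
        cross = np.corrcoef(Q.values[:, :10].T, X.values[:, 20:].T)[:10, 10:]
        assert np.mean(np.abs(cross)) < 0.03

    def test_shared_latent_creates_qtl_marker_ld(self):
        spec = LdBlockSpec(n_qtl_total=4, n_markers_total=4,
                           qtl_ld_block=(0, 2), marker_ld_block=(0, 2))
        Q, X = sample_ld_genotypes(3000, spec, seed=7)
        r = np.corrcoef(Q.values[:, 0], X.values[:, 0])[0, 1]
        assert r > 0.3  # expected 0.5 with Beta(0.5, 0.5)

    def test_invalid_block_spec_rejected(self):
        with pytest.raises(ParameterError):
            LdBlockSpec(n_qtl_total=5, n_markers_total=0,
                        qtl_ld_block=(0, 9), marker_ld_block=(0, 0))
        with pytest.raises(ParameterError):
            LdBlockSpec(n_qtl_total=5, n_markers_total=0,
                        qtl_ld_block=(0, 2), marker_ld_block=(0, 0),
                        beta_a=0.0)


class TestPhenotypes:
    def test_h2_matches_independent_identity(self):
        Q = sample_binary_genotypes(300, 50, seed=1)
        ds = make_phenotypes(Q, effect_sd=1.0, sigma2_e=10.0, seed=2)
        resid = ds.y - ds.signal
        assert np.allclose(ds.y, ds.signal + resid)
        assert 0.0 <= ds.h2_effective <= 1.0
        # recomputed independently from the realized vectors
        assert np.isclose(ds.h2_effective,
                          np.var(ds.signal) / np.var(ds.y))
        # var(y) decomposes into signal + residual + twice the realized
        # covariance, so 1 - var(resid)/var(y) agrees up to that term
        cov = np.cov(ds.signal, resid, bias=True)[0, 1]
        alt = 1.0 - np.var(resid) / np.var(ds.y)
        assert np.isclose(ds.h2_effective, alt - 2 * cov / np.var(ds.y))

    def test_noiseless_limit_h2_near_one(self):
        Q = sample_binary_genotypes(100, 20, seed=3)
        ds = make_phenotypes(Q, effect_sd=1.0, sigma2_e=1e-12, seed=4)
        assert ds.h2_effective > 0.999

    def test_null_genetics_h2_zero(self):
        Q = sample_binary_genotypes(100, 20, seed=5)
        ds = make_phenotypes(Q, effect_sd=0.0, sigma2_e=1.0, seed=6)
        assert np.all(ds.signal == 0)
        assert ds.h2_effective == 0.0

    def test_invalid_variances_rejected(self):
        Q = sample_binary_genotypes(10, 3, seed=1)
        with pytest.raises(ParameterError):
            make_phenotypes(Q, sigma2_e=0.0)
        with pytest.raises(ParameterError):
            make_phenotypes(Q, effect_sd=-1.0)


class TestCaseStudies:
    def test_preset_shapes_and_heritabilities(self):
        expect = {1: (200, None, 0.34), 2: (1000, None, 0.68),
                  3: (20, 200, 0.19), 4: (100, 500, 0.74)}
        for cid, (q, p, h2) in expect.items():
            h2_seen = []
            for seed in range(10):
                ds = case_study(cid, seed=seed)
                assert ds.n == 500 and ds.Q.p == q
                assert (ds.X is None) == (p is None)
                if p is not None:
                    assert ds.X.p == p
                h2_seen.append(ds.h2_effective)
            # the median realized h2 sits on the calibrated target; the
            # LD cases (3-4) scatter more because of block cross-terms
            tol = 0.05 if cid in (1, 2) else 0.09
            assert abs(np.median(h2_seen) - h2) < tol

    def test_case2_is_ols_inestimable(self):
        ds = case_study(2, seed=1)
        assert ds.Q.p / ds.n == 2
        with pytest.raises(EstimabilityError):
            ols_effects(ds.Q, ds.y)

    def test_seed_contract(self):
        a = case_study(1, seed=1)
        b = case_study(1, seed=2)
        c = case_study(1, seed=1)
        assert not np.array_equal(a.y, b.y)
        assert np.array_equal(a.y, c.y)
        assert a.config == b.config

    def test_unknown_case_rejected(self):
        with pytest.raises(ParameterError):
            case_study(5)
        with pytest.raises(ParameterError):
            case_config(0)

    def test_case3_markers_overfit_but_miss_signal(self):
        # more parameters fit the phenotypes better, yet the QTL model
        # captures far more of the true signal
        ds = case_study(3, seed=21)
        fit_q, r2_q = ols_fit(ds.Q, ds.y)
        fit_x, r2_x = ols_fit(ds.X, ds.y)
        assert r2_x > r2_q
        sig_q = np.corrcoef(fit_q, ds.signal)[0, 1] ** 2
        sig_x = np.corrcoef(fit_x, ds.signal)[0, 1] ** 2
        assert sig_q > 2 * sig_x

    def test_case3_block_qtl_recoverable_from_markers(self):
        ds = case_study(3, seed=22)
        r2s = [ols_fit(ds.X, ds.Q.values[:, j])[1] for j in range(10)]
        assert np.mean(r2s) > 0.6
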