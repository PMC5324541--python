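"""Phylogenetic GLS: covariance construction, the Pagel-lambda transform,
GLS numerics (cross-checked against statsmodels), ML lambda recovery and
the domestication contrast bookkeeping."""

import dendropy
import numpy as np
import pytest
import statsmodels.api as sm

import yieldparts as yp
from yieldparts.pgls import (PGLS, PglsError, gls_fit, pagel_transform,
                             pgls_ml, phylo_covariance)
from yieldparts.simulate import SPECIES


@pytest.fixture(scope="module")
def three_taxon():
    tree = dendropy.Tree.get(data="((A:1,B:1):1,Cc:2):0;", schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="module")
def C17(tree):
    C, order = phylo_covariance(tree, list(SPECIES))
    return C, order


class TestCovariance:
    def test_three_taxon_shared_branch_lengths(self, three_taxon):
        C, order = phylo_covariance(three_taxon, ["A", "B", "Cc"])
        np.testing.assert_allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]], atol=1e-12)

    def test_pagel_endpoints_and_midpoint(self, three_taxon):
        C, _ = phylo_covariance(three_taxon, ["A", "B", "Cc"])
        V0 = pagel_transform(C, 0.0)
        np.testing.assert_allclose(V0, np.diag([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(pagel_transform(C, 1.0), C)
        V5 = pagel_transform(C, 0.5)
        assert V5[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(V5), np.diag(C))

    def test_lambda_outside_unit_interval_rejected(self, three_taxon):
        C, _ = phylo_covariance(three_taxon, ["A", "B", "Cc"])
        with pytest.raises(PglsError):
            pagel_transform(C, 1.2)

    def test_seventeen_taxon_matrix_spd(self, C17):
        C, order = C17
        assert order == list(SPECIES)
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)  # unit depth


class TestGls:
    def test_identity_covariance_reduces_to_ols(self, rng):
        n = 17
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        fit = gls_fit(y, X, np.eye(n))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ols.params, atol=1e-12)
        np.testing.assert_allclose(fit.se, ols.bse, atol=1e-10)

    def test_noiseless_data_recovered_exactly(self, rng):
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([2.0, -0.7])
        V = np.eye(n) * 0.5 + 0.5
        fit = gls_fit(y, X, V)
        np.testing.assert_allclose(fit.beta, [2.0, -0.7], atol=1e-10)
        assert fit.sigma2_ml == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_gls_under_general_covariance(self, rng, C17):
        C, _ = C17
        V = pagel_transform(C, 0.7)
        n = V.shape[0]
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.multivariate_normal(X @ [1.0, 0.5], V)
        mine = gls_fit(y, X, V)
        ref = sm.GLS(y, X, sigma=V).fit()
        np.testing.assert_allclose(mine.beta, ref.params, rtol=1e-10)
        np.testing.assert_allclose(mine.se, ref.bse, rtol=1e-8)

    def test_single_status_design_rejected(self, C17):
        C, _ = C17
        n = C.shape[0]
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(PglsError, match="singular"):
            gls_fit(np.zeros(n), X, C)


def _simulate_bm(rng, C, lam, beta, x):
    V = pagel_transform(C, lam)
    return rng.multivariate_normal(beta[0] + beta[1] * x, V)


class TestPglsMl:
    def test_lambda_zero_fit_equals_ols(self, rng, C17):
        C, order = C17
        n = C.shape[0]
        x = rng.integers(0, 2, n).astype(float)
        y = rng.normal(size=n)
        est = PGLS(lambda_method=0.0).fit(x.reshape(-1, 1), y, C)
        # diag(C) = 1 at unit depth, so lambda=0 is exactly OLS
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert est.intercept_ == pytest.approx(ols.params[0], abs=1e-10)
        assert est.coef_[0] == pytest.approx(ols.params[1], abs=1e-10)

    def test_f_equals_t_squared_and_df(self, species_summary, tree):
        res = yp.crop_progenitor_contrast(species_summary, "Y", tree)
        assert res.F == pytest.approx((res.beta / res.se) ** 2, rel=1e-10)
        assert res.df == (1, 15)

    def test_cereal_subset_df(self, species_summary, tree):
        res = yp.crop_progenitor_contrast(species_summary, "Ns", tree)
        assert res.df == (1, 8)

    def test_star_phylogeny_flat_likelihood_flagged(self, rng):
        n = 17
        C = np.eye(n)
        x = rng.integers(0, 2, n).astype(float)
        y = rng.normal(size=n)
        res = pgls_ml(y, x, C)
        assert res.lambda_flat

    def test_lambda_recovery_no_signal(self, C17):
        C, _ = C17
        n = C.shape[0]
        x = np.tile([1.0, 0.0], 9)[:n]
        lams = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            y = _simulate_bm(rng, C, 0.0, [0.0, 0.3], x)
            lams.append(PGLS().fit(x.reshape(-1, 1), y, C).lambda_)
        assert np.median(lams) <= 0.1

    def test_lambda_recovery_brownian(self, C17):
        C, _ = C17
        n = C.shape[0]
        x = np.tile([1.0, 0.0], 9)[:n]
        lams = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            y = _simulate_bm(rng, C, 1.0, [0.0, 0.3], x)
            lams.append(PGLS().fit(x.reshape(-1, 1), y, C).lambda_)
        assert np.median(lams) >= 0.8

    def test_planted_effect_unbiased_under_brownian(self, C17):
        C, order = C17
        n = C.shape[0]
        x = np.tile([1.0, 0.0], 9)[:n]
        beta_true = np.log(1.5)
        betas = []
        for seed in range(200):
            rng = np.random.default_rng(7_000 + seed)
            y = _simulate_bm(rng, C, 1.0, [1.0, beta_true], x)
            betas.append(PGLS().fit(x.reshape(-1, 1), y, C).coef_[0])
        betas = np.array(betas)
        mcse = betas.std(ddof=1) / np.sqrt(len(betas))
        assert abs(betas.mean() - beta_true) < 2 * mcse

    def test_ratio_backtransform_monotone_ci(self, species_summary, tree):
        res = yp.crop_progenitor_contrast(species_summary, "Ms_sown", tree)
        assert res.ratio_ci[0] < res.ratio < res.ratio_ci[1]
        assert res.ratio == pytest.approx(np.exp(res.beta))

    def test_correlation_r2_in_unit_interval(self, species_summary, tree):
        out = yp.pgls.pgls_correlation(species_summary, "Md", "Y", tree)
        assert 0.0 <= out["r2"] <= 1.0
        # plant size explains most of the variance in yield across species
        assert out["r2"] > 0.5 and out["slope"] > 0
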