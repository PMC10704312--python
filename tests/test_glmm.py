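import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from actema.glmm import (MixedGLM, center_within, fit_glmm, select_family,
                         summarize_effect, variance_decomposition)


def _binary_clusters(rng, n_clusters=3, n_per=10, sigma_u=0.6,
                     beta=(0.2, 0.5)):
    u = rng.normal(0, sigma_u, n_clusters)
    x = rng.normal(0, 1, (n_clusters, n_per))
    eta = beta[0] + beta[1] * x + u[:, None]
    y = rng.binomial(1, expit(eta)).ravel()
    X = np.column_stack([np.ones(n_clusters * n_per), x.ravel()])
    groups = np.repeat(np.arange(n_clusters), n_per)
    return y, X, groups


def trapezoid_loglike(y, X, groups, beta, sigma_u, npts=10_001, lim=8.0):
    """Independent oracle: dense 1-D integration of each cluster's likelihood."""
    ll = 0.0
    ug = np.linspace(-lim * sigma_u, lim * sigma_u, npts)
    phi = np.exp(-0.5 * (ug / sigma_u) ** 2) / (sigma_u * np.sqrt(2 * np.pi))
    for g in np.unique(groups):
        sel = groups == g
        eta = X[sel] @ beta
        like = np.ones_like(ug)
        for e, yv in zip(eta, y[sel]):
            p = expit(e + ug)
            like *= p**yv * (1 - p) ** (1 - yv)
        ll += np.log(np.trapezoid(like * phi, ug))
    return ll


class TestCentering:
    def test_symmetric_triple(self):
        w, b = center_within([3, 5, 7], ["a", "a", "a"])
        assert np.allclose(b, 5.0) and np.allclose(w, [-2, 0, 2])

    def test_constant_cluster(self):
        w, _ = center_within([4, 4, 4], ["a"] * 3)
        assert np.allclose(w, 0.0)

    def test_two_constant_clusters(self):
        w, b = center_within([1, 1, 7, 7], ["a", "a", "b", "b"])
        assert np.allclose(b, [1, 1, 7, 7]) and np.allclose(w, 0.0)

    def test_reconstruction_and_zero_cluster_means(self, rng):
        x = rng.normal(4, 2, 200)
        g = rng.integers(0, 12, 200)
        w, b = center_within(x, g)
        assert np.allclose(w + b, x)
        means = pd.Series(w).groupby(g).mean()
        assert np.abs(means).max() < 1e-10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center_within([], [])


class TestVarianceDecomposition:
    def test_pure_between(self, rng):
        g = np.repeat(np.arange(10), 20)
        x = g.astype(float) + rng.normal(0, 1e-4, 200)
        assert variance_decomposition(x, g) < 0.01

    def test_pure_within(self, rng):
        g = np.repeat(np.arange(10), 50)
        x = rng.normal(0, 1.0, 500)
        assert variance_decomposition(x, g) > 0.9

    def test_known_mixture(self):
        rng = np.random.default_rng(99)
        g = np.repeat(np.arange(200), 30)
        x = np.repeat(rng.normal(0, 0.8, 200), 30) + rng.normal(0, 1.2, 6000)
        share = variance_decomposition(x, g)
        assert abs(share - 0.692) < 0.05

    def test_constant_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            share = variance_decomposition(np.ones(40), np.repeat([0, 1], 20))
        assert np.isnan(share)


class TestMarginalLikelihood:
    def test_quadrature_matches_dense_integration(self, rng):
        y, X, groups = _binary_clusters(rng)
        model = MixedGLM(y, X, groups, family="binomial", n_quad=15)
        beta = np.array([0.2, 0.5])
        ll = model.loglike(np.r_[beta, np.log(0.6)])
        oracle = trapezoid_loglike(y, X, groups, beta, 0.6)
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_sigma_zero_matches_plain_glm(self, rng):
        import statsmodels.api as sm

        y, X, groups = _binary_clusters(rng, n_clusters=10, n_per=20)
        res = MixedGLM(y, X, groups, family="binomial").fit(fix_sigma_u=0.0)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(res.params.to_numpy(), glm.params, atol=1e-6)
        assert res.llf == pytest.approx(glm.llf, abs=1e-6)

    def test_sigma_zero_matches_plain_glm_poisson(self, rng):
        import statsmodels.api as sm

        g = np.repeat(np.arange(8), 25)
        x = rng.normal(0, 1, 200)
        y = rng.poisson(np.exp(0.5 + 0.3 * x))
        X = np.column_stack([np.ones(200), x])
        res = MixedGLM(y, X, g, family="poisson").fit(fix_sigma_u=0.0)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.allclose(res.params.to_numpy(), glm.params, atol=1e-6)
        assert res.llf == pytest.approx(glm.llf, abs=1e-6)

    def test_negbin_large_theta_approaches_poisson(self, rng):
        g = np.repeat(np.arange(12), 20)
        u = np.repeat(rng.normal(0, 0.4, 12), 20)
        x = rng.normal(0, 1, 240)
        y = rng.poisson(np.exp(0.8 + 0.2 * x + u))
        X = np.column_stack([np.ones(240), x])
        pois = MixedGLM(y, X, g, family="poisson").fit()
        nb = MixedGLM(y, X, g, family="negbin")
        ll_nb = nb.loglike(np.r_[pois.params.to_numpy(),
                                 np.log(pois.sigma_u), np.log(1e6)])
        assert ll_nb == pytest.approx(pois.llf, abs=1e-3)

    def test_gaussian_matches_mixedlm(self, rng):
        import statsmodels.formula.api as smf

        G, n = 30, 8
        u = rng.normal(0, 1.2, G)
        x = rng.normal(0, 1, (G, n))
        y = 2 + 0.5 * x + u[:, None] + rng.normal(0, 0.9, (G, n))
        d = pd.DataFrame({"y": y.ravel(), "x": x.ravel(),
                          "g": np.repeat(np.arange(G), n)})
        mine = MixedGLM(d["y"], np.column_stack([np.ones(len(d)), d["x"]]),
                        d["g"], family="gaussian").fit()
        sm_fit = smf.mixedlm("y ~ x", d, groups=d["g"]).fit(reml=False)
        assert mine.llf == pytest.approx(sm_fit.llf, abs=1e-4)
        assert np.allclose(mine.params.to_numpy(), sm_fit.fe_params, atol=1e-4)

    def test_permutation_invariance(self, rng):
        y, X, groups = _binary_clusters(rng, n_clusters=6, n_per=15)
        p = np.array([0.1, 0.4, np.log(0.5)])
        ll1 = MixedGLM(y, X, groups, family="binomial").loglike(p)
        perm = rng.permutation(len(y))
        ll2 = MixedGLM(y[perm], X[perm], groups[perm],
                       family="binomial").loglike(p)
        assert abs(ll1 - ll2) < 1e-10

    def test_node_count_convergence(self, rng):
        y, X, groups = _binary_clusters(rng, n_clusters=40, n_per=20,
                                        sigma_u=0.8)
        fit15 = MixedGLM(y, X, groups, family="binomial", n_quad=15).fit()
        p = fit15.params_all
        ll = {k: MixedGLM(y, X, groups, family="binomial", n_quad=k).loglike(p)
              for k in (5, 15, 31)}
        assert abs(ll[31] - ll[15]) < 1e-4
        assert abs(ll[15] - ll[5]) < 1e-2


class TestFitting:
    def test_recovers_moderate_logistic_effect(self):
        rng = np.random.default_rng(7)
        G, n = 100, 30
        u = rng.normal(0, 0.8, G)
        x = rng.normal(4, 1.5, (G, n))
        xw = x - x.mean(axis=1, keepdims=True)
        eta = -0.3 + 0.4 * xw + 0.1 * x.mean(axis=1, keepdims=True) + u[:, None]
        d = pd.DataFrame({"y": rng.binomial(1, expit(eta)).ravel(),
                          "x": x.ravel(), "g": np.repeat(np.arange(G), n)})
        res = fit_glmm(d, "y", "x", "g", family="binomial")
        assert res.converged
        lo, hi = res.conf_int().loc["within"]
        assert lo < 0.4 < hi
        assert res.bse["within"] > 0

    def test_aic_counts_estimated_parameters(self, rng):
        y, X, groups = _binary_clusters(rng, n_clusters=20, n_per=20)
        res = MixedGLM(y, X, groups, family="binomial").fit()
        # 2 fixed effects + sigma_u
        assert res.aic == pytest.approx(2 * 3 - 2 * res.llf)
        res0 = MixedGLM(y, X, groups, family="binomial").fit(fix_sigma_u=0.0)
        assert res0.aic == pytest.approx(2 * 2 - 2 * res0.llf)

    def test_boundary_sigma_u_flagged(self):
        # underdispersed clusters (identical 50/50 splits everywhere):
        # the random-intercept variance MLE is exactly 0
        y = np.tile(np.r_[np.ones(10), np.zeros(10)], 20)
        X = np.ones((400, 1))
        g = np.repeat(np.arange(20), 20)
        res = MixedGLM(y, X, g, family="binomial").fit()
        assert res.boundary_sigma_u
        assert res.sigma_u == 0.0
        assert "boundary" in res.message

    def test_summary_prints(self, rng):
        y, X, groups = _binary_clusters(rng, n_clusters=10, n_per=12)
        s = MixedGLM(y, X, groups, family="binomial").fit().summary()
        assert "sigma_u" in s and "logLik" in s


class TestFamilySelection:
    def _mock(self, family, aic, converged=True):
        class R:
            pass

        r = R()
        r.family, r.aic, r.converged = family, aic, converged
        return r

    def test_argmin(self):
        fits = [self._mock("gaussian", 500), self._mock("poisson", 480),
                self._mock("negbin", 460)]
        assert select_family(fits).family == "negbin"

    def test_tie_prefers_negbin_with_warning(self):
        fits = [self._mock("gaussian", 100.0), self._mock("negbin", 100.0)]
        with pytest.warns(UserWarning, match="tie"):
            assert select_family(fits).family == "negbin"

    def test_nonconverged_excluded(self):
        fits = [self._mock("negbin", 100.0, converged=False),
                self._mock("poisson", 120.0)]
        with pytest.warns(UserWarning, match="non-converged"):
            assert select_family(fits).family == "poisson"

    def test_all_failed_raises(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(RuntimeError):
                select_family([self._mock("negbin", 1.0, converged=False)])


class TestEffectSummary:
    def test_null_effect_arithmetic(self, rng):
        y, X, groups = _binary_clusters(rng, n_clusters=10, n_per=12)
        res = MixedGLM(y, X, groups, family="binomial").fit()
        res.params["x1"] = 0.0
        res.bse["x1"] = 0.1
        eff = summarize_effect(res, "x1", scale="OR")
        assert eff.point == pytest.approx(1.0)
        assert eff.ci_low == pytest.approx(np.exp(-1.959964 * 0.1), abs=1e-4)
        assert eff.ci_high == pytest.approx(np.exp(1.959964 * 0.1), abs=1e-4)
        assert eff.p == pytest.approx(1.0)
        assert not eff.significant

    def test_strong_effect_significant(self, rng):
        y, X, groups = _binary_clusters(rng, n_clusters=10, n_per=12)
        res = MixedGLM(y, X, groups, family="binomial").fit()
        res.params["x1"] = np.log(1.33)
        res.bse["x1"] = 0.01
        eff = summarize_effect(res, "x1")
        assert eff.point == pytest.approx(1.33)
        assert eff.significant

    def test_wald_duality_ci_excludes_one_iff_significant(self, rng):
        y, X, groups = _binary_clusters(rng, n_clusters=4, n_per=6)
        res = MixedGLM(y, X, groups, family="binomial").fit(maxiter=5)
        for _ in range(50):
            b = rng.normal(0, 0.3)
            se = rng.uniform(0.02, 0.4)
            res.params["x1"], res.bse["x1"] = b, se
            eff = summarize_effect(res, "x1")
            excludes = eff.ci_low > 1.0 or eff.ci_high < 1.0
            assert excludes == eff.significant
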