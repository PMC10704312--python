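"""Random-intercept generalized linear mixed models via adaptive
Gauss-Hermite quadrature.

This module is the numerical core of the package.  It estimates models of
the form

    y_ij | u_i  ~  F( g^{-1}( b0 + b_w * x_within_ij + b_b * x_between_i + u_i ) )
    u_i         ~  Normal(0, sigma_u^2)

where F is binomial (logit link), Poisson, negative binomial (NB2,
variance mu + mu^2/theta, log link, optionally zero-truncated) or
Gaussian, and the predictor is decomposed into a within-person deviation
and a between-person mean (hybrid / person-mean centering).  The marginal
likelihood integrates the random intercept out cluster by cluster:

    L_i = int prod_j f(y_ij | eta_ij + u) phi(u; 0, sigma_u^2) du

evaluated by adaptive Gauss-Hermite quadrature (default 15 nodes): each
cluster's integrand is re-centred at its mode and re-scaled by the
curvature there, found by a vectorised Newton iteration.  The Gaussian
family uses the closed-form linear-mixed-model likelihood instead of
quadrature.

The API follows the statsmodels Model/Results convention:
``MixedGLM(endog, exog, groups, family=...).fit()`` returns a
:class:`MixedGLMResults` with estimates, standard errors from the inverse
observed information, log-likelihood, AIC and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "MixedGLM",
    "MixedGLMResults",
    "EffectSummary",
    "center_within",
    "variance_decomposition",
    "fit_glmm",
    "select_family",
    "summarize_effect",
    "FAMILIES",
]

_ETA_MAX = 40.0  # guard: exp(eta) stays finite on the count scale


# ---------------------------------------------------------------------------
# Families: per-observation log-likelihood and its eta-derivatives
# ---------------------------------------------------------------------------


class _Binomial:
    """Bernoulli outcome, logit link."""

    name = "binomial"
    n_aux = 0

    @staticmethod
    def loglike_obs(y, eta, aux=()):
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def d1(y, eta, aux=()):
        return y - special.expit(eta)

    @staticmethod
    def d2(y, eta, aux=()):
        p = special.expit(eta)
        return -p * (1.0 - p)

    @staticmethod
    def validate(y):
        if not np.all(np.isin(y, (0, 1))):
            raise ValueError("binomial family requires a 0/1 outcome")


class _Poisson:
    name = "poisson"
    n_aux = 0

    @staticmethod
    def loglike_obs(y, eta, aux=()):
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        return y * eta - np.exp(eta) - special.gammaln(y + 1.0)

    @staticmethod
    def d1(y, eta, aux=()):
        return y - np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    @staticmethod
    def d2(y, eta, aux=()):
        return -np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    @staticmethod
    def validate(y):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson family requires non-negative integers")


class _NegBin:
    """NB2: variance mu + mu^2/theta, log link; aux = (theta,)."""

    name = "negbin"
    n_aux = 1

    @staticmethod
    def loglike_obs(y, eta, aux):
        theta = aux[0]
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        return (
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1.0)
            + theta * np.log(theta)
            + y * eta
            - (y + theta) * np.log(theta + mu)
        )

    @staticmethod
    def d1(y, eta, aux):
        theta = aux[0]
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        return y - (y + theta) * mu / (theta + mu)

    @staticmethod
    def d2(y, eta, aux):
        theta = aux[0]
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        return -(y + theta) * theta * mu / (theta + mu) ** 2

    @staticmethod
    def validate(y):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("negbin family requires non-negative integers")


class _TruncNegBin(_NegBin):
    """Zero-truncated NB2 for strictly positive counts (sensitivity option).

    Adds -log(1 - P(Y=0)) to the NB2 log-likelihood, with
    P(Y=0) = (theta / (theta + mu))^theta.
    """

    name = "truncnegbin"
    n_aux = 1

    @staticmethod
    def _p0(mu, theta):
        # (theta/(theta+mu))^theta computed in logs for stability
        return np.exp(theta * (np.log(theta) - np.log(theta + mu)))

    @classmethod
    def loglike_obs(cls, y, eta, aux):
        theta = aux[0]
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        p0 = cls._p0(mu, theta)
        return _NegBin.loglike_obs(y, eta, aux) - np.log1p(-p0)

    @classmethod
    def d1(cls, y, eta, aux):
        theta = aux[0]
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        p0 = cls._p0(mu, theta)
        a = theta * mu / (theta + mu)
        return _NegBin.d1(y, eta, aux) - p0 * a / (1.0 - p0)

    @classmethod
    def d2(cls, y, eta, aux):
        theta = aux[0]
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        p0 = cls._p0(mu, theta)
        a = theta * mu / (theta + mu)
        da = theta**2 * mu / (theta + mu) ** 2
        f = p0 / (1.0 - p0)
        # derivative of  -f * a  using  dp0/deta = -p0 * a
        d_extra = f * a * a / (1.0 - p0) - f * da
        return _NegBin.d2(y, eta, aux) + d_extra

    @staticmethod
    def validate(y):
        if np.any(y < 1) or np.any(y != np.round(y)):
            raise ValueError("truncated negbin requires strictly positive integers")


class _Gaussian:
    """Identity link; aux = (sigma_e,).  Fitted in closed form, no quadrature."""

    name = "gaussian"
    n_aux = 1

    @staticmethod
    def validate(y):
        if not np.all(np.isfinite(y)):
            raise ValueError("gaussian family requires finite outcomes")


FAMILIES = {
    "binomial": _Binomial,
    "poisson": _Poisson,
    "negbin": _NegBin,
    "truncnegbin": _TruncNegBin,
    "gaussian": _Gaussian,
}


# ---------------------------------------------------------------------------
# Predictor decomposition
# ---------------------------------------------------------------------------


def center_within(x, groups):
    """Split a time-varying predictor into within- and between-person parts.

    ``x_between`` is the person mean; ``x_within`` is the momentary
    deviation from it (so the person mean of ``x_within`` is zero and
    ``x_within + x_between`` reconstructs ``x`` exactly).  Clusters with a
    single observation get ``x_within = 0``.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    if x.empty:
        raise ValueError("empty predictor")
    g = pd.Series(np.asarray(groups)).reset_index(drop=True)
    between = x.groupby(g, sort=False).transform("mean")
    within = x - between
    return within.to_numpy(), between.to_numpy()


def variance_decomposition(x, groups, n_quad: int = 15) -> float:
    """Share of a variable's variance that lies within persons.

    Fits an intercept-only random-intercept Gaussian model and returns
    sigma_within^2 / (sigma_within^2 + sigma_between^2).  Items are kept
    for momentary analysis only when this share exceeds 0.5.  Returns NaN
    (with a warning) when the variable is constant.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(groups)
    if len(np.unique(g)) < 2:
        raise ValueError("variance decomposition needs at least 2 clusters")
    if np.ptp(x) == 0:
        warnings.warn("constant variable: variance share undefined", stacklevel=2)
        return float("nan")
    model = MixedGLM(x, np.ones((len(x), 1)), g, family="gaussian", n_quad=n_quad)
    res = model.fit()
    s2_w = res.scale**2
    s2_b = res.sigma_u**2
    return float(s2_w / (s2_w + s2_b))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class MixedGLM:
    """Random-intercept GLMM estimated by adaptive Gauss-Hermite quadrature.

    Parameters
    ----------
    endog : array-like
        Outcome vector (0/1 for binomial, non-negative integers for the
        count families, real for gaussian).
    exog : array-like, 2-d
        Fixed-effect design matrix, including the intercept column.
    groups : array-like
        Cluster (participant) labels, one per observation.
    family : str
        One of ``binomial``, ``poisson``, ``negbin``, ``truncnegbin``,
        ``gaussian``.
    exog_names : list of str, optional
        Column names for the design matrix.
    n_quad : int
        Number of Gauss-Hermite nodes (ignored for gaussian).
    """

    def __init__(self, endog, exog, groups, family="binomial",
                 exog_names=None, n_quad=15):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family_name = family
        self.family = FAMILIES[family]
        endog = np.asarray(endog, dtype=float).ravel()
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != endog.shape[0]:
            exog = exog.T
        groups = np.asarray(groups)
        if len(endog) == 0:
            raise ValueError("empty model data")
        if exog.shape[0] != len(endog) or len(groups) != len(endog):
            raise ValueError("endog, exog and groups must align")
        self.family.validate(endog)

        # sort by cluster so per-cluster sums can use reduceat
        order = np.argsort(groups, kind="stable")
        self.endog = endog[order]
        self.exog = exog[order]
        self.groups = groups[order]
        labels, idx = np.unique(self.groups, return_index=True)
        self.group_labels = labels
        self._starts = np.sort(idx)
        self._group_idx = np.searchsorted(self._starts, np.arange(len(endog)),
                                          side="right") - 1
        self.n_groups = len(labels)
        self.nobs = len(endog)
        self.k_exog = self.exog.shape[1]
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.k_exog)]
        )
        if len(self.exog_names) != self.k_exog:
            raise ValueError("exog_names length mismatch")
        self.n_quad = int(n_quad)
        t, w = special.roots_hermite(self.n_quad)
        self._gh_t = t
        self._gh_logw_t2 = np.log(w) + t * t
        self._warm_u = np.zeros(self.n_groups)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, predictor: str,
                       group: str = "participant_id", family: str = "binomial",
                       n_quad: int = 15) -> "MixedGLM":
        """Build the hybrid (within + between) model from a tidy table.

        The predictor column is person-mean centered; the design is
        ``[const, within, between]``.
        """
        d = data[[outcome, predictor, group]].dropna()
        if d.empty:
            raise ValueError("no complete rows for model")
        xw, xb = center_within(d[predictor], d[group])
        exog = np.column_stack([np.ones(len(d)), xw, xb])
        m = cls(d[outcome].to_numpy(), exog, d[group].to_numpy(),
                family=family, exog_names=["const", "within", "between"],
                n_quad=n_quad)
        m.predictor = predictor
        m.outcome = outcome
        return m

    # -- parameter vector layout: [beta, log sigma_u?, log aux?] -----------

    def _unpack(self, params, fix_sigma_u=None):
        k = self.k_exog
        beta = np.asarray(params[:k], dtype=float)
        pos = k
        if fix_sigma_u is None:
            sigma_u = float(np.exp(params[pos]))
            pos += 1
        else:
            sigma_u = float(fix_sigma_u)
        aux = tuple(np.exp(params[pos:pos + self.family.n_aux]))
        return beta, sigma_u, aux

    def _cluster_sum(self, values_2d):
        """Sum a (nobs, k) array within clusters -> (n_groups, k)."""
        return np.add.reduceat(values_2d, self._starts, axis=0)

    def loglike(self, params, fix_sigma_u=None) -> float:
        """Marginal log-likelihood at the given parameter vector."""
        beta, sigma_u, aux = self._unpack(params, fix_sigma_u)
        if self.family_name == "gaussian":
            return self._loglike_gaussian(beta, sigma_u, aux[0])
        eta0 = self.exog @ beta
        if sigma_u <= 1e-8:
            return float(np.sum(self.family.loglike_obs(self.endog, eta0, aux)))
        u_hat, curv = self._find_modes(eta0, sigma_u, aux)
        s2 = sigma_u * sigma_u
        tau = 1.0 / np.sqrt(-curv)
        # nodes per cluster: (G, K)
        u_nodes = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self._gh_t[None, :]
        eta = eta0[:, None] + u_nodes[self._group_idx, :]
        ll_obs = self.family.loglike_obs(self.endog[:, None], eta, aux)
        h = self._cluster_sum(ll_obs)  # (G, K)
        h += -0.5 * u_nodes**2 / s2 - 0.5 * np.log(2.0 * np.pi * s2)
        h += self._gh_logw_t2[None, :]
        m = np.max(h, axis=1)
        ll = m + np.log(np.sum(np.exp(h - m[:, None]), axis=1))
        ll += 0.5 * np.log(2.0) + np.log(tau)
        return float(np.sum(ll))

    def _find_modes(self, eta0, sigma_u, aux, tol=1e-9, maxiter=100):
        """Vectorised Newton for each cluster's integrand mode and curvature."""
        s2 = sigma_u * sigma_u
        u = self._warm_u.copy()
        y = self.endog
        ones = np.ones((len(y), 1))
        for _ in range(maxiter):
            eta = eta0 + u[self._group_idx]
            g = self._cluster_sum(self.family.d1(y, eta, aux)[:, None])[:, 0] - u / s2
            hcurv = self._cluster_sum(self.family.d2(y, eta, aux)[:, None])[:, 0] - 1.0 / s2
            step = g / hcurv
            np.clip(step, -4.0, 4.0, out=step)
            u -= step
            if np.max(np.abs(step)) < tol:
                break
        eta = eta0 + u[self._group_idx]
        curv = self._cluster_sum(self.family.d2(y, eta, aux)[:, None])[:, 0] - 1.0 / s2
        del ones
        self._warm_u = u.copy()
        return u, curv

    def _loglike_gaussian(self, beta, sigma_u, sigma_e) -> float:
        """Closed-form random-intercept LMM likelihood (compound symmetry)."""
        r = self.endog - self.exog @ beta
        s2e = max(sigma_e * sigma_e, 1e-300)
        s2u = sigma_u * sigma_u
        n_i = np.diff(np.append(self._starts, self.nobs))
        sum_r = self._cluster_sum(r[:, None])[:, 0]
        sum_r2 = self._cluster_sum((r * r)[:, None])[:, 0]
        denom = s2e + n_i * s2u
        logdet = (n_i - 1) * np.log(s2e) + np.log(denom)
        quad = sum_r2 / s2e - s2u * sum_r**2 / (s2e * denom)
        ll = -0.5 * (n_i * np.log(2.0 * np.pi) + logdet + quad)
        return float(np.sum(ll))

    # -- starting values ----------------------------------------------------

    def _start_params(self, fix_sigma_u):
        import statsmodels.api as sm

        y, X = self.endog, self.exog
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.family_name == "binomial":
                glm = sm.GLM(y, X, family=sm.families.Binomial())
            elif self.family_name == "gaussian":
                glm = sm.GLM(y, X, family=sm.families.Gaussian())
            else:
                glm = sm.GLM(y, X, family=sm.families.Poisson())
            try:
                beta = glm.fit(maxiter=100).params
            except Exception:
                beta = np.zeros(self.k_exog)
        parts = [np.asarray(beta, dtype=float)]
        if fix_sigma_u is None:
            parts.append([np.log(0.5)])
        if self.family_name == "gaussian":
            resid = y - X @ beta
            parts.append([np.log(max(np.std(resid), 1e-3))])
        elif self.family.n_aux == 1:  # negbin theta: method of moments
            mu = np.mean(y)
            v = np.var(y)
            theta0 = mu * mu / (v - mu) if v > mu else 10.0
            parts.append([np.log(np.clip(theta0, 0.1, 100.0))])
        return np.concatenate([np.atleast_1d(p) for p in parts])

    # -- fitting -------------------------------------------------------------

    def fit(self, start_params=None, fix_sigma_u=None, maxiter=200,
            gtol=1e-6) -> "MixedGLMResults":
        """Maximise the marginal likelihood; returns :class:`MixedGLMResults`.

        ``fix_sigma_u`` pins the random-intercept SD (0 gives the plain
        GLM).  A fitted sigma_u collapsing to the boundary is refitted
        with sigma_u = 0 and flagged.
        """
        from statsmodels.tools import numdiff

        if start_params is None:
            start_params = self._start_params(fix_sigma_u)
        start_params = np.asarray(start_params, dtype=float)

        def nll(p):
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                v = -self.loglike(p, fix_sigma_u=fix_sigma_u)
            return v if np.isfinite(v) else 1e12

        self._warm_u = np.zeros(self.n_groups)
        bounds = [(None, None)] * self.k_exog
        pos = self.k_exog
        if fix_sigma_u is None:
            bounds.append((np.log(1e-6), np.log(50.0)))
            pos += 1
        bounds.extend([(np.log(1e-4), np.log(1e6))] * (len(start_params) - pos))

        opt = optimize.minimize(
            nll, start_params, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        params = opt.x
        converged = bool(opt.success)
        message = str(opt.message)
        boundary = False

        if fix_sigma_u is None:
            sigma_u_hat = float(np.exp(params[self.k_exog]))
            if sigma_u_hat < 1e-3:  # indistinguishable from no cluster effect
                # boundary: random-intercept variance vanished; report the
                # plain-GLM fit with sigma_u = 0
                sub = np.delete(params, self.k_exog)
                res0 = self.fit(start_params=sub, fix_sigma_u=0.0,
                                maxiter=maxiter, gtol=gtol)
                res0.boundary_sigma_u = True
                res0.message += " (sigma_u at boundary; refit with sigma_u=0)"
                return res0

        # observed information on the working parameter scale
        with np.errstate(all="ignore"):
            hess = numdiff.approx_hess(params, nll)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        diag = np.diag(cov).copy()
        if np.any(diag <= 0):
            warnings.warn("non-positive-definite information; SEs unreliable",
                          stacklevel=2)
            diag[diag <= 0] = np.nan
            converged = converged and False
        bse = np.sqrt(diag)

        beta, sigma_u, aux = self._unpack(params, fix_sigma_u)
        k_params = len(params)
        llf = -nll(params)
        return MixedGLMResults(
            model=self, params_all=params, cov_all=cov, bse_all=bse,
            beta=beta, sigma_u=sigma_u, aux=aux,
            fixed_sigma_u=fix_sigma_u, llf=llf, k_params=k_params,
            converged=converged, boundary_sigma_u=boundary, message=message,
            n_iter=int(opt.nit),
        )


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


class MixedGLMResults:
    """Fit of a :class:`MixedGLM`.

    Attributes
    ----------
    params : pandas.Series
        Fixed-effect estimates, named.
    bse : pandas.Series
        Standard errors of the fixed effects (inverse observed information).
    sigma_u : float
        Random-intercept SD on the link scale.
    theta : float or None
        NB2 dispersion (count families).
    scale : float or None
        Residual SD (gaussian family).
    llf, aic : float
        Marginal log-likelihood and 2k - 2*llf.
    """

    def __init__(self, model, params_all, cov_all, bse_all, beta, sigma_u, aux,
                 fixed_sigma_u, llf, k_params, converged, boundary_sigma_u,
                 message, n_iter):
        self.model = model
        self.family = model.family_name
        self.params_all = params_all
        self.cov_all = cov_all
        k = model.k_exog
        self.params = pd.Series(beta, index=model.exog_names)
        self.bse = pd.Series(bse_all[:k], index=model.exog_names)
        self.cov_params = pd.DataFrame(cov_all[:k, :k], index=model.exog_names,
                                       columns=model.exog_names)
        self.sigma_u = sigma_u
        self.fixed_sigma_u = fixed_sigma_u
        if model.family_name == "gaussian":
            self.scale = aux[0] if aux else None
            self.theta = None
        else:
            self.scale = None
            self.theta = aux[0] if aux else None
        self.llf = llf
        self.k_params = k_params
        self.aic = 2.0 * k_params - 2.0 * llf
        self.nobs = model.nobs
        self.n_groups = model.n_groups
        self.converged = converged
        self.boundary_sigma_u = boundary_sigma_u
        self.message = message
        self.n_iter = n_iter
        self.n_quad = model.n_quad

    def tvalues(self):
        return self.params / self.bse

    def pvalues(self):
        z = np.abs(self.params / self.bse)
        return pd.Series(2.0 * stats.norm.sf(z), index=self.params.index)

    def conf_int(self, alpha=0.05):
        zc = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - zc * self.bse
        hi = self.params + zc * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def to_dict(self) -> dict:
        """JSON-serialisable record of the fit."""
        return {
            "family": self.family,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "cov_params": self.cov_params.to_numpy().tolist(),
            "sigma_u": self.sigma_u,
            "theta": self.theta,
            "scale": self.scale,
            "llf": self.llf,
            "aic": self.aic,
            "nobs": int(self.nobs),
            "n_groups": int(self.n_groups),
            "converged": bool(self.converged),
            "boundary_sigma_u": bool(self.boundary_sigma_u),
            "n_quad": int(self.n_quad),
        }

    def summary(self) -> str:
        ci = self.conf_int()
        p = self.pvalues()
        lines = [
            "Random-intercept GLMM (adaptive Gauss-Hermite quadrature)",
            f"Family: {self.family}   obs: {self.nobs}   clusters: {self.n_groups}",
            f"logLik: {self.llf:.3f}   AIC: {self.aic:.3f}   "
            f"converged: {self.converged}",
            f"sigma_u: {self.sigma_u:.4f}"
            + (f"   theta: {self.theta:.4f}" if self.theta is not None else "")
            + (f"   resid SD: {self.scale:.4f}" if self.scale is not None else ""),
            "-" * 72,
            f"{'':<12}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>9}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.params.index:
            b, se = self.params[name], self.bse[name]
            z = b / se if se > 0 else np.nan
            lines.append(
                f"{name:<12}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p[name]:>9.3g}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        return "\n".join(lines)

    def __repr__(self):
        return (f"<MixedGLMResults family={self.family} nobs={self.nobs} "
                f"llf={self.llf:.2f} aic={self.aic:.2f}>")


# ---------------------------------------------------------------------------
# Convenience: one-call fit, family selection, effect summaries
# ---------------------------------------------------------------------------


def fit_glmm(data: pd.DataFrame, outcome: str, predictor: str,
             group: str = "participant_id", family: str = "binomial",
             n_quad: int = 15, **fit_kwargs) -> MixedGLMResults:
    """Fit the hybrid within/between random-intercept GLMM from a tidy table."""
    model = MixedGLM.from_dataframe(data, outcome, predictor, group,
                                    family=family, n_quad=n_quad)
    return model.fit(**fit_kwargs)


#: AIC tie-break preference for the count part.
FAMILY_TIE_ORDER = ("negbin", "poisson", "gaussian")


def select_family(fits) -> MixedGLMResults:
    """Pick the count-model family with the lowest AIC.

    ``fits`` maps family name -> MixedGLMResults (or is a list of results).
    Non-converged candidates are excluded with a warning; exact AIC ties go
    to the first family in the order negbin, poisson, gaussian, with a
    warning.
    """
    if isinstance(fits, dict):
        items = list(fits.values())
    else:
        items = list(fits)
    usable = []
    for r in items:
        if r.converged:
            usable.append(r)
        else:
            warnings.warn(f"excluding non-converged {r.family} candidate",
                          stacklevel=2)
    if not usable:
        raise RuntimeError("no converged candidate model")
    best_aic = min(r.aic for r in usable)
    tied = [r for r in usable if r.aic <= best_aic + 1e-9]
    if len(tied) > 1:
        warnings.warn("AIC tie between candidate families; using tie order",
                      stacklevel=2)
        order = {f: i for i, f in enumerate(FAMILY_TIE_ORDER)}
        tied.sort(key=lambda r: order.get(r.family, 99))
    return tied[0]


@dataclass(frozen=True)
class EffectSummary:
    """Exponentiated effect with Wald CI, as reported in the results table."""

    scale: str  # "OR" (logistic part) or "expB" (count part)
    coef: float
    se: float
    point: float
    ci_low: float
    ci_high: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def summarize_effect(results: MixedGLMResults, coefficient: str = "within",
                     scale: str = "OR", alpha: float = 0.05) -> EffectSummary:
    """Exponentiate a coefficient and its Wald CI; two-sided normal p."""
    b = float(results.params[coefficient])
    se = float(results.bse[coefficient])
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    z = b / se if se > 0 else np.inf * np.sign(b)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return EffectSummary(
        scale=scale, coef=b, se=se, point=float(np.exp(b)),
        ci_low=float(np.exp(b - zc * se)), ci_high=float(np.exp(b + zc * se)),
        p=p,
    )
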