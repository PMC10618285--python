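"""Laplace-approximate maximum-likelihood mixed models.

Fits generalized linear mixed models with one grouping factor (participant)
and a random structure of either a random intercept or a random intercept
plus a random time slope:

    eta_ij = x_ij' beta + z_ij' b_i,   b_i ~ N(0, Sigma)

for binomial (logit link, proportion response with integer trial weights),
Poisson (log link) and gaussian (identity link) families. The marginal
likelihood is approximated by the Laplace method: the random-effect modes
``b_i`` are found by a vectorized per-group Newton solve, and the Gaussian
curvature correction ``-1/2 log det(Sigma H_i)`` is added per group. The
gaussian family is fitted by ML (not REML), so AIC values are comparable
across random structures and with the GLMM families.

Sigma is parametrized by its Cholesky factor with log-transformed diagonal,
so the outer optimization (scipy L-BFGS-B over fixed effects and covariance
parameters jointly) is unconstrained. Standard errors come from the inverse
of the numerically differentiated Hessian of the Laplace log-likelihood.

With ``random=None`` the model collapses to an ordinary weighted GLM fitted
by the same machinery — the exact zero-variance limit of the mixed fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

FAMILIES = ("binomial", "poisson", "gaussian")
RANDOM_STRUCTURES = (None, "intercept", "intercept_slope")

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedGLMResult:
    """Fitted mixed model: coefficients, tests, likelihood and variance parts."""

    family: str
    random_structure: str | None
    fixed_names: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    theta: np.ndarray
    Sigma: np.ndarray | None
    sigma_e: float | None
    df_resid: int
    stat_name: str  # "z" (binomial/poisson) or "t" (gaussian)
    random_modes: np.ndarray | None = None

    @property
    def statistics(self) -> np.ndarray:
        return self.beta / self.beta_se

    @property
    def pvalues(self) -> np.ndarray:
        s = self.statistics
        if self.stat_name == "z":
            return 2.0 * stats.norm.sf(np.abs(s))
        return 2.0 * stats.t.sf(np.abs(s), df=self.df_resid)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.fixed_names,
                "B": self.beta,
                "SE": self.beta_se,
                self.stat_name: self.statistics,
                "p": self.pvalues,
            }
        )

    @property
    def variance_components(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.Sigma is not None:
            out["var_intercept"] = float(self.Sigma[0, 0])
            if self.Sigma.shape[0] > 1:
                out["var_slope"] = float(self.Sigma[1, 1])
                out["cov_intercept_slope"] = float(self.Sigma[0, 1])
        if self.sigma_e is not None:
            out["var_residual"] = float(self.sigma_e**2)
        return out


class _Problem:
    """Preassembled arrays for one fit; owns the Laplace objective."""

    def __init__(self, X, y, group_idx, family, weights, slope, random):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.g = np.asarray(group_idx, dtype=int)
        self.family = family
        self.w = (
            np.ones_like(self.y) if weights is None else np.asarray(weights, float)
        )
        self.n, self.p = self.X.shape
        self.G = int(self.g.max()) + 1 if self.n else 0
        self.random = random
        if random == "intercept":
            self.q = 1
            self.Z = np.ones((self.n, 1))
        elif random == "intercept_slope":
            self.q = 2
            if slope is None:
                raise ValueError("intercept_slope structure needs slope values")
            self.Z = np.column_stack([np.ones(self.n), np.asarray(slope, float)])
        elif random is None:
            self.q = 0
            self.Z = np.zeros((self.n, 0))
        else:
            raise ValueError(f"unknown random structure {random!r}")
        self.n_theta = {0: 0, 1: 1, 2: 3}[self.q]
        self.has_sigma_e = family == "gaussian"
        self.n_params = self.p + self.n_theta + (1 if self.has_sigma_e else 0)
        self.b = np.zeros((self.G, self.q))  # warm-started modes
        if family == "binomial":
            k = np.round(self.w * self.y)
            self.const = float(
                np.sum(
                    special.gammaln(self.w + 1)
                    - special.gammaln(k + 1)
                    - special.gammaln(self.w - k + 1)
                )
            )
        elif family == "poisson":
            self.const = float(-np.sum(special.gammaln(self.y + 1)))
        else:
            self.const = 0.0

    # -- family kernels ----------------------------------------------------
    def _loglik_rows(self, eta, sigma_e):
        y, w = self.y, self.w
        if self.family == "binomial":
            mu = np.clip(_expit(eta), 1e-12, 1.0 - 1e-12)
            return w * (y * np.log(mu) + (1.0 - y) * np.log1p(-mu))
        if self.family == "poisson":
            return y * eta - np.exp(eta)
        r = y - eta
        return -0.5 * (r * r) / sigma_e**2 - 0.5 * np.log(sigma_e**2) - 0.5 * _LOG2PI

    def _score_weight_rows(self, eta, sigma_e):
        """Per-row dl/deta and -d2l/deta2."""
        y, w = self.y, self.w
        if self.family == "binomial":
            mu = _expit(eta)
            return w * (y - mu), w * mu * (1.0 - mu)
        if self.family == "poisson":
            mu = np.exp(eta)
            return y - mu, mu
        inv = 1.0 / sigma_e**2
        return (y - eta) * inv, np.full_like(eta, inv)

    # -- covariance parametrization ----------------------------------------
    def _chol(self, theta):
        if self.q == 1:
            return np.array([[np.exp(theta[0])]])
        L = np.zeros((2, 2))
        L[0, 0] = np.exp(theta[0])
        L[1, 0] = theta[1]
        L[1, 1] = np.exp(theta[2])
        return L

    def split_params(self, params):
        beta = params[: self.p]
        theta = params[self.p : self.p + self.n_theta]
        sigma_e = np.exp(params[-1]) if self.has_sigma_e else 1.0
        return beta, theta, sigma_e

    # -- inner Newton solve for the modes -----------------------------------
    def _inner(self, beta, Sigma_inv, sigma_e, max_iter=60, tol=1e-11):
        # non-finite intermediates (overflow at extreme outer proposals,
        # singular per-group Hessians) are caught below and signalled as None
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            return self._inner_impl(beta, Sigma_inv, sigma_e, max_iter, tol)

    def _inner_impl(self, beta, Sigma_inv, sigma_e, max_iter, tol):
        Xb = self.X @ beta
        b = self.b
        g = self.g
        Z = self.Z
        for _ in range(max_iter):
            eta = Xb + np.einsum("ij,ij->i", Z, b[g])
            u, W = self._score_weight_rows(eta, sigma_e)
            # gradient per group: sum_rows Z*u - Sigma_inv b
            Gu = np.column_stack(
                [np.bincount(g, weights=Z[:, j] * u, minlength=self.G)
                 for j in range(self.q)]
            )
            grad = Gu - b @ Sigma_inv
            # per-group Hessian H = sum W z z' + Sigma_inv
            if self.q == 1:
                h11 = np.bincount(g, weights=W, minlength=self.G) + Sigma_inv[0, 0]
                step = grad[:, 0] / h11
                step = step[:, None]
            else:
                z1, z2 = Z[:, 0], Z[:, 1]
                h11 = np.bincount(g, weights=W * z1 * z1, minlength=self.G) + Sigma_inv[0, 0]
                h12 = np.bincount(g, weights=W * z1 * z2, minlength=self.G) + Sigma_inv[0, 1]
                h22 = np.bincount(g, weights=W * z2 * z2, minlength=self.G) + Sigma_inv[1, 1]
                det = h11 * h22 - h12 * h12
                step = np.column_stack(
                    [(h22 * grad[:, 0] - h12 * grad[:, 1]) / det,
                     (h11 * grad[:, 1] - h12 * grad[:, 0]) / det]
                )
            if not np.all(np.isfinite(step)):
                self.b = np.zeros_like(b)
                return None
            b = b + step
            if np.max(np.abs(step)) < tol:
                break
        self.b = b
        eta = Xb + np.einsum("ij,ij->i", Z, b[g])
        u, W = self._score_weight_rows(eta, sigma_e)
        if self.q == 1:
            h11 = np.bincount(g, weights=W, minlength=self.G) + Sigma_inv[0, 0]
            logdet_H = np.log(h11)
        else:
            z1, z2 = Z[:, 0], Z[:, 1]
            h11 = np.bincount(g, weights=W * z1 * z1, minlength=self.G) + Sigma_inv[0, 0]
            h12 = np.bincount(g, weights=W * z1 * z2, minlength=self.G) + Sigma_inv[0, 1]
            h22 = np.bincount(g, weights=W * z2 * z2, minlength=self.G) + Sigma_inv[1, 1]
            logdet_H = np.log(h11 * h22 - h12 * h12)
        return b, eta, logdet_H

    # -- Laplace negative log-likelihood -------------------------------------
    def neg_loglik(self, params):
        beta, theta, sigma_e = self.split_params(params)
        if self.q == 0:
            eta = self.X @ beta
            return -(float(np.sum(self._loglik_rows(eta, sigma_e))) + self.const)
        L = self._chol(theta)
        Sigma = L @ L.T
        try:
            Sigma_inv = np.linalg.inv(Sigma)
            _, logdet_Sigma = np.linalg.slogdet(Sigma)
        except np.linalg.LinAlgError:
            return np.inf
        inner = self._inner(beta, Sigma_inv, sigma_e)
        if inner is None:
            return np.inf
        b, eta, logdet_H = inner
        ll_rows = float(np.sum(self._loglik_rows(eta, sigma_e)))
        quad = float(np.einsum("ij,jk,ik->", b, Sigma_inv, b))
        ll = (
            ll_rows
            - 0.5 * quad
            - 0.5 * self.G * logdet_Sigma
            - 0.5 * float(np.sum(logdet_H))
            + self.const
        )
        if not np.isfinite(ll):
            return np.inf
        return -ll


def _expit(x):
    return special.expit(x)


def fit_mixed_glm(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    *,
    family: str,
    weights: np.ndarray | None = None,
    random: str | None = "intercept",
    slope: np.ndarray | None = None,
    fixed_names: list[str] | None = None,
    start_beta: np.ndarray | None = None,
) -> MixedGLMResult:
    """Fit one mixed model (or its fixed-effects-only limit).

    Parameters
    ----------
    X : (n, p) fixed-effects design matrix (include the intercept column).
    y : response — proportions (binomial), counts (poisson) or continuous.
    group_idx : integer group codes ``0..G-1`` (the participant factor).
    family : "binomial" | "poisson" | "gaussian".
    weights : binomial trial counts per row (required for binomial).
    random : None (ordinary GLM limit, random variance fixed at zero),
        "intercept", or "intercept_slope".
    slope : per-row random-slope regressor (the post-test indicator) when
        ``random="intercept_slope"``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "binomial":
        if weights is None:
            raise ValueError("binomial fits need trial weights")
        w = np.asarray(weights, dtype=float)
        if np.any(np.abs(w - np.round(w)) > 1e-9) or np.any(w <= 0):
            raise ValueError("binomial weights must be positive integers")
    prob = _Problem(X, y, group_idx, family, weights, slope, random)
    p = prob.p
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(p)]

    if start_beta is None:
        start_beta = _glm_start(prob)
    x0 = np.zeros(prob.n_params)
    x0[:p] = start_beta
    if prob.n_theta:
        x0[p] = np.log(0.3)
        if prob.n_theta == 3:
            x0[p + 2] = np.log(0.3)
    if prob.has_sigma_e:
        resid = prob.y - prob.X @ start_beta
        x0[-1] = 0.5 * np.log(max(float(np.mean(resid**2)), 1e-8))

    res = optimize.minimize(
        prob.neg_loglik, x0, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    params = res.x
    converged = bool(res.success)
    if not converged:
        # L-BFGS-B reports line-search failure when started at (or driven
        # very near) the optimum; accept stationary points on gradient norm
        grad = optimize.approx_fprime(params, prob.neg_loglik, 1e-6)
        converged = bool(np.max(np.abs(grad)) < 5e-3)
    loglik = -float(res.fun)
    k = prob.n_params
    aic = 2.0 * k - 2.0 * loglik

    hess = approx_hess1(params, prob.neg_loglik)
    cov = _safe_inv(hess)
    cov_beta = cov[:p, :p]
    beta_se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    beta, theta, sigma_e = prob.split_params(params)
    Sigma = None
    if prob.q:
        L = prob._chol(theta)
        Sigma = L @ L.T
    return MixedGLMResult(
        family=family,
        random_structure=random,
        fixed_names=list(fixed_names),
        beta=beta.copy(),
        beta_se=beta_se,
        cov_beta=cov_beta,
        loglik=loglik,
        aic=aic,
        n_obs=prob.n,
        n_groups=prob.G,
        converged=converged,
        theta=theta.copy(),
        Sigma=Sigma,
        sigma_e=float(sigma_e) if prob.has_sigma_e else None,
        df_resid=prob.n - p,
        stat_name="t" if family == "gaussian" else "z",
        random_modes=prob.b.copy() if prob.q else None,
    )


def _glm_start(prob: _Problem) -> np.ndarray:
    """Cheap fixed-effects starting values via a few IRLS steps."""
    X, y, w = prob.X, prob.y, prob.w
    beta = np.zeros(prob.p)
    if prob.family == "gaussian":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    # initialize intercept from the mean response
    if prob.family == "binomial":
        mean = min(max(float(np.average(y, weights=w)), 1e-4), 1 - 1e-4)
        beta[0] = np.log(mean / (1 - mean))
    else:
        beta[0] = np.log(max(float(np.mean(y)), 1e-4))
    for _ in range(25):
        eta = X @ beta
        u, W = prob._score_weight_rows(eta, 1.0)
        XtW = X.T * W
        try:
            step = np.linalg.solve(XtW @ X, X.T @ u)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _safe_inv(h: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(h)
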