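"""Random-intercept mixed models: linear (profiled ML) and logistic (adaptive GHQ).

Both models share the structure of repeated menstrual cycles nested in women:

    gaussian:  y_ij = x_ij' beta + u_i + eps_ij,  u_i ~ N(0, sigma_u^2),
               eps_ij ~ N(0, sigma_e^2)
    binomial:  logit P(y_ij = 1 | u_i) = x_ij' beta + u_i

The linear model is fitted by maximum likelihood with the variance ratio
theta = sigma_u^2 / sigma_e^2 profiled out: for fixed theta, beta and
sigma_e^2 have closed GLS forms, leaving a one-dimensional deterministic
optimization.

The logistic model's per-woman marginal likelihood integral

    L_i = int prod_j p_ij(u)^{y_ij} (1 - p_ij(u))^{1 - y_ij} phi(u; 0, sigma_u^2) du

is evaluated by *adaptive* Gauss-Hermite quadrature: nodes are recentred at
the per-group posterior mode and rescaled by the curvature there.  Clusters
here are tiny (1-3 cycles per woman), where a plain Laplace approximation is
noticeably inaccurate; adaptive quadrature with 15 points is essentially
exact.  Standard errors are Wald, from the numerically differentiated
observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logsumexp

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ConvergenceError",
    "fit_lmm_ri",
    "fit_logistic_ri",
    "wald_summary",
    "predict_marginal",
]

INTERCEPT = "(Intercept)"


class ConvergenceError(RuntimeError):
    """Raised when inference is requested from an unconverged fit."""


@dataclass(frozen=True)
class ModelSpec:
    """A model formula: response ~ fixed_terms + (1 | group)."""

    response: str
    fixed_terms: tuple[str, ...] = ()
    group: str = "woman_id"
    family: str = "gaussian"

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"family must be gaussian or binomial, got {self.family}")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))


@dataclass
class ModelFit:
    """Fixed effects, variance components and likelihood of a fitted model."""

    spec: ModelSpec
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma_u: float
    sigma_e: float | None
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    message: str = ""
    quad_points: int | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.se, index=self.names)


def _design(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    missing = [c for c in (spec.response, spec.group, *spec.fixed_terms) if c not in data.columns]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    sub = data[[spec.response, spec.group, *spec.fixed_terms]].dropna()
    y = sub[spec.response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[t].to_numpy(dtype=float) for t in spec.fixed_terms]
    )
    gidx, _ = pd.factorize(sub[spec.group], sort=True)
    names = [INTERCEPT, *spec.fixed_terms]
    return y, X, gidx.astype(np.int64), names


# ---------------------------------------------------------------------------
# Linear mixed model, profiled maximum likelihood
# ---------------------------------------------------------------------------

def _lmm_profile(theta: float, y, X, gidx, G, XtX, Xty, yty):
    """Profile log-likelihood pieces at variance ratio theta >= 0."""
    n_i = np.bincount(gidx, minlength=G).astype(float)
    c = theta / (1.0 + theta * n_i)          # V_i^{-1} = I - c_i * J
    SX = np.zeros((G, X.shape[1]))
    for j in range(X.shape[1]):
        SX[:, j] = np.bincount(gidx, weights=X[:, j], minlength=G)
    Sy = np.bincount(gidx, weights=y, minlength=G)
    A = XtX - (SX * c[:, None]).T @ SX
    b = Xty - SX.T @ (c * Sy)
    beta = np.linalg.solve(A, b)
    r = y - X @ beta
    Sr = np.bincount(gidx, weights=r, minlength=G)
    quad = float(r @ r - np.sum(c * Sr**2))
    N = len(y)
    sigma_e2 = quad / N
    logdet = float(np.sum(np.log1p(theta * n_i)))
    ll = -0.5 * N * (np.log(2 * np.pi * sigma_e2) + 1.0) - 0.5 * logdet
    return ll, beta, sigma_e2, A


def fit_lmm_ri(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """ML fit of the gaussian random-intercept model.

    The variance ratio is profiled and maximized by deterministic bounded
    scalar optimization (tolerance 1e-8 on the profile objective); singleton
    groups are allowed.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm_ri requires family='gaussian'")
    y, X, gidx, names = _design(spec, data)
    if np.var(y) == 0:
        raise ValueError("response has zero variance; model is degenerate")
    G = int(gidx.max()) + 1
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)

    def neg_profile(s: float) -> float:
        return -_lmm_profile(np.exp(s), y, X, gidx, G, XtX, Xty, yty)[0]

    res = minimize_scalar(
        neg_profile, bounds=(-30.0, 12.0), method="bounded",
        options={"xatol": 1e-10, "maxiter": 2000},
    )
    # the boundary sigma_u = 0 is at s -> -inf; compare explicitly
    s_hat = float(res.x)
    if neg_profile(-30.0) <= res.fun:
        s_hat = -30.0
    theta = float(np.exp(s_hat))
    ll, beta, sigma_e2, A = _lmm_profile(theta, y, X, gidx, G, XtX, Xty, yty)
    # convergence = verified local optimality of the profile objective, not
    # the optimizer's flag (the bounded method reports failure on very flat
    # profiles it has in fact solved)
    tol = 1e-8 * (1.0 + abs(ll))
    at_opt = all(
        -_lmm_profile(np.exp(s_hat + d), y, X, gidx, G, XtX, Xty, yty)[0]
        >= -ll - tol
        for d in (-1e-4, 1e-4)
        if -30.0 <= s_hat + d <= 12.0
    )
    vcov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(vcov))
    sigma_u = float(np.sqrt(theta * sigma_e2))
    if theta <= np.exp(-29.0):
        sigma_u = 0.0
    return ModelFit(
        spec=spec, names=names, beta=beta, se=se, vcov=vcov,
        sigma_u=sigma_u, sigma_e=float(np.sqrt(sigma_e2)), loglik=float(ll),
        n_obs=len(y), n_groups=G, converged=bool(res.success or at_opt),
        message="" if (res.success or at_opt) else str(getattr(res, "message", "")),
    )


# ---------------------------------------------------------------------------
# Logistic random-intercept model, adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _log1pexp(x):
    return np.logaddexp(0.0, x)


def _irls_logistic(X, y, max_iter=100, tol=1e-10):
    """Plain logistic regression by iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
        if np.max(np.abs(beta)) > 1e3:
            break
    return beta


def _glmm_loglik(params, y, X, gidx, G, z_nodes, log_w):
    """Marginal log-likelihood of the logistic RI model via adaptive GHQ.

    Vectorized across groups: the per-group posterior mode is found by a
    damped Newton iteration on the whole vector of group effects at once.
    """
    beta, ls = params[:-1], params[-1]
    sigma = float(np.exp(ls))
    eta0 = X @ beta
    if sigma < 1e-8:
        ll = float(np.sum(y * eta0 - _log1pexp(eta0)))
        return ll
    inv_s2 = 1.0 / sigma**2
    u = np.zeros(G)
    for _ in range(200):
        eta = eta0 + u[gidx]
        p = expit(eta)
        grad = np.bincount(gidx, weights=y - p, minlength=G) - u * inv_s2
        hess = -(np.bincount(gidx, weights=p * (1 - p), minlength=G) + inv_s2)
        step = -grad / hess
        step = np.clip(step, -5.0, 5.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[gidx]
    p = expit(eta)
    h = np.bincount(gidx, weights=p * (1 - p), minlength=G) + inv_s2  # -g''(u_hat)
    scale = np.sqrt(2.0 / h)                                          # (G,)
    # node grid: u_hat + scale * z_k, shape (K, G)
    U = u[None, :] + scale[None, :] * z_nodes[:, None]
    eta_k = eta0[None, :] + U[:, gidx]
    ll_rows = y[None, :] * eta_k - _log1pexp(eta_k)
    group_ll = np.stack(
        [np.bincount(gidx, weights=row, minlength=G) for row in ll_rows]
    )
    log_prior = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * U**2 * inv_s2
    a = group_ll + log_prior + z_nodes[:, None] ** 2 + log_w[:, None]
    log_Li = np.log(scale) + logsumexp(a, axis=0)
    if not np.all(np.isfinite(log_Li)):
        bad = int(np.flatnonzero(~np.isfinite(log_Li))[0])
        raise FloatingPointError(f"quadrature failed for group index {bad}")
    return float(np.sum(log_Li))


def _numeric_hessian(f, x, h_rel=1e-4):
    """Central-difference Hessian of scalar f at x."""
    k = len(x)
    h = h_rel * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_logistic_ri(
    spec: ModelSpec,
    data: pd.DataFrame,
    quad_points: int = 15,
    sigma_u_fixed: float | None = None,
) -> ModelFit:
    """ML fit of the logistic random-intercept model by adaptive GHQ.

    Optimized over (beta, log sigma_u) with L-BFGS-B (tolerance 1e-8,
    max 500 iterations), initialized from a plain logistic fit with
    sigma_u = 1.  Apparent complete separation is flagged, never silently
    reported as converged.

    ``sigma_u_fixed`` pins the random-intercept SD instead of estimating it
    (0 collapses the model to plain logistic regression); useful for
    degenerate designs such as singleton-only groups, where (beta, sigma_u)
    are jointly identified only through a nearly flat likelihood ridge.
    """
    if spec.family != "binomial":
        raise ValueError("fit_logistic_ri requires family='binomial'")
    if quad_points < 7:
        raise ValueError("quad_points must be >= 7")
    y, X, gidx, names = _design(spec, data)
    bad = set(np.unique(y)) - {0.0, 1.0}
    if bad:
        raise ValueError(f"binomial response must be 0/1, found {sorted(bad)}")
    G = int(gidx.max()) + 1
    z_nodes, w = np.polynomial.hermite.hermgauss(quad_points)
    log_w = np.log(w)

    beta0 = _irls_logistic(X, y)
    separated = bool(np.max(np.abs(beta0)) > 15)
    if sigma_u_fixed is not None:
        if sigma_u_fixed < 0:
            raise ValueError("sigma_u_fixed must be >= 0")
        ls_fix = float(np.log(max(sigma_u_fixed, 1e-12)))
        x0 = np.concatenate([beta0, [ls_fix]])
        bounds = [(None, None)] * X.shape[1] + [(ls_fix, ls_fix)]
    else:
        x0 = np.concatenate([beta0, [0.0]])  # log sigma_u = 0 -> sigma_u = 1
        bounds = [(None, None)] * X.shape[1] + [(-10.0, 3.0)]

    def nll(params):
        return -_glmm_loglik(params, y, X, gidx, G, z_nodes, log_w)
    res = minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and sigma_u_fixed is None:
        # finite-difference gradients can abort the line search on flat
        # likelihoods; polish derivative-free from the best point found
        polish = minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-10},
        )
        if polish.fun <= res.fun:
            polish.x[-1] = np.clip(polish.x[-1], -10.0, 3.0)
            res = polish
    beta = res.x[:-1]
    ls = float(res.x[-1])
    sigma_u = float(np.exp(ls))
    at_floor = ls <= -9.5
    if at_floor:
        # at the boundary the marginal model *is* plain logistic regression,
        # whose MLE is computed exactly by IRLS rather than taken from the
        # last quasi-Newton iterate
        sigma_u = 0.0
        beta = _irls_logistic(X, y)
        eta = X @ beta
        res.fun = -float(np.sum(y * eta - _log1pexp(eta)))
        res.x = np.concatenate([beta, [res.x[-1]]])

    converged = bool(res.success) and not separated and np.all(np.abs(beta) < 15)
    message = str(res.message)
    if separated or np.any(np.abs(beta) >= 15):
        message = (
            "possible complete separation: a fixed-effect estimate diverged; "
            + message
        )

    # observed information; drop the sigma_u direction when it is fixed or
    # pinned at the boundary
    if at_floor or sigma_u_fixed is not None:
        ls_eval = ls if sigma_u_fixed is not None else -10.0

        def nll_beta(b):
            return nll(np.concatenate([b, [ls_eval]]))

        H = _numeric_hessian(nll_beta, beta)
        vcov = np.linalg.inv(H)
    else:
        H = _numeric_hessian(nll, res.x)
        try:
            vcov = np.linalg.inv(H)[: len(beta), : len(beta)]
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)[: len(beta), : len(beta)]
    diag = np.diag(vcov).copy()
    if np.any(diag <= 0):
        converged = False
        message = "non-positive-definite observed information; " + message
        diag = np.abs(diag)
    se = np.sqrt(diag)

    return ModelFit(
        spec=spec, names=names, beta=beta, se=se, vcov=vcov,
        sigma_u=sigma_u, sigma_e=None, loglik=float(-res.fun),
        n_obs=len(y), n_groups=G, converged=converged, message=message,
        quad_points=quad_points,
    )


def glmm_loglik_at(
    fit_or_params, y, X, gidx, quad_points: int = 15
) -> float:
    """Evaluate the AGQ marginal log-likelihood at given (beta, log sigma_u).

    Exposed so the likelihood surface can be inspected and cross-checked
    against direct numerical integration.
    """
    params = (
        np.concatenate([fit_or_params.beta, [np.log(max(fit_or_params.sigma_u, 1e-12))]])
        if isinstance(fit_or_params, ModelFit)
        else np.asarray(fit_or_params, dtype=float)
    )
    gidx = np.asarray(gidx, dtype=np.int64)
    G = int(gidx.max()) + 1
    z_nodes, w = np.polynomial.hermite.hermgauss(quad_points)
    return _glmm_loglik(params, np.asarray(y, float), np.asarray(X, float), gidx, G, z_nodes, np.log(w))


# ---------------------------------------------------------------------------
# Wald inference and population-level prediction
# ---------------------------------------------------------------------------

def wald_summary(
    fit: ModelFit, level: float = 0.95, exponentiate: bool = False
) -> pd.DataFrame:
    """Estimates, Wald CIs and two-sided normal p-values, one row per term.

    With ``exponentiate`` the estimate and CI endpoints are mapped to the
    odds-ratio scale; the standard error stays on the log-odds scale, as
    conventionally reported.
    """
    if not fit.converged:
        raise ConvergenceError(f"fit did not converge: {fit.message}")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    est = fit.beta.copy()
    lo = est - z * fit.se
    hi = est + z * fit.se
    with np.errstate(divide="ignore"):
        pvals = 2 * norm.sf(np.abs(est / fit.se))
    if exponentiate:
        est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
    return pd.DataFrame(
        {"estimate": est, "ci_low": lo, "ci_high": hi, "se": fit.se, "p": pvals},
        index=fit.names,
    )


def predict_marginal(fit: ModelFit, newdata: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Population-level predictions at u_i = 0, with delta-method intervals.

    Gaussian: the linear predictor.  Binomial: the probability at the random
    intercept's conditional mode u = 0 (not the population-averaged
    probability, which is attenuated by sigma_u); intervals are computed on
    the linear predictor and transformed.
    """
    if not fit.converged:
        raise ConvergenceError(f"fit did not converge: {fit.message}")
    from scipy.stats import norm

    missing = [t for t in fit.spec.fixed_terms if t not in newdata.columns]
    if missing:
        raise KeyError(f"newdata lacks model columns: {missing}")
    X = np.column_stack(
        [np.ones(len(newdata))]
        + [newdata[t].to_numpy(dtype=float) for t in fit.spec.fixed_terms]
    )
    eta = X @ fit.beta
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.vcov, X))
    z = norm.ppf(0.5 + level / 2)
    lo, hi = eta - z * se_eta, eta + z * se_eta
    if fit.spec.family == "binomial":
        pred = expit(eta)
        se_pred = pred * (1 - pred) * se_eta
        lo, hi = expit(lo), expit(hi)
    else:
        pred, se_pred = eta, se_eta
    return pd.DataFrame(
        {"predicted": pred, "se": se_pred, "ci_low": lo, "ci_high": hi},
        index=newdata.index,
    )
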