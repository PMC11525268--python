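"""Binomial (logit) mixed model with a per-participant random intercept.

The marginal likelihood integrates each participant's Bernoulli/binomial
likelihood over a Gaussian random intercept,

    L_i(beta, sigma_u) = ∫ Π_j p_ij(u)^y_ij (1-p_ij(u))^(n_ij-y_ij)
                           φ(u; 0, sigma_u²) du,
    logit p_ij(u) = x_ij' beta + u,

by adaptive Gauss–Hermite quadrature: the integrand is re-centred at its
mode (found by a vectorised per-participant Newton iteration) and scaled
by the curvature there, so a modest number of nodes is accurate even for
large clusters.  One node reproduces the Laplace approximation.

The log-likelihood omits binomial coefficients, so fitting counts
aggregated by identical covariate rows gives exactly the trial-level
Bernoulli log-likelihood — AICc bookkeeping therefore uses the number of
Bernoulli trials as the sample size.

Estimation maximises the marginal likelihood over (beta, log sigma_u)
with L-BFGS-B; the coefficient covariance is the inverse observed
information (numerical Hessian) at the optimum.  sigma_u is floored just
above zero so boundary fits (no participant heterogeneity) are allowed
and then agree with plain logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp

__all__ = ["GlmmFit", "fit_binomial_glmm"]

_LOG_SIGMA_FLOOR = np.log(1e-5)  # sigma_u2 floor 1e-10
_SQRT2 = np.sqrt(2.0)


@dataclass
class GlmmFit:
    """Fitted random-intercept logistic model."""

    beta: np.ndarray
    vcov: np.ndarray  # covariance of beta (observed information)
    sigma_u2: float
    loglik: float
    K: int  # fixed effects + 1 variance component
    n_obs: int  # Bernoulli trials entering the fit
    converged: bool
    term_names: list[str] = field(default_factory=list)
    term_slices: dict[str, slice] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return self.beta.size


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, int]:
    _, idx = np.unique(groups, return_inverse=True)
    return idx, int(idx.max()) + 1


def _irls_logistic(X: np.ndarray, y: np.ndarray, n: np.ndarray, iters: int = 25) -> np.ndarray:
    """Plain binomial-logit IRLS, used only for starting values."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = expit(eta)
        w = n * p * (1 - p) + 1e-10
        z = eta + (y - n * p) / w
        wx = X * w[:, None]
        new = np.linalg.solve(X.T @ wx + 1e-10 * np.eye(X.shape[1]), wx.T @ z)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def _cluster_modes(
    eta: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    sigma2: float,
    u0: np.ndarray,
    iters: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster posterior modes and curvatures of the integrand, by Newton."""
    u = u0.copy()
    for _ in range(iters):
        p = expit(eta + u[gidx])
        grad = np.bincount(gidx, weights=y - n * p, minlength=n_groups) - u / sigma2
        hess = -np.bincount(gidx, weights=n * p * (1 - p), minlength=n_groups) - 1.0 / sigma2
        step = grad / hess
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(eta + u[gidx])
    curv = np.bincount(gidx, weights=n * p * (1 - p), minlength=n_groups) + 1.0 / sigma2
    return u, curv


def _marginal_loglik(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    nodes_z: np.ndarray,
    nodes_logw: np.ndarray,
    u_cache: np.ndarray,
) -> float:
    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    sigma2 = sigma * sigma
    eta = X @ beta
    u_hat, curv = _cluster_modes(eta, y, n, gidx, n_groups, sigma2, u_cache)
    u_cache[:] = u_hat
    tau = 1.0 / np.sqrt(curv)  # mode-centred scale
    # adaptive abscissae: u = u_hat + sqrt(2) tau z_k
    lse_terms = np.empty((len(nodes_z), n_groups))
    for k, (z, logw) in enumerate(zip(nodes_z, nodes_logw)):
        u_k = u_hat + _SQRT2 * tau * z
        eta_k = eta + u_k[gidx]
        # Bernoulli-equivalent binomial loglik, no choose() term
        ll_rows = y * eta_k - n * np.logaddexp(0.0, eta_k)
        ll_g = np.bincount(gidx, weights=ll_rows, minlength=n_groups)
        ll_g += -0.5 * u_k**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        # quadrature weight with exp(z²) correction folded in log space
        lse_terms[k] = logw + z * z + ll_g
    log_L = logsumexp(lse_terms, axis=0) + 0.5 * np.log(2.0) + np.log(tau)
    return float(np.sum(log_L))


def fit_binomial_glmm(
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray,
    nodes: int = 15,
    term_names: list[str] | None = None,
    term_slices: dict[str, slice] | None = None,
    n_obs: int | None = None,
    start_sigma: float = 0.3,
    compute_vcov: bool = True,
) -> GlmmFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Parameters
    ----------
    X, y, n, groups
        Design matrix, success counts, trial counts and participant labels,
        one row per participant × covariate-pattern cell.
    nodes
        Gauss–Hermite nodes; 1 gives the Laplace approximation.
    n_obs
        Bernoulli sample size for information criteria (defaults to
        ``sum(n)``).

    Raises
    ------
    ValueError
        on degenerate responses (no successes or no failures overall).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if y.sum() == 0 or (n - y).sum() == 0:
        raise ValueError("response is degenerate: needs at least one success and one failure")
    gidx, n_groups = _group_index(np.asarray(groups))
    if n_groups < 1:
        raise ValueError("no participants")
    z, w = hermgauss(nodes)
    logw = np.log(w)
    u_cache = np.zeros(n_groups)

    beta0 = _irls_logistic(X, y, n)
    x0 = np.append(beta0, np.log(start_sigma))

    def nll(params: np.ndarray) -> float:
        return -_marginal_loglik(params, X, y, n, gidx, n_groups, z, logw, u_cache)

    bounds = [(None, None)] * X.shape[1] + [(_LOG_SIGMA_FLOOR, 5.0)]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    params = res.x.copy()
    # compare with the boundary candidate (sigma_u -> 0): there the profile
    # MLE for beta is the plain logistic solution; the likelihood is very
    # flat near the boundary, so adopt it whenever it is essentially as good
    beta_boundary = _irls_logistic(X, y, n, iters=100)
    params_boundary = np.append(beta_boundary, _LOG_SIGMA_FLOOR)
    f_boundary = nll(params_boundary)
    if f_boundary <= res.fun + 1e-6:
        params = params_boundary
        res.fun = f_boundary
    sigma_u = float(np.exp(params[-1]))
    at_floor = params[-1] <= _LOG_SIGMA_FLOOR + 1e-8
    loglik = -res.fun

    # observed information at the optimum: central-difference Hessian of the
    # negative log-likelihood over (beta, log sigma); beta block reported
    p_dim = X.shape[1]
    if compute_vcov:
        dim = p_dim + 1
        hess = np.zeros((dim, dim))
        h = 1e-4 * np.maximum(1.0, np.abs(params))
        if at_floor:
            dim = p_dim  # variance pinned at the boundary: profile it out
        f0 = res.fun
        for j in range(dim):
            ej = np.zeros_like(params)
            ej[j] = h[j]
            hess[j, j] = (nll(params + ej) - 2 * f0 + nll(params - ej)) / h[j] ** 2
            for k in range(j):
                ek = np.zeros_like(params)
                ek[k] = h[k]
                hess[j, k] = hess[k, j] = (
                    nll(params + ej + ek)
                    - nll(params + ej - ek)
                    - nll(params - ej + ek)
                    + nll(params - ej - ek)
                ) / (4 * h[j] * h[k])
        try:
            vcov = np.linalg.inv(hess[:dim, :dim])[:p_dim, :p_dim]
        except np.linalg.LinAlgError:  # pragma: no cover
            vcov = np.full((p_dim, p_dim), np.nan)
    else:
        vcov = np.full((p_dim, p_dim), np.nan)

    return GlmmFit(
        beta=params[:p_dim],
        vcov=vcov,
        sigma_u2=0.0 if at_floor else sigma_u**2,
        loglik=float(loglik),
        K=p_dim + 1,
        n_obs=int(n_obs if n_obs is not None else n.sum()),
        converged=bool(res.success),
        term_names=term_names or [f"b{j}" for j in range(p_dim)],
        term_slices=term_slices or {},
        meta={"nodes": nodes, "opt_message": str(res.message)},
    )
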