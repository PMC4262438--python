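"""Random-intercept logistic regression by adaptive Gauss–Hermite quadrature.

Model: y_ij ~ Bernoulli(logit^-1(x_ij' beta + u_i)), u_i ~ N(0, sigma^2),
with clusters i (here: articles) and binary outcomes j nested within them.
The marginal likelihood integrates the random intercept out of each cluster's
contribution; the integral has no closed form and is approximated by
Gauss–Hermite quadrature recentred and rescaled at each cluster's posterior
mode (adaptive GH), which is accurate even with few nodes when cluster sizes
are small and outcomes are binary.

Estimation maximises the marginal log-likelihood over (beta, log sigma) with
L-BFGS-B; standard errors come from the inverse of a central-finite-difference
Hessian at the optimum.  The mode search per cluster is a damped Newton
iteration, vectorised across clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = ["GLMMResult", "fit_random_intercept_logit", "marginal_probability"]

_LOG_SIGMA_MIN = -10.0  # sigma ~ 4.5e-5: numerically a zero-variance fit
_LOG_SIGMA_MAX = 3.0


@dataclass
class GLMMResult:
    """Fitted random-intercept logistic model."""

    beta: np.ndarray                  # fixed-effect coefficients
    se_beta: np.ndarray               # Wald standard errors
    sigma: float                      # random-intercept SD
    se_sigma: float                   # delta-method SE of sigma (nan if sigma ~ 0)
    loglik: float
    n_obs: int
    n_clusters: int
    converged: bool
    cov_beta: np.ndarray = field(repr=False, default=None)
    n_nodes: int = 15
    message: str = ""

    @property
    def sigma_is_zero(self) -> bool:
        return self.sigma < 1e-4


def _cluster_loglik(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                    group_idx: np.ndarray, n_groups: int,
                    nodes: np.ndarray, weights: np.ndarray) -> float:
    """Marginal log-likelihood, adaptive GH per cluster."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta0 = X @ beta

    if sigma < 2e-5:
        # Degenerate fit: random effect numerically zero.
        ll = y * eta0 - np.logaddexp(0.0, eta0)
        return float(ll.sum())

    # Posterior mode per cluster: maximise
    #   h_i(u) = sum_j [y eta - log(1 + e^eta)] - u^2 / (2 sigma^2)
    u = np.zeros(n_groups)
    for _ in range(50):
        eta = eta0 + u[group_idx]
        mu = special.expit(eta)
        grad = np.bincount(group_idx, weights=y - mu, minlength=n_groups) - u / sigma**2
        hess = -np.bincount(group_idx, weights=mu * (1.0 - mu), minlength=n_groups) - 1.0 / sigma**2
        step = grad / hess
        # Damped Newton: halve steps that are too large to be trustworthy.
        step = np.clip(step, -4.0, 4.0)
        u_new = u - step
        if np.max(np.abs(u_new - u)) < 1e-9:
            u = u_new
            break
        u = u_new
    eta = eta0 + u[group_idx]
    mu = special.expit(eta)
    curv = np.bincount(group_idx, weights=mu * (1.0 - mu), minlength=n_groups) + 1.0 / sigma**2
    tau = 1.0 / np.sqrt(curv)  # Laplace SD per cluster

    # Adaptive GH: u_ik = u_i + sqrt(2) tau_i z_k
    #   L_i = sqrt(2) tau_i sum_k w_k exp(z_k^2) exp(h_i(u_ik)) / (sigma sqrt(2 pi)) * ...
    # assembled in log space below.
    log_terms = np.empty((len(nodes), n_groups))
    sqrt2_tau = np.sqrt(2.0) * tau
    for k, (z, w) in enumerate(zip(nodes, weights)):
        uk = u + sqrt2_tau * z
        etak = eta0 + uk[group_idx]
        ll_obs = y * etak - np.logaddexp(0.0, etak)
        ll_clust = np.bincount(group_idx, weights=ll_obs, minlength=n_groups)
        log_prior = stats.norm.logpdf(uk, scale=sigma)
        log_terms[k] = np.log(w) + z * z + ll_clust + log_prior
    log_Li = special.logsumexp(log_terms, axis=0) + np.log(sqrt2_tau)
    return float(log_Li.sum())


def fit_random_intercept_logit(y, X, groups, *, n_nodes: int = 15,
                               start: np.ndarray | None = None,
                               fix_sigma_zero: bool = False) -> GLMMResult:
    """Fit the random-intercept logistic model by maximum likelihood.

    Parameters
    ----------
    y : (n,) binary outcomes.
    X : (n, p) fixed-effects design matrix (include the intercept column).
    groups : (n,) cluster labels (any hashable values).
    n_nodes : quadrature nodes for the adaptive GH rule.
    fix_sigma_zero : constrain the random-intercept SD to zero, collapsing
        the model to ordinary logistic regression (useful as a null model
        and as a consistency check).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, _ = _factorize(groups)
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ValueError("need at least 2 clusters for a multilevel fit")
    nodes, weights = hermgauss(n_nodes)

    p = X.shape[1]
    if start is None:
        # Moment start: pooled logit for beta, modest heterogeneity.
        pbar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        start = np.zeros(p + 1)
        start[0] = special.logit(pbar)
        start[-1] = np.log(0.5)

    if fix_sigma_zero:
        def nll0(beta):
            eta = X @ beta
            return -float((y * eta - np.logaddexp(0.0, eta)).sum())

        res0 = optimize.minimize(nll0, start[:p], method="BFGS",
                                 options={"gtol": 1e-10})
        hess0 = _fd_hessian(nll0, res0.x)
        cov0, se0 = _safe_cov(hess0)
        return GLMMResult(
            beta=res0.x.copy(), se_beta=se0, sigma=0.0, se_sigma=float("nan"),
            loglik=-float(res0.fun), n_obs=len(y), n_clusters=n_groups,
            converged=bool(res0.success), cov_beta=cov0, n_nodes=n_nodes,
            message=str(res0.message),
        )

    def nll(theta):
        return -_cluster_loglik(theta, y, X, codes, n_groups, nodes, weights)

    bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    res = optimize.minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-11})

    theta = res.x
    sigma = float(np.exp(theta[-1]))
    hess = _fd_hessian(nll, theta)
    cov, se = _safe_cov(hess)
    se_beta = se[:p]
    if not np.all(np.isfinite(se_beta)):
        # Weakly identified sigma (e.g. single-observation clusters) makes the
        # joint Hessian near-singular; fall back to the curvature in beta with
        # log sigma held at its estimate.
        log_sigma_hat = theta[-1]

        def nll_beta(beta):
            return nll(np.append(beta, log_sigma_hat))

        cov_bb, se_bb = _safe_cov(_fd_hessian(nll_beta, theta[:p]))
        cov = np.full((p + 1, p + 1), np.nan)
        cov[:p, :p] = cov_bb
        se_beta = se_bb
    # Delta method: SE(sigma) = sigma * SE(log sigma); meaningless at the boundary.
    se_sigma = sigma * se[p] if sigma >= 1e-4 else float("nan")
    return GLMMResult(
        beta=theta[:p].copy(),
        se_beta=se_beta,
        sigma=sigma,
        se_sigma=se_sigma,
        loglik=-float(res.fun),
        n_obs=len(y),
        n_clusters=n_groups,
        converged=bool(res.success),
        cov_beta=cov[:p, :p],
        n_nodes=n_nodes,
        message=str(res.message),
    )


def marginal_probability(intercept: float, sigma: float, n_nodes: int = 40) -> float:
    """Population-averaged probability: E_u[logit^-1(intercept + u)]."""
    if sigma < 1e-8:
        return float(special.expit(intercept))
    nodes, weights = hermgauss(n_nodes)
    vals = special.expit(intercept + np.sqrt(2.0) * sigma * nodes)
    return float((weights * vals).sum() / np.sqrt(np.pi))


def _factorize(groups):
    arr = np.asarray(groups)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.int64), uniq


def _fd_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (small parameter counts only)."""
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            if i == j:
                val = (f(x + ei) - 2.0 * f0 + f(x - ei)) / steps[i] ** 2
            else:
                val = (f(x + ei + ej) - f(x + ei - ej)
                       - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * steps[i] * steps[j])
            H[i, j] = H[j, i] = val
    return H


def _safe_cov(hess: np.ndarray):
    """Invert the Hessian, falling back to pseudo-inverse near the boundary."""
    n = hess.shape[0]
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan
    return cov, np.sqrt(diag)
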