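"""Maximum-likelihood logistic regression with a site random intercept.

The screening models use a Bernoulli GLMM

    logit P(y_ij = 1) = x_ij' beta + u_i,    u_i ~ N(0, sigma_u^2)

with one random intercept per site.  The marginal likelihood integrates each
site's intercept out with adaptive Gauss-Hermite quadrature (mode + curvature
found per site by Newton steps, then a shifted/scaled quadrature rule), and
(beta, log sigma_u) is maximized with BFGS.  Wald intervals come from the
numerical Hessian at the optimum.  With a single site the random intercept is
dropped and a plain logistic ML fit is returned, which makes the one-site
behavior coincide with ordinary logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit

__all__ = ["LogisticGLMMResult", "fit_logistic_glmm"]


@dataclass
class LogisticGLMMResult:
    beta: np.ndarray
    se: np.ndarray
    sigma_u: float
    loglik: float
    converged: bool
    names: list[str]

    def wald_ci(self, j: int, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return self.beta[j] - z * self.se[j], self.beta[j] + z * self.se[j]


def _site_loglik(Xu: np.ndarray, y: np.ndarray, beta: np.ndarray, sigma: float,
                 nodes: np.ndarray, weights: np.ndarray) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood for one site."""
    eta0 = Xu @ beta

    def g_parts(u: float) -> tuple[float, float, float]:
        eta = eta0 + u
        p = expit(eta)
        val = float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta))) \
            - 0.5 * u * u / (sigma * sigma)
        grad = float(np.sum(y - p)) - u / (sigma * sigma)
        hess = -float(np.sum(p * (1 - p))) - 1.0 / (sigma * sigma)
        return val, grad, hess

    u = 0.0
    for _ in range(50):  # 1-d Newton with step halving
        val, grad, hess = g_parts(u)
        step = -grad / hess
        while abs(step) > 10.0:
            step *= 0.5
        u_new = u + step
        if abs(step) < 1e-10:
            u = u_new
            break
        u = u_new
    val, grad, hess = g_parts(u)
    scale = 1.0 / np.sqrt(-hess)
    pts = u + scale * nodes
    etas = eta0[:, None] + pts[None, :]
    logf = (np.sum(y[:, None] * log_expit(etas) + (1 - y)[:, None] * log_expit(-etas), axis=0)
            - 0.5 * pts * pts / (sigma * sigma))
    # hermegauss integrates against exp(-t^2/2); undo it and add the jacobian
    logterms = logf + 0.5 * nodes * nodes + np.log(weights) + np.log(scale)
    m = logterms.max()
    return float(m + np.log(np.sum(np.exp(logterms - m))) - np.log(np.sqrt(2 * np.pi) * sigma))


def fit_logistic_glmm(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                      names: list[str] | None = None, n_quad: int = 25
                      ) -> LogisticGLMMResult:
    """Fit the random-intercept logistic model by adaptive quadrature ML."""
    import statsmodels.api as sm
    from statsmodels.tools.numdiff import approx_hess1

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    names = names or [f"x{j}" for j in range(X.shape[1])]
    uniq = np.unique(groups)
    if len(uniq) < 2:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return LogisticGLMMResult(beta=np.asarray(fit.params), se=np.asarray(fit.bse),
                                  sigma_u=0.0, loglik=float(fit.llf),
                                  converged=bool(fit.mle_retvals["converged"]), names=names)

    site_data = [(X[groups == g], y[groups == g]) for g in uniq]
    nodes, weights = hermegauss(n_quad)

    def negll(theta: np.ndarray) -> float:
        beta = theta[:-1]
        sigma = float(np.exp(np.clip(theta[-1], -10.0, 4.0)))
        ll = sum(_site_loglik(Xi, yi, beta, sigma, nodes, weights)
                 for Xi, yi in site_data)
        return -ll if np.isfinite(ll) else 1e12

    start = np.zeros(X.shape[1] + 1)
    try:
        start[:-1] = sm.Logit(y, X).fit(disp=0, maxiter=200).params
    except Exception:
        pass
    start[-1] = np.log(0.5)
    opt = minimize(negll, start, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    beta = opt.x[:-1]
    sigma_hat = float(np.exp(np.clip(opt.x[-1], -10.0, 4.0)))
    if sigma_hat < 1e-3:
        # the random-intercept variance collapsed to the boundary: the model
        # degenerates to ordinary logistic regression, whose ML fit and Wald
        # covariance are exact
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return LogisticGLMMResult(beta=np.asarray(fit.params), se=np.asarray(fit.bse),
                                  sigma_u=0.0, loglik=float(fit.llf),
                                  converged=bool(fit.mle_retvals["converged"]),
                                  names=names)
    hess = approx_hess1(opt.x, negll)
    se = np.full_like(beta, np.nan)
    ok = opt.success or opt.status == 2  # precision loss near optimum is fine
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)[: len(beta)]
        if not np.all(d > 0):  # boundary-distorted Hessian: use the beta block
            d = np.diag(np.linalg.inv(hess[: len(beta), : len(beta)]))
        if np.all(d > 0):
            se = np.sqrt(d)
        else:
            ok = False
    except np.linalg.LinAlgError:
        ok = False
    if np.any(np.abs(beta) > 15.0):  # quasi-separation
        ok = False
    return LogisticGLMMResult(beta=beta, se=se,
                              sigma_u=float(np.exp(opt.x[-1])),
                              loglik=float(-opt.fun), converged=bool(ok), names=names)
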