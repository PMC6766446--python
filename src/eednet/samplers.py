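"""Gibbs samplers for the network's node regressions.

Each node of the network is a generalized linear regression whose parents are
all observed, so nodes are conditionally independent and are sampled one at a
time:

* linear nodes — conjugate Gibbs.  Coefficients get a Normal(0, tau0^2) prior;
  the residual SD prior is either Half-Cauchy(1) (default; handled through its
  inverse-gamma scale-mixture representation so every conditional stays
  conjugate) or an explicit InverseGamma(a0, b0) on the variance, which admits
  an exact closed-form (normal-inverse-gamma) posterior used as a test oracle.
* logistic nodes — Gibbs with Polya-Gamma data augmentation: omega_i ~
  PG(1, x_i'beta), then beta | omega is a conjugate Gaussian update.

Chains are initialized overdispersed and seeded from (seed, node, chain)
substreams, so posteriors are reproducible draw-for-draw and independent of
which other nodes are fitted in the same call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from ._rng import substream, substream_int
from .pg import pg_draw, seed_pg

__all__ = ["MCMCConfig", "sample_linear_node", "sample_logistic_node",
           "conjugate_nig_posterior"]


@dataclass
class MCMCConfig:
    """Sampler settings shared by every node fit."""

    n_chains: int = 4
    n_iterations: int = 5000
    n_burnin: int = 2500
    thin: int = 1
    seed: int = 0
    coef_prior_sd: float = 10.0
    sigma_prior: tuple = ("half_cauchy", 1.0)   # or ("inv_gamma", a0, b0)
    rhat_limit: float = 1.01
    ess_limit: float = 400.0

    def __post_init__(self) -> None:
        if self.n_iterations <= self.n_burnin:
            raise ValueError("n_iterations must exceed n_burnin")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")

    @property
    def n_kept(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


def _draw_mvn(rng: np.random.Generator, mean: np.ndarray, prec: np.ndarray) -> np.ndarray:
    """N(mean, prec^-1) draw via the Cholesky factor of the precision."""
    upper = cholesky(prec, lower=False)
    z = rng.standard_normal(mean.shape[0])
    from scipy.linalg import solve_triangular

    return mean + solve_triangular(upper, z, lower=False)


def sample_linear_node(X: np.ndarray, y: np.ndarray, mcmc: MCMCConfig,
                       node_key: str = "node") -> tuple[np.ndarray, np.ndarray]:
    """Posterior draws for a Gaussian regression node.

    Returns ``(beta_draws, sigma_draws)`` with shapes (chains, kept, p) and
    (chains, kept).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    prior_prec = np.eye(p) / mcmc.coef_prior_sd**2
    kept = mcmc.n_kept
    betas = np.empty((mcmc.n_chains, kept, p))
    sigmas = np.empty((mcmc.n_chains, kept))
    kind = mcmc.sigma_prior[0]
    if kind == "half_cauchy":
        A = float(mcmc.sigma_prior[1])
    elif kind in ("inv_gamma", "nig"):
        a0, b0 = float(mcmc.sigma_prior[1]), float(mcmc.sigma_prior[2])
    else:
        raise ValueError(f"unknown sigma prior {kind!r}")
    if kind == "nig":
        # beta | sigma^2 ~ N(0, sigma^2 tau0^2 I): the fully conjugate family
        # whose exact posterior is normal-inverse-gamma (the test oracle)
        Vn_prec = XtX + prior_prec
        cf = cho_factor(Vn_prec)
        mn = cho_solve(cf, Xty)

    for chain in range(mcmc.n_chains):
        rng = substream(mcmc.seed, "lin", node_key, chain)
        beta = 2.0 * rng.standard_normal(p)
        sigma2 = float(np.exp(rng.normal(0.0, 1.0)))
        k = 0
        for it in range(mcmc.n_iterations):
            if kind == "nig":
                beta = _draw_mvn(rng, mn, Vn_prec / sigma2)
            else:
                prec = XtX / sigma2 + prior_prec
                beta = _draw_mvn(rng, cho_solve(cho_factor(prec), Xty / sigma2), prec)
            resid = y - X @ beta
            ssr = float(resid @ resid)
            if kind == "half_cauchy":
                a_aux = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A**2 + 1.0 / sigma2))
                sigma2 = 1.0 / rng.gamma((n + 1.0) / 2.0, 1.0 / (ssr / 2.0 + 1.0 / a_aux))
            elif kind == "inv_gamma":
                sigma2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + ssr / 2.0))
            else:
                shape = a0 + (n + p) / 2.0
                rate = b0 + 0.5 * (ssr + float(beta @ prior_prec @ beta))
                sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                betas[chain, k] = beta
                sigmas[chain, k] = math.sqrt(sigma2)
                k += 1
    return betas, sigmas


def sample_logistic_node(X: np.ndarray, y: np.ndarray, mcmc: MCMCConfig,
                         node_key: str = "node") -> np.ndarray:
    """Posterior draws for a Bernoulli-logit node via Polya-Gamma Gibbs.

    Returns beta draws with shape (chains, kept, p).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    kappa = X.T @ (y - 0.5)
    prior_prec = np.eye(p) / mcmc.coef_prior_sd**2
    kept = mcmc.n_kept
    betas = np.empty((mcmc.n_chains, kept, p))

    for chain in range(mcmc.n_chains):
        rng = substream(mcmc.seed, "logit", node_key, chain)
        seed_pg(substream_int(mcmc.seed, "pg", node_key, chain))
        beta = 2.0 * rng.standard_normal(p)
        k = 0
        for it in range(mcmc.n_iterations):
            psi = X @ beta
            omega = pg_draw(psi)
            prec = (X.T * omega) @ X + prior_prec
            mean = cho_solve(cho_factor(prec), kappa)
            beta = _draw_mvn(rng, mean, prec)
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                betas[chain, k] = beta
                k += 1
    return betas


def conjugate_nig_posterior(X: np.ndarray, y: np.ndarray, coef_prior_sd: float,
                            a0: float, b0: float) -> dict[str, np.ndarray]:
    """Exact normal-inverse-gamma posterior for a linear node.

    Prior: beta | sigma^2 ~ N(0, sigma^2 * coef_prior_sd^2 I) and
    sigma^2 ~ InvGamma(a0, b0) — the fully conjugate family matching the
    sampler's ``sigma_prior=("nig", a0, b0)`` option.  The marginal posterior
    of beta is a multivariate t with 2*an degrees of freedom; returns its mean
    and per-coefficient SD plus (an, bn, Vn).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    V0_inv = np.eye(p) / coef_prior_sd**2
    Vn = np.linalg.inv(X.T @ X + V0_inv)
    mn = Vn @ (X.T @ y)
    an = a0 + n / 2.0
    bn = b0 + 0.5 * float(y @ y - mn @ (X.T @ X + V0_inv) @ mn)
    scale = bn / an
    df = 2.0 * an
    var = np.diag(Vn) * scale * df / (df - 2.0)
    return {"mean": mn, "sd": np.sqrt(var), "an": an, "bn": bn, "Vn": Vn}
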