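"""Exact Polya-Gamma PG(1, z) random variates.

Implements the alternating-series rejection sampler of Devroye (as used for
Bayesian logistic regression with Polya-Gamma data augmentation): draw
X ~ J*(1, z/2) from a mixture of a truncated inverse-Gaussian (left of
t = 0.64) and a truncated exponential (right of t), accept via the partial
sums of the alternating series for the J* density, and return X / 4.

The sampler is JIT-compiled with numba; determinism is obtained by seeding
numba's internal Mersenne state through :func:`seed_pg` before each chain.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__TRUNC = 0.64

__all__ = ["seed_pg", "pg_draw", "pg_mean"]


@njit(cache=True)
def _log_norm_cdf(x: float) -> float:
    if x > -37.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    # asymptotic tail expansion; erfc underflows around -38
    return -0.5 * x * x - math.log(-x) - 0.5 * math.log(2.0 * math.pi)


@njit(cache=True)
def _mass_texpon(z: float) -> float:
    """P(proposal comes from the truncated-exponential piece)."""
    t = 0.64
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z: float) -> float:
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    t = 0.64
    x = t + 1.0
    if z < 1.0 / t:  # near-flat regime: rejection from scaled inverse-chi^2
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.normal(0.0, 1.0)
            y = y * y
            half = mu * 0.5
            x = mu + half * mu * y - half * math.sqrt(4.0 * mu * y + (mu * y) * (mu * y))
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    t = 0.64
    k = (n + 0.5) * math.pi
    if x > t:
        return k * math.exp(-0.5 * k * k * x)
    return k * math.pow(2.0 / (math.pi * x), 1.5) * math.exp(-2.0 * (n + 0.5) * (n + 0.5) / x)


@njit(cache=True)
def _pg1(psi: float) -> float:
    """One PG(1, psi) draw."""
    z = 0.5 * abs(psi)
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    p_texp = _mass_texpon(z)
    while True:
        if np.random.random() < p_texp:
            x = 0.64 + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        accept = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accept = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
        if accept:
            return 0.25 * x


@njit(cache=True)
def _seed(seed: int) -> None:
    np.random.seed(seed)


@njit(cache=True)
def pg_draw(psi: np.ndarray) -> np.ndarray:
    """Vector of PG(1, psi_i) draws from numba's current RNG state."""
    out = np.empty(psi.shape[0])
    for i in range(psi.shape[0]):
        out[i] = _pg1(psi[i])
    return out


def seed_pg(seed: int) -> None:
    """Seed the (process-global) numba RNG used by :func:`pg_draw`."""
    _seed(int(seed) & 0x7FFFFFFF)


def pg_mean(psi: np.ndarray | float) -> np.ndarray | float:
    """E[PG(1, psi)] = tanh(psi/2) / (2 psi), with the psi -> 0 limit 1/4."""
    psi = np.asarray(psi, float)
    small = np.abs(psi) < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.tanh(psi / 2.0) / (2.0 * psi)
    return np.where(small, 0.25, m)
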