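"""Closed-form count-distribution machinery: ZINB, NB, ZIP, Poisson.

The zero-inflated negative binomial models sparse, overdispersed cleavage
read counts as a two-component mixture

    ZINB(k; pi, mu, theta) = pi * delta_0(k) + (1 - pi) * NB(k; mu, theta)

where ``pi`` is the zero-inflation weight (technical zeros), ``mu`` the NB
mean and ``theta`` the NB dispersion (variance mu + mu^2/theta).  All
functions broadcast over numpy arrays and are evaluated in log space via
log-gamma for stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy import special, stats

ArrayLike = Union[float, np.ndarray]

# Numerical floors applied after network activations to keep the NLL finite.
PI_EPS = 1e-6
PARAM_MIN = 1e-6
PARAM_MAX = 1e6


class DomainError(ValueError):
    """Parameters outside the distribution's domain (non-finite or <= 0)."""


def clamp_params(pi: ArrayLike, mu: ArrayLike, theta: ArrayLike):
    """Clamp (pi, mu, theta) into their numerically safe ranges."""
    pi = np.clip(pi, PI_EPS, 1.0 - PI_EPS)
    mu = np.clip(mu, PARAM_MIN, PARAM_MAX)
    theta = np.clip(theta, PARAM_MIN, PARAM_MAX)
    return pi, mu, theta


@dataclass
class ZINBParams:
    """Zero-inflation weight, NB mean and NB dispersion for one or more sites."""

    pi: ArrayLike
    mu: ArrayLike
    theta: ArrayLike

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=np.float64)
        mu = np.asarray(self.mu, dtype=np.float64)
        theta = np.asarray(self.theta, dtype=np.float64)
        if not (np.all(np.isfinite(pi)) and np.all(np.isfinite(mu)) and np.all(np.isfinite(theta))):
            raise DomainError("ZINB parameters must be finite")
        if np.any(pi < 0) or np.any(pi > 1):
            raise DomainError("pi must lie in [0, 1]")
        if np.any(mu <= 0) or np.any(theta <= 0):
            raise DomainError("mu and theta must be positive")
        self.pi, self.mu, self.theta = pi, mu, theta


def _check_counts(k: ArrayLike) -> np.ndarray:
    k = np.asarray(k, dtype=np.float64)
    if np.any(k < 0) or not np.all(np.isfinite(k)):
        raise DomainError("counts must be finite and >= 0")
    return k


def _check_pos(name: str, x: ArrayLike) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise DomainError(f"{name} must be finite and > 0")
    return x


def nb_log_pmf(k: ArrayLike, mu: ArrayLike, theta: ArrayLike) -> np.ndarray:
    """log NB(k; mu, theta) = log Gamma(k+theta)/(Gamma(theta) k!)
    + k log(mu/(mu+theta)) + theta log(theta/(mu+theta))."""
    k = _check_counts(k)
    mu = _check_pos("mu", mu)
    theta = _check_pos("theta", theta)
    log_mu_ratio = np.log(mu) - np.log(mu + theta)
    log_theta_ratio = np.log(theta) - np.log(mu + theta)
    return (
        special.gammaln(k + theta)
        - special.gammaln(theta)
        - special.gammaln(k + 1.0)
        + k * log_mu_ratio
        + theta * log_theta_ratio
    )


def zinb_log_pmf(k: ArrayLike, params: ZINBParams) -> np.ndarray:
    """log ZINB(k) with a log-sum-exp at k = 0 for stability."""
    k = _check_counts(k)
    pi, mu, theta = np.broadcast_arrays(
        np.clip(params.pi, 0.0, 1.0), params.mu, params.theta
    )
    k_b = np.broadcast_to(k, np.broadcast_shapes(np.shape(k), pi.shape))
    pi = np.broadcast_to(pi, k_b.shape)
    mu = np.broadcast_to(mu, k_b.shape)
    theta = np.broadcast_to(theta, k_b.shape)
    nb = nb_log_pmf(k_b, mu, theta)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1m_pi = np.log1p(-pi)
    zero = k_b == 0
    # k = 0: logsumexp(log pi, log(1-pi) + NB(0)); k > 0: log(1-pi) + NB(k)
    out = log_1m_pi + nb
    if np.any(zero):
        a = np.where(zero, log_pi, -np.inf)
        b = out
        m = np.maximum(a, b)
        m = np.where(np.isfinite(m), m, 0.0)
        lse = m + np.log(np.exp(a - m) + np.exp(b - m))
        out = np.where(zero, lse, out)
    return out


def zinb_nll(params_batch: ZINBParams, y_batch: ArrayLike) -> float:
    """Negative log likelihood -sum_i log ZINB(y_i; pi_i, mu_i, theta_i)."""
    y = np.atleast_1d(_check_counts(y_batch))
    pi = np.atleast_1d(np.asarray(params_batch.pi, dtype=np.float64))
    mu = np.atleast_1d(np.asarray(params_batch.mu, dtype=np.float64))
    theta = np.atleast_1d(np.asarray(params_batch.theta, dtype=np.float64))
    if y.size == 0:
        raise DomainError("empty observation batch")
    if not (pi.shape == mu.shape == theta.shape == y.shape):
        raise DomainError(
            f"shape mismatch: params {pi.shape}/{mu.shape}/{theta.shape} vs y {y.shape}"
        )
    pi_c, mu_c, theta_c = clamp_params(pi, mu, theta)
    return float(-np.sum(zinb_log_pmf(np.round(y), ZINBParams(pi_c, mu_c, theta_c))))


def zinb_moments(params: ZINBParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (mean, variance, CV) of the ZINB mixture.

    mean = (1-pi) mu;  var = (1-pi) mu (1 + mu/theta + pi mu);
    cv = sqrt(var)/mean, +inf where the mean is 0.
    """
    pi = np.asarray(params.pi, dtype=np.float64)
    mu = np.asarray(params.mu, dtype=np.float64)
    theta = np.asarray(params.theta, dtype=np.float64)
    mean = (1.0 - pi) * mu
    var = (1.0 - pi) * mu * (1.0 + mu / theta + pi * mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / np.where(mean > 0, mean, 1.0), np.inf)
    return mean, var, cv


def zinb_sample(params: ZINBParams, n: int, seed: int) -> np.ndarray:
    """Draw n ZINB variates via the gamma-Poisson mixture, reproducibly.

    For array-valued params the draw is vectorized per element with shape
    ``(n,) + params.shape``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pi = np.broadcast_arrays(
        np.asarray(params.pi, dtype=np.float64),
        np.asarray(params.mu, dtype=np.float64),
        np.asarray(params.theta, dtype=np.float64),
    )
    pi, mu, theta = pi
    shape = (n,) + pi.shape
    lam = rng.gamma(np.broadcast_to(theta, shape), np.broadcast_to(mu / theta, shape))
    counts = rng.poisson(lam)
    dropped = rng.random(shape) < np.broadcast_to(pi, shape)
    counts = np.where(dropped, 0, counts)
    if pi.shape == ():
        return counts.reshape(n)
    return counts


def zinb_cdf(k: ArrayLike, params: ZINBParams) -> np.ndarray:
    """ZINB CDF: pi + (1-pi) * NB_CDF(k), with CDF(k<0) = 0."""
    k = np.asarray(k, dtype=np.float64)
    pi = np.asarray(params.pi, dtype=np.float64)
    mu = np.asarray(params.mu, dtype=np.float64)
    theta = np.asarray(params.theta, dtype=np.float64)
    p_nb = theta / (theta + mu)
    cdf = pi + (1.0 - pi) * stats.nbinom.cdf(np.floor(k), theta, p_nb)
    return np.where(k < 0, 0.0, cdf)


def zinb_ppf(level: ArrayLike, params: ZINBParams) -> np.ndarray:
    """Right-continuous quantile: min{k : CDF(k) >= level}."""
    level = np.asarray(level, dtype=np.float64)
    pi = np.asarray(params.pi, dtype=np.float64)
    mu = np.asarray(params.mu, dtype=np.float64)
    theta = np.asarray(params.theta, dtype=np.float64)
    p_nb = theta / (theta + mu)
    # CDF(0) = pi + (1-pi) NB(0); below that the quantile is 0.
    adj = (level - pi) / np.clip(1.0 - pi, PI_EPS, None)
    q = stats.nbinom.ppf(np.clip(adj, 0.0, 1.0), theta, p_nb)
    q = np.where(level <= zinb_cdf(0, params) + 1e-15, 0.0, q)
    return q


# ---------------------------------------------------------------------------
# Reduced heads used in the ablation comparison (ZIP, Poisson, plain NB).
# ---------------------------------------------------------------------------

def poisson_log_pmf(k: ArrayLike, lam: ArrayLike) -> np.ndarray:
    k = _check_counts(k)
    lam = _check_pos("lambda", lam)
    return k * np.log(lam) - lam - special.gammaln(k + 1.0)


def zip_log_pmf(k: ArrayLike, pi: ArrayLike, lam: ArrayLike) -> np.ndarray:
    """Zero-inflated Poisson: pi * delta_0 + (1-pi) * Poisson(lam)."""
    k = _check_counts(k)
    pi = np.clip(np.asarray(pi, dtype=np.float64), 0.0, 1.0)
    lam = _check_pos("lambda", lam)
    k_b, pi, lam = np.broadcast_arrays(k, pi, lam)
    pois = poisson_log_pmf(k_b, lam)
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1m_pi = np.log1p(-pi)
    out = log_1m_pi + pois
    zero = k_b == 0
    if np.any(zero):
        a = np.where(zero, log_pi, -np.inf)
        m = np.maximum(a, out)
        m = np.where(np.isfinite(m), m, 0.0)
        lse = m + np.log(np.exp(a - m) + np.exp(out - m))
        out = np.where(zero, lse, out)
    return out


def poisson_nll(lam: ArrayLike, y: ArrayLike) -> float:
    y = np.round(np.atleast_1d(_check_counts(y)))
    lam = np.clip(np.atleast_1d(np.asarray(lam, dtype=np.float64)), PARAM_MIN, PARAM_MAX)
    if lam.shape != y.shape:
        raise DomainError("shape mismatch between lambda and y")
    return float(-np.sum(poisson_log_pmf(y, lam)))


def zip_nll(pi: ArrayLike, lam: ArrayLike, y: ArrayLike) -> float:
    y = np.round(np.atleast_1d(_check_counts(y)))
    pi = np.clip(np.atleast_1d(np.asarray(pi)), PI_EPS, 1 - PI_EPS)
    lam = np.clip(np.atleast_1d(np.asarray(lam)), PARAM_MIN, PARAM_MAX)
    if not (pi.shape == lam.shape == y.shape):
        raise DomainError("shape mismatch in ZIP NLL")
    return float(-np.sum(zip_log_pmf(y, pi, lam)))


def nb_nll(mu: ArrayLike, theta: ArrayLike, y: ArrayLike) -> float:
    y = np.round(np.atleast_1d(_check_counts(y)))
    mu = np.clip(np.atleast_1d(np.asarray(mu)), PARAM_MIN, PARAM_MAX)
    theta = np.clip(np.atleast_1d(np.asarray(theta)), PARAM_MIN, PARAM_MAX)
    if not (mu.shape == theta.shape == y.shape):
        raise DomainError("shape mismatch in NB NLL")
    return float(-np.sum(nb_log_pmf(y, mu, theta)))
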