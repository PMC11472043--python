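"""Distribution layer: closed forms vs independent oracles, samplers, moments."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import guidepost as gp
from guidepost.distributions import DomainError, ZINBParams


def _param_grid(n, seed):
    rng = np.random.default_rng(seed)
    pi = rng.uniform(0.0, 0.95, n)
    mu = 10 ** rng.uniform(-1, 3, n)
    theta = 10 ** rng.uniform(-1, 2, n)
    return pi, mu, theta


def _nb_log_pmf_direct(k, mu, theta):
    """Independent evaluation straight from the gamma-function formula."""
    return (gammaln(k + theta) - gammaln(theta) - gammaln(k + 1)
            + k * np.log(mu / (mu + theta)) + theta * np.log(theta / (mu + theta)))


def test_nb_log_pmf_closed_forms():
    assert gp.nb_log_pmf(0, 1.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)
    mu, theta = 3.7, 2.2
    assert gp.nb_log_pmf(0, mu, theta) == pytest.approx(
        theta * (np.log(theta) - np.log(mu + theta)), abs=1e-12)
    assert gp.nb_log_pmf(3, 2.0, 5.0) == pytest.approx(
        _nb_log_pmf_direct(3.0, 2.0, 5.0), rel=1e-12)


def test_log_pmfs_match_direct_formula_grid():
    """200-point random parameter grid vs direct-formula and scipy oracles."""
    pi, mu, theta = _param_grid(200, seed=7)
    rng = np.random.default_rng(8)
    k = rng.integers(0, 50, 200).astype(float)
    mine = gp.nb_log_pmf(k, mu, theta)
    direct = _nb_log_pmf_direct(k, mu, theta)
    assert np.allclose(mine, direct, rtol=1e-10)
    # independent library route: scipy's NB pmf
    scipy_nb = stats.nbinom.logpmf(k, theta, theta / (theta + mu))
    assert np.allclose(mine, scipy_nb, rtol=1e-9, atol=1e-9)
    # ZINB against an explicit mixture evaluation
    zinb = gp.zinb_log_pmf(k, ZINBParams(pi, mu, theta))
    mix = np.where(k == 0, np.log(pi + (1 - pi) * np.exp(direct)),
                   np.log1p(-pi) + direct)
    assert np.allclose(zinb, mix, rtol=1e-10, atol=1e-12)
    # ZIP against the same construction with a Poisson core
    zipv = gp.zip_log_pmf(k, pi, mu)
    pois = stats.poisson.logpmf(k, mu)
    mixp = np.where(k == 0, np.log(pi + (1 - pi) * np.exp(pois)),
                    np.log1p(-pi) + pois)
    assert np.allclose(zipv, mixp, rtol=1e-10, atol=1e-12)
    assert np.allclose(gp.poisson_log_pmf(k, mu), pois, rtol=1e-10)


def test_zinb_log_pmf_special_cases():
    assert gp.zinb_log_pmf(0, ZINBParams(1.0, 5.0, 2.0)) == pytest.approx(0.0, abs=1e-12)
    p = ZINBParams(0.0, 2.0, 5.0)
    assert gp.zinb_log_pmf(4, p) == pytest.approx(gp.nb_log_pmf(4, 2.0, 5.0), rel=1e-12)
    assert gp.zinb_log_pmf(0, ZINBParams(0.5, 1.0, 1.0)) == pytest.approx(
        np.log(0.75), abs=1e-12)


def test_poisson_zero_and_zip_degeneracy():
    lam = 2.3
    assert gp.poisson_log_pmf(0, lam) == pytest.approx(-lam, abs=1e-12)
    assert gp.zip_log_pmf(2, 0.0, 1.5) == pytest.approx(gp.poisson_log_pmf(2, 1.5), rel=1e-12)
    direct = np.log(0.7 * np.exp(stats.poisson.logpmf(2, 1.5)))
    assert gp.zip_log_pmf(2, 0.3, 1.5) == pytest.approx(direct, rel=1e-12)


def test_pmfs_sum_to_one():
    """Total mass over a tail-bounded support, for a grid of parameters."""
    pi, mu, theta = _param_grid(20, seed=1)
    for p, m, t in zip(pi, mu, theta):
        params = ZINBParams(p, m, t)
        # support bound from the NB quantile tail
        K = int(stats.nbinom.ppf(1 - 1e-9, t, t / (t + m))) + 10
        k = np.arange(K + 1)
        total = np.exp(gp.zinb_log_pmf(k, ZINBParams(p, m, t))).sum()
        assert total == pytest.approx(1.0, abs=1e-6)


def test_nb_approaches_poisson_at_large_theta():
    k = np.arange(0, 60)
    mu = 7.5
    nb = np.exp(gp.nb_log_pmf(k, mu, 1e6))
    pois = np.exp(gp.poisson_log_pmf(k, mu))
    assert np.max(np.abs(nb - pois)) < 1e-4


def test_nll_matches_loop_oracle_and_additivity():
    pi, mu, theta = _param_grid(50, seed=2)
    rng = np.random.default_rng(3)
    y = rng.integers(0, 30, 50).astype(float)
    batch = gp.zinb_nll(ZINBParams(pi, mu, theta), y)
    loop = -sum(float(gp.zinb_log_pmf(y[i], ZINBParams(pi[i], mu[i], theta[i])))
                for i in range(50))
    assert batch == pytest.approx(loop, rel=1e-10)
    single = gp.zinb_nll(ZINBParams(pi[:1], mu[:1], theta[:1]), y[:1])
    assert single == pytest.approx(-float(gp.zinb_log_pmf(y[0], ZINBParams(pi[0], mu[0], theta[0]))), rel=1e-12)


def test_nll_shape_mismatch_raises():
    with pytest.raises(DomainError):
        gp.zinb_nll(ZINBParams([0.1, 0.2], [1, 2], [1, 1]), [1.0])


def test_moments_against_monte_carlo():
    """Closed-form mean/variance vs 10^6 draws, within 3 standard errors."""
    rng = np.random.default_rng(5)
    for seed in range(4):
        pi = rng.uniform(0, 0.8)
        mu = 10 ** rng.uniform(0, 2.5)
        theta = 10 ** rng.uniform(-0.5, 1.5)
        params = ZINBParams(pi, mu, theta)
        mean, var, cv = gp.zinb_moments(params)
        draws = gp.zinb_sample(params, 1_000_000, seed=100 + seed)
        se_mean = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se_mean
        # variance SE via the fourth central moment
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_var = np.sqrt(max(m4 - draws.var() ** 2, 0) / draws.size)
        assert abs(draws.var() - var) < 3 * se_var + 1e-9
        emp_cv = draws.std() / draws.mean()
        assert emp_cv == pytest.approx(cv, rel=0.02)


def test_moment_limits():
    mean, var, _ = gp.zinb_moments(ZINBParams(0.0, 4.0, 2.0))
    assert mean == pytest.approx(4.0)
    assert var == pytest.approx(4.0 + 16.0 / 2.0)
    mean1, _, cv1 = gp.zinb_moments(ZINBParams(1.0, 4.0, 2.0))
    assert mean1 == 0.0 and np.isinf(cv1)


def test_sampler_determinism_and_degenerate_pi():
    params = ZINBParams(0.4, 8.0, 1.5)
    a = gp.zinb_sample(params, 1000, seed=9)
    b = gp.zinb_sample(params, 1000, seed=9)
    assert np.array_equal(a, b)
    assert np.all(gp.zinb_sample(ZINBParams(1.0, 8.0, 1.5), 500, seed=1) == 0)


def test_sampler_total_variation_against_pmf():
    """Empirical pmf of 10^6 draws within TV 0.005 of the closed form."""
    params = ZINBParams(0.35, 12.0, 1.2)
    draws = gp.zinb_sample(params, 1_000_000, seed=42)
    kmax = 200
    emp = np.bincount(np.clip(draws, 0, kmax), minlength=kmax + 1) / draws.size
    theo = np.exp(gp.zinb_log_pmf(np.arange(kmax + 1), params))
    tv = 0.5 * np.abs(emp - theo).sum()
    assert tv < 0.005


def test_cdf_ppf_consistency():
    params = ZINBParams(0.3, 20.0, 2.0)
    ks = np.arange(0, 120)
    pmf_cum = np.cumsum(np.exp(gp.zinb_log_pmf(ks, params)))
    cdf = gp.zinb_cdf(ks, params)
    assert np.allclose(pmf_cum, cdf, atol=1e-10)
    for level in (0.05, 0.5, 0.9, 0.95, 0.99):
        q = gp.zinb_ppf(level, params)
        # right-continuous inversion against the accumulation oracle
        oracle = ks[np.searchsorted(pmf_cum, level)]
        assert q == oracle


def test_invalid_params_raise():
    with pytest.raises(DomainError):
        ZINBParams(0.5, -1.0, 1.0)
    with pytest.raises(DomainError):
        ZINBParams(1.5, 1.0, 1.0)
    with pytest.raises(DomainError):
        gp.nb_log_pmf(1, np.inf, 1.0)
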