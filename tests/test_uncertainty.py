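"""Uncertainty outputs: point predictions, one-sided intervals, CV,
calibration diagnostics."""

import numpy as np
import pytest

import guidepost as gp
from guidepost.distributions import ZINBParams
from guidepost.uncertainty import PosteriorStateError, SitePosterior


def _random_params(n, seed):
    rng = np.random.default_rng(seed)
    return [ZINBParams(rng.uniform(0, 0.8), 10 ** rng.uniform(0.5, 2.5),
                       10 ** rng.uniform(-0.3, 1.3)) for _ in range(n)]


def test_point_prediction_closed_forms_and_scale():
    assert gp.point_prediction(SitePosterior(ZINBParams(1.0, 5.0, 1.0))) == 0.0
    assert gp.point_prediction(SitePosterior(ZINBParams(1e-9, 10.0, 2.0))) == \
        pytest.approx(10.0, rel=1e-6)
    post = SitePosterior(ZINBParams(0.2, 50.0, 2.0), scale=10_000.0)
    assert gp.point_prediction(post) == pytest.approx((0.8 * 50.0) / 10_000.0)


def test_point_prediction_matches_monte_carlo():
    params = ZINBParams(0.3, 80.0, 1.2)
    post = SitePosterior(params)
    draws = post.draw(1_000_000, seed=5)
    se = draws.std() / np.sqrt(draws.size)
    assert abs(gp.point_prediction(post) - draws.mean()) < 3 * se


def test_interval_conventions():
    iv = gp.off_target_interval(SitePosterior(ZINBParams(1.0, 5.0, 1.0)))
    assert (iv.lcb, iv.ucb) == (0.0, 0.0)
    # quantile against the sampler oracle
    params = ZINBParams(0.4, 30.0, 1.5)
    iv95 = gp.off_target_interval(SitePosterior(params), level=0.95)
    draws = gp.zinb_sample(params, 1_000_000, seed=2)
    emp = np.quantile(draws, 0.95, method="inverted_cdf")
    assert iv95.lcb == 0.0
    assert abs(iv95.ucb - emp) <= 1.0
    with pytest.raises(ValueError):
        gp.off_target_interval(SitePosterior(params), level=1.5)


def test_interval_from_samples_nearest_rank():
    post = SitePosterior(samples=np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 9]))
    iv = gp.off_target_interval(post, level=0.5)
    assert iv.ucb == 4.0


def test_ucb_monotone_in_level():
    for params in _random_params(5, seed=9):
        post = SitePosterior(params)
        levels = np.linspace(0.05, 0.99, 20)
        ucbs = [gp.off_target_interval(post, lv).ucb for lv in levels]
        assert np.all(np.diff(ucbs) >= 0)


def test_cv_poisson_limit_and_scale_invariance():
    post = SitePosterior(ZINBParams(1e-12, 100.0, 1e6))
    assert gp.coefficient_of_variation(post) == pytest.approx(0.1, rel=1e-3)
    p = ZINBParams(0.3, 40.0, 2.0)
    cv1 = gp.coefficient_of_variation(SitePosterior(p, scale=1.0))
    cv2 = gp.coefficient_of_variation(SitePosterior(p, scale=10_000.0))
    assert cv1 == cv2
    draws = gp.zinb_sample(p, 1_000_000, seed=3)
    assert cv1 == pytest.approx(draws.std() / draws.mean(), rel=0.02)


def test_posterior_requires_params_or_samples():
    with pytest.raises(PosteriorStateError):
        SitePosterior()


@pytest.mark.parametrize("head_params", [
    lambda r: ZINBParams(r.uniform(0.05, 0.6), 10 ** r.uniform(1, 2.5), 10 ** r.uniform(0, 1)),
    lambda r: ZINBParams(r.uniform(0.05, 0.6), 10 ** r.uniform(1, 2.5), 1e6),  # ZIP-like
    lambda r: ZINBParams(1e-6, 10 ** r.uniform(1, 2.5), 10 ** r.uniform(0, 1)),  # NB
    lambda r: ZINBParams(1e-6, 10 ** r.uniform(1, 2.5), 1e6),  # Poisson-like
])
def test_pit_calibration_self_consistency_all_heads(head_params):
    """Observations drawn from the posteriors themselves are calibrated."""
    rng = np.random.default_rng(17)
    n = 2000
    posteriors = [SitePosterior(head_params(rng)) for _ in range(n)]
    obs = np.array([p.draw(1, seed=1000 + i)[0] for i, p in enumerate(posteriors)],
                   dtype=float)
    grid = np.arange(0.05, 0.951, 0.05)
    observed = gp.calibration_curve(posteriors, obs, grid, method="pit", seed=5)
    assert np.max(np.abs(observed - grid)) <= 0.05


def test_quantile_calibration_is_conservative():
    """The discrete-quantile rule never under-covers its nominal level."""
    rng = np.random.default_rng(23)
    n = 1500
    posteriors = [SitePosterior(ZINBParams(rng.uniform(0, 0.7),
                                           10 ** rng.uniform(0, 2),
                                           10 ** rng.uniform(-0.3, 1)))
                  for _ in range(n)]
    obs = np.array([p.draw(1, seed=2000 + i)[0] for i, p in enumerate(posteriors)],
                   dtype=float)
    grid = np.arange(0.05, 0.951, 0.05)
    observed = gp.calibration_curve(posteriors, obs, grid, method="quantile")
    # binomial slack at n=1500
    assert np.all(observed >= grid - 0.04)


def test_calibration_degenerate_cases():
    post = SitePosterior(ZINBParams(0.999999, 5.0, 1.0))
    grid = [0.1, 0.5, 0.9]
    observed = gp.calibration_curve([post] * 50, np.zeros(50), grid, method="quantile")
    assert np.allclose(observed, 1.0)
    # a single observation far above the posterior's 0.99-quantile
    post2 = SitePosterior(ZINBParams(0.01, 5.0, 5.0))
    observed2 = gp.calibration_curve([post2], [500.0], grid, method="quantile")
    assert np.allclose(observed2, 0.0)
    with pytest.raises(ValueError):
        gp.calibration_curve([post], [0.0, 1.0], grid)


def test_sort_by_ucb_orders_by_upper_bound():
    posteriors = [SitePosterior(ZINBParams(0.1, mu, 2.0)) for mu in (50, 5, 500)]
    order = gp.sort_by_ucb(posteriors)
    assert order.tolist() == [1, 0, 2]
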