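"""Per-site uncertainty outputs: point predictions, one-sided credible
intervals, coefficient of variation, and the calibration diagnostic.

In guide design only the upper tail of an off-target posterior matters, so
intervals follow the convention of a lower bound fixed at zero activity with
the upper bound at the requested level (95% by default).  Counts are
converted to activity frequencies by the stored ``scale`` divisor (the
post-normalization maximum, 10 000 by default in the training pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .distributions import ZINBParams, zinb_cdf, zinb_log_pmf, zinb_moments, zinb_ppf, zinb_sample


class PosteriorStateError(RuntimeError):
    """A posterior has neither parameters nor samples to work from."""


@dataclass
class SitePosterior:
    """Predictive count distribution for one site.

    Either closed-form ``params`` or an array of Monte-Carlo ``samples``
    must be present; ``scale`` converts counts to activity frequencies.
    """

    params: Optional[ZINBParams] = None
    samples: Optional[np.ndarray] = None
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=np.float64)
            if np.any(self.samples < 0):
                raise ValueError("posterior samples must be nonnegative")
        if self.params is None and self.samples is None:
            raise PosteriorStateError("posterior needs params or samples")

    def draw(self, n: int, seed: int) -> np.ndarray:
        if self.params is None:
            raise PosteriorStateError("sampling requires closed-form params")
        return zinb_sample(self.params, n, seed)


@dataclass
class CredibleInterval:
    lcb: float
    ucb: float
    level: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lcb <= self.ucb):
            raise ValueError("need 0 <= lcb <= ucb")


def point_prediction(post: SitePosterior) -> float:
    """Posterior expected activity: (1-pi)*mu / scale (or the sample mean)."""
    if post.params is not None:
        mean, _, _ = zinb_moments(post.params)
        return float(mean) / post.scale
    return float(post.samples.mean()) / post.scale


def off_target_interval(post: SitePosterior, level: float = 0.95) -> CredibleInterval:
    """One-sided credible interval [0, q_level] on the activity-frequency scale.

    The upper bound is the right-continuous quantile
    ``min{k : CDF(k) >= level}`` when closed-form parameters are available,
    else the nearest-rank empirical quantile of the samples.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if post.params is not None:
        ucb = float(zinb_ppf(level, post.params))
    elif post.samples is not None:
        srt = np.sort(post.samples)
        rank = int(np.ceil(level * srt.size)) - 1
        ucb = float(srt[max(rank, 0)])
    else:
        raise PosteriorStateError("interval needs params or samples")
    return CredibleInterval(0.0, ucb / post.scale, level)


def coefficient_of_variation(post: SitePosterior) -> float:
    """sqrt(variance)/mean of the posterior; scale-invariant; inf at mean 0."""
    if post.params is not None:
        _, _, cv = zinb_moments(post.params)
        return float(cv)
    m = post.samples.mean()
    return float(post.samples.std() / m) if m > 0 else float("inf")


def calibration_curve(
    posteriors: Sequence[SitePosterior],
    observations: Sequence[float],
    grid: Optional[Sequence[float]] = None,
    method: str = "pit",
    seed: int = 0,
) -> np.ndarray:
    """Observed coverage frequency at each nominal one-sided level.

    A well-calibrated forecaster puts p percent of observations below its
    p-quantile, so the plot of (nominal level, observed frequency) should
    follow the identity line.

    ``method="quantile"`` counts observations at or below the
    right-continuous p-quantile of their posterior — conservative on a
    discrete support (coverage >= p by construction, and far above p when
    a zero point mass is large).  ``method="pit"`` uses the randomized
    probability integral transform u = F(y-1) + v * pmf(y), v ~ U(0,1),
    which is exactly uniform when observations are drawn from the
    posteriors themselves and is the default diagnostic.
    """
    obs = np.asarray(observations, dtype=np.float64)
    if len(posteriors) != obs.size:
        raise ValueError(
            f"length mismatch: {len(posteriors)} posteriors vs {obs.size} observations")
    if grid is None:
        grid = np.arange(0.05, 0.951, 0.05)
    grid = np.asarray(grid, dtype=np.float64)
    if np.any(np.diff(grid) <= 0) or np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid must be strictly increasing within (0, 1)")
    y = np.round(obs)
    if method == "quantile":
        hits = np.zeros((grid.size, obs.size), dtype=bool)
        for i, post in enumerate(posteriors):
            if post.params is not None:
                q = zinb_ppf(grid, post.params)
            else:
                srt = np.sort(post.samples)
                ranks = np.maximum(np.ceil(grid * srt.size).astype(int) - 1, 0)
                q = srt[ranks]
            hits[:, i] = y[i] <= q
        return hits.mean(axis=1)
    if method != "pit":
        raise ValueError("method must be 'pit' or 'quantile'")
    rng = np.random.default_rng(seed)
    u = np.empty(obs.size)
    for i, post in enumerate(posteriors):
        if post.params is not None:
            below = float(zinb_cdf(y[i] - 1, post.params))
            pmf = float(np.exp(zinb_log_pmf(y[i], post.params)))
        else:
            below = float(np.mean(post.samples < y[i]))
            pmf = float(np.mean(post.samples == y[i]))
        u[i] = below + rng.random() * pmf
    return np.array([(u <= p).mean() for p in grid])


def sort_by_ucb(posteriors: Sequence[SitePosterior], level: float = 0.95) -> np.ndarray:
    """Indices ordering sites by their UCB (ties broken by mean, then input order)."""
    ucbs = np.array([off_target_interval(p, level).ucb for p in posteriors])
    means = np.array([point_prediction(p) for p in posteriors])
    return np.lexsort((np.arange(len(posteriors)), means, ucbs))
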