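"""Genome-wide sgRNA specificity as a distribution: the aggregate score.

For a guide with one on-target site and M putative off-target sites (found
by an external genome search up to N mismatches), each site's predictive
count distribution is sampled n_samp times and sample s of the specificity
score is

    y_sg[s] = log( sum_i offtarget_draw_i[s] / max(ontarget_draw[s], floor) )

Lower values mean higher genome-wide specificity: a specific guide has
little predicted off-target activity relative to its on-target activity.
The result is kept as a full Monte-Carlo distribution so that guides with
similar mean scores can still be separated by their spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .distributions import ZINBParams, zinb_sample
from .encoding import SgRNATargetPair, mismatch_count

DEFAULT_MAX_MISMATCHES = 5
DEFAULT_N_SAMP = 1000
DEFAULT_ON_TARGET_FLOOR = 1.0


class AggregateInputError(ValueError):
    pass


class SearchParseError(ValueError):
    pass


@dataclass
class AggregateInput:
    """On-target site plus the putative off-target list for one sgRNA."""

    sgrna_seq: str
    on_target: SgRNATargetPair
    off_targets: List[SgRNATargetPair]
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    n_samp: int = DEFAULT_N_SAMP

    def __post_init__(self) -> None:
        if mismatch_count(self.on_target) != 0:
            raise AggregateInputError("on-target site must have 0 mismatches")
        if not self.off_targets:
            raise AggregateInputError("off-target list is empty")
        for ot in self.off_targets:
            m = mismatch_count(ot)
            if m > self.max_mismatches:
                raise AggregateInputError(
                    f"off-target at {ot.chrom}:{ot.start} has {m} mismatches "
                    f"(> {self.max_mismatches})")


@dataclass
class AggregateDistribution:
    """Monte-Carlo samples of the specificity score plus summaries."""

    samples: np.ndarray
    n_off_targets: int
    log_base: str = "natural"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0 or not np.all(np.isfinite(self.samples)):
            raise AggregateInputError("aggregate samples must be nonempty and finite")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def cv(self) -> float:
        m = abs(self.mean)
        return float(self.samples.std() / m) if m > 0 else float("inf")

    def quantile(self, q) -> np.ndarray:
        return np.quantile(self.samples, q)

    def summary(self) -> dict:
        return {
            "mean": self.mean,
            "cv": self.cv,
            "q05": float(self.quantile(0.05)),
            "q50": float(self.quantile(0.50)),
            "q95": float(self.quantile(0.95)),
            "n_samp": int(self.samples.size),
            "n_off_targets": self.n_off_targets,
        }


def aggregate_from_params(
    on_params: ZINBParams,
    off_params: Sequence[ZINBParams],
    n_samp: int = DEFAULT_N_SAMP,
    seed: int = 0,
    floor: float = DEFAULT_ON_TARGET_FLOOR,
) -> AggregateDistribution:
    """Sample the specificity distribution from known per-site parameters.

    Each site is drawn independently ``n_samp`` times; the on-target draws
    are floored (default 1 count) before division to guard against a zero
    denominator.  Natural log.
    """
    if n_samp < 1 or not off_params:
        raise AggregateInputError("need n_samp >= 1 and at least one off-target")
    on_draws = zinb_sample(on_params, n_samp, seed).astype(np.float64)
    total = np.zeros(n_samp)
    for i, p in enumerate(off_params):
        total += zinb_sample(p, n_samp, seed + 1 + i).astype(np.float64)
    ratio = total / np.maximum(on_draws, floor)
    # An all-zero off-target draw would give log(0); floor the numerator at
    # the smallest representable activity of one count for those samples.
    ratio = np.maximum(ratio, np.finfo(float).tiny)
    return AggregateDistribution(np.log(ratio), n_off_targets=len(off_params), seed=seed)


def aggregate_score(model, agg_input: AggregateInput, featurizer, seed: int = 0,
                    floor: float = DEFAULT_ON_TARGET_FLOOR) -> AggregateDistribution:
    """Predict per-site posteriors with a trained model and aggregate them.

    ``featurizer`` maps site pairs to (interface, descriptor) feature
    arrays; see ``guidepost.io.Featurizer``.
    """
    if model is None:
        raise AggregateInputError("a trained model is required")
    pairs = [agg_input.on_target] + list(agg_input.off_targets)
    xs, xp = featurizer.features(pairs)
    params = model.predict_params(xs, xp)
    pi, mu, theta = params.pi, params.mu, params.theta
    on_params = ZINBParams(pi[0], mu[0], theta[0])
    off_params = [ZINBParams(pi[i], mu[i], theta[i]) for i in range(1, len(pairs))]
    return aggregate_from_params(on_params, off_params, agg_input.n_samp, seed, floor)


def aggregate_cdf(dist: AggregateDistribution, grid: Sequence[float]) -> np.ndarray:
    """Right-continuous empirical CDF of the score samples at grid points."""
    grid = np.asarray(grid, dtype=np.float64)
    srt = np.sort(dist.samples)
    return np.searchsorted(srt, grid, side="right") / srt.size


def parse_offtarget_search(path) -> List[SgRNATargetPair]:
    """Parse a genome-search output into site pairs.

    Expected dialect (tab-separated, optional ``#`` comments):
    pattern-with-Ns, matched target sequence, chrom, 0-based position,
    strand, mismatch count.  Duplicate (chrom, start, strand) entries keep
    the first occurrence.
    """
    pairs: List[SgRNATargetPair] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise SearchParseError(f"malformed search line {lineno}: {line!r}")
            pattern, target, chrom, pos, strand = parts[:5]
            try:
                start = int(pos)
            except ValueError as exc:
                raise SearchParseError(f"bad position on line {lineno}: {pos!r}") from exc
            key = (chrom, start, strand)
            if key in seen:
                continue
            seen.add(key)
            try:
                pairs.append(SgRNATargetPair(
                    sgrna_seq=pattern, target_seq=target,
                    chrom=chrom, start=start, strand=strand))
            except ValueError as exc:
                raise SearchParseError(f"invalid site on line {lineno}: {exc}") from exc
    return pairs
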