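"""Check calibration of a set of probabilistic forecasts.

A calibrated forecaster puts p percent of the observations below its
p-quantile.  When the observations are drawn from the forecast
distributions themselves the randomized-PIT diagnostic sits on the
identity line; the discrete-quantile variant is conservative (coverage
above nominal) because of the point mass at zero.
"""

import numpy as np

import guidepost as gp
from guidepost.distributions import ZINBParams
from guidepost.uncertainty import SitePosterior

rng = np.random.default_rng(0)
n = 3000
posteriors = [SitePosterior(ZINBParams(rng.uniform(0.1, 0.7),
                                       10 ** rng.uniform(0.5, 2.5),
                                       10 ** rng.uniform(-0.3, 1.0)))
              for _ in range(n)]
obs = np.array([p.draw(1, seed=100 + i)[0] for i, p in enumerate(posteriors)],
               dtype=float)

grid = np.arange(0.05, 0.951, 0.05)
pit = gp.calibration_curve(posteriors, obs, grid, method="pit", seed=1)
quant = gp.calibration_curve(posteriors, obs, grid, method="quantile")

print("nominal   " + " ".join(f"{g:5.2f}" for g in grid))
print("PIT       " + " ".join(f"{v:5.2f}" for v in pit))
print("quantile  " + " ".join(f"{v:5.2f}" for v in quant))
print(f"max |PIT - nominal|      = {np.max(np.abs(pit - grid)):.3f}  (calibrated)")
print(f"max (quantile - nominal) = {np.max(quant - grid):.3f}  (conservative)")
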