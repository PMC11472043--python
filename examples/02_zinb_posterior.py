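"""Work with a zero-inflated negative binomial site posterior.

A ZINB with zero-inflation pi, mean mu and dispersion theta models sparse,
overdispersed cleavage counts.  From its closed form we get the expected
activity, the coefficient of variation (the per-site uncertainty summary)
and the one-sided 95% credible interval with the lower bound pinned at
zero activity.
"""

import numpy as np

import guidepost as gp
from guidepost.uncertainty import SitePosterior

params = gp.ZINBParams(pi=0.45, mu=120.0, theta=1.3)
post = SitePosterior(params, scale=10_000.0)  # counts -> activity frequency

mean, var, cv = gp.zinb_moments(params)
iv = gp.off_target_interval(post, level=0.95)

print(f"mixture: pi={params.pi}, mu={params.mu}, theta={params.theta}")
print(f"expected count   : {mean:.2f}  (frequency {gp.point_prediction(post):.5f})")
print(f"count variance   : {var:.1f}  -> CV {cv:.2f}")
print(f"95% interval     : [0, {iv.ucb:.5f}] on the frequency scale")
print(f"P(zero count)    : {np.exp(gp.zinb_log_pmf(0, params)):.3f}")

# Monte-Carlo draws agree with the closed form
draws = gp.zinb_sample(params, 100_000, seed=1)
print(f"sampled mean     : {draws.mean():.2f} (closed form {mean:.2f})")
print(f"sampled zero frac: {(draws == 0).mean():.3f}")
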