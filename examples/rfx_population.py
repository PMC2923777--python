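"""Random-effects inference on a population's spatial pattern.

Simulates a cohort whose per-subject patterns are drawn from a population
Dirichlet that over-represents region 1, samples the posterior over the
population mean pattern m and concentration c by MCMC, and prints the
penalised marginal credible intervals next to the chance proportions.
Also compares two informed (fixed-m) models by their RFX evidence.
"""

import numpy as np

from peakpattern import (
    EventCounts, NullPattern, SubjectCounts, MCMCConfig,
    rfx_sample, rfx_intervals, informed_rfx_evidence, CredibleSpec,
)

rng = np.random.default_rng(11)
a = np.array([0.25, 0.35, 0.40])       # chance (resel) proportions
m_true = np.array([0.40, 0.30, 0.30])  # population over-weights region 1
I, k_i, c_true = 16, 120, 40.0

theta = rng.dirichlet(c_true * m_true, size=I)
d = np.array([rng.multinomial(k_i, t) for t in theta])
data = SubjectCounts(counts=tuple(EventCounts(row) for row in d),
                     nulls=(NullPattern(a),))

post = rfx_sample(data, cfg=MCMCConfig(chains=4, iters=6000, burn_in=2000,
                                       seed=5))
print("posterior summary:", post.summary())

spec = CredibleSpec(x=0.99, n=3)
intervals, flags = rfx_intervals(post, data.reference_null(), spec)
print("region   a_j    posterior mean   99% penalised CI      flag")
for j in range(3):
    mj = post.m_pooled[:, j].mean()
    lo, hi = intervals[j]
    print(f"  {j + 1}    {a[j]:.3f}      {mj:.3f}       "
          f"[{lo:.3f}, {hi:.3f}]   {flags[j]}")

log_e_alt = informed_rfx_evidence(data, m_true)
log_e_null = informed_rfx_evidence(data, a)
print(f"informed RFX log BF (m_true vs chance): "
      f"{log_e_alt - log_e_null:.2f}")

# A "rich" flag on region 1 says its population mean proportion exceeds
# its resel share; the informed Bayes factor quantifies how much better
# the generating pattern explains the cohort than chance does.
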