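"""Multivariable MR: direct effects of two correlated exposures.

Builds two simulated instruments whose SNPs affect the outcome through
two exposures with known direct effects (+0.3 and -0.2), assembles the
union-of-instruments multivariable set, and estimates the direct effect
of each exposure with conditional instrument strength.
"""

import numpy as np

from mrgap import mvmr
from mrgap.summary_stats import SummaryStatRecord, select_instrument

rng = np.random.default_rng(11)
J = 40
theta = {"X1": 0.3, "X2": -0.2}

bx1 = rng.normal(0.0, 0.10, J)
bx2 = 0.3 * bx1 + rng.normal(0.0, 0.10, J)  # correlated but not collinear
by = theta["X1"] * bx1 + theta["X2"] * bx2 + rng.normal(0.0, 0.01, J)


def records(betas, se):
    return [
        SummaryStatRecord(f"rs{j}", "A", "G", float(b), se, 1e-12, eaf=0.3)
        for j, b in enumerate(betas)
    ]


ins1 = select_instrument(records(bx1, 0.005), exposure_name="X1")
ins2 = select_instrument(records(bx2, 0.005), exposure_name="X2")
outcome = records(by, 0.01)

mvset = mvmr.build_mvmr_set([ins1, ins2], outcome)
print(f"multivariable set: {mvset.n_snp} SNPs x {mvset.n_exposure} exposures")

estimates = mvmr.mvmr_ivw(mvset)
het = mvmr.mvmr_q(mvset, estimates)
cond_f = mvmr.conditional_f(mvset)
for est in estimates:
    name = est.method.split("[")[1].rstrip("]")
    print(f"  {name}: direct effect = {est.beta:+.3f} +/- {est.se:.3f} "
          f"(true {theta[name]:+.1f}), conditional F = {cond_f[name]:.1f}")
print(f"heterogeneity: Q = {het.Q:.1f} on {het.df} df (I2 = {het.I2:.1f}%)")
print("\nEach coefficient is the effect of that exposure with the other "
      "held fixed; conditional F > 10 means the SNPs separate the two "
      "exposures well enough for the adjustment to be trustworthy.")
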