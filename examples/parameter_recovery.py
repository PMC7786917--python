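"""Parameter recovery on known-truth parametric cohorts.

Draws replicated cohorts from a logistic model with known coefficients,
refits the model and summarizes bias and 95% Wald-interval coverage —
the calibration evidence that the estimator is trustworthy at survey
sample sizes.
"""

import math

import numpy as np

from frailkit import default_parametric_spec, fit_logistic, generate_parametric

spec = default_parametric_spec(n=2000)
n_rep = 200
seeds = np.random.default_rng(0).integers(0, 2**31 - 1, size=n_rep)

bias = {k: [] for k in spec.beta}
covered = {k: 0 for k in spec.beta}
for s in seeds:
    cohort = generate_parametric(spec, seed=int(s))
    fit = fit_logistic(cohort, list(spec.covariates), references=spec.references())
    for key, truth in spec.beta.items():
        cov, _, lvl = key.partition(":")
        term = fit.term(cov, lvl)
        bias[key].append(term.beta - truth)
        covered[key] += term.ci_low <= math.exp(truth) <= term.ci_high

print(f"{n_rep} replicates at n = {spec.n}:")
for key in spec.beta:
    print(
        f"  {key:<18} true beta {spec.beta[key]:+.3f}  "
        f"mean bias {np.mean(bias[key]):+.4f}  coverage {covered[key] / n_rep:.3f}"
    )
# Bias near zero and coverage near 0.95 mean the maximum-likelihood fit and
# its Wald intervals behave as advertised at this sample size.
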