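"""Lindley-approximated Bayes estimators on a simulated sample.

Draws one sample of n = 80 from Frechet(alpha=1, lambda=2, eta=3), fits the
MLE, and computes the LINEX-loss Bayes estimator under the noninformative
prior in both algebraic variants, comparing them with direct quadrature of
the exact posterior.  The `derived` variant is the standard expansion of
E[exp(-k theta)] and should track the quadrature reference closely; the
`as_printed` variant reproduces the commonly typeset bracket.
"""

import numpy as np

import frechetbayes as fb
from frechetbayes.lindley import LossSpec, PriorSpec, posterior_loss_estimate

truth = fb.FrechetParams(1.0, 2.0, 3.0)
data = fb.sample(truth, 80, seed=7)
ml = fb.fit_mle(data)
fisher = fb.observed_fisher(ml.params, data)
prior = PriorSpec("noninformative")
loss = LossSpec("linex", k=1.0)

print("truth:            ", truth.as_array())
print("ML estimate:      ", ml.params.as_array().round(4))
for variant in ("as_printed", "derived"):
    est = fb.estimate_linex(data, prior, loss, ml, fisher, variant=variant)
    print(f"BLNP ({variant:10s}):", est.params.as_array().round(4))
exact = posterior_loss_estimate(data, prior, loss, ml, fisher)
print("exact posterior:  ", exact.round(4))

print(
    "\nWith k = 1 the LINEX loss penalizes overestimation: the exact Bayes"
    "\nestimates adjust the MLE by O(1/n) corrections, and the derived"
    "\nLindley variant reproduces them to a few hundredths here."
)
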