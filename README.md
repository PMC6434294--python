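# frechetbayes

Maximum-likelihood and Lindley-approximated Bayesian estimation for the
**three-parameter Fréchet distribution** (extreme value type II), with a
Monte Carlo engine for comparing the estimators and a goodness-of-fit
workflow for right-skewed survival data.

## The problem

Clinical survival times are typically strongly right-skewed and
heavy-tailed. The three-parameter Fréchet family

```
F(x; α, λ, η) = exp(−((x − η)/λ)^−α),   x > η,   α, λ > 0,
```

with shape `α` (tail heaviness), scale `λ` and location `η` (left endpoint
of the support, allowed to fall below the smallest observation) is a natural
candidate for such data. This package provides, for complete samples:

* **ML estimation** — BFGS quasi-Newton maximization of the log-likelihood
  in transformed coordinates `(log α, log λ, log(min(x) − η))` that enforce
  all constraints smoothly, plus the observed Fisher information and its
  inverse `σ` from fully analytic second derivatives.
* **Bayes estimation via Lindley's approximation** — posterior expectations
  expanded to second order about the MLE, using the analytic third-derivative
  tensor `L_ijk`, the log-prior gradient `ρ`, and the contractions
  `Λ_k = Σ_ij L_ijk σ_ij`. Two asymmetric losses (LINEX, Bayes rule
  `−(1/k) log E[e^{−kθ}]`; general entropy, Bayes rule `E[θ^{−k}]^{−1/k}`)
  crossed with two priors (noninformative `π ∝ 1/(αλη)`; gamma on the scale)
  give the four estimators BLNP, BLGP, BGENP, BGEGP. Each comes in an
  `as_printed` and a `derived` algebraic variant (see `docs/methods.md`),
  and a direct quadrature of the exact posterior is available as a
  reference (`posterior_loss_estimate`).
* **Monte Carlo comparison** — replicate sampling by inverse transform
  `X = η + λ(−ln U)^{−1/α}`, per-cell means, MSEs and Monte Carlo standard
  errors for all five methods, with non-convergent replicates and
  out-of-domain Bayes brackets counted rather than hidden.
* **Goodness of fit** — one-sample Kolmogorov–Smirnov distance against the
  fitted cdf with asymptotic p-values, and a density-overlay plot.

The 44 head-and-neck-cancer survival times (radiotherapy + chemotherapy,
Efron's classic data set) ship as a bundled fixture.

## Worked example

```python
import frechetbayes as fb

data = fb.head_neck_survival()
res = fb.fit_mle(data)
print(res.params)
# FrechetParams(alpha=1.5294016597501918, lam=120.74761613656455, eta=-33.63765091367523)

ks = fb.ks_test(data, res.params)
print(round(ks.D, 4), round(ks.p_value, 4))
# 0.0554 0.9993
```

The fitted shape `α ≈ 1.53` means a very heavy right tail (infinite
variance); the scale is about 121 days, and the fitted support starts 34
days below zero — the location acts purely as a shape-flexibility device
here. The KS distance 0.055 with p ≈ 1 says the fitted cdf is statistically
indistinguishable from the empirical one at any conventional level.

The full five-method report (and the same thing from the shell via
`frechetbayes analyze <file>`):

```python
report = fb.analyze(data)
print(report.to_text())
```

One Monte Carlo cell of the estimator comparison:

```python
from frechetbayes.montecarlo import SimulationCell, run_cell
cell = SimulationCell(truth=fb.FrechetParams(1, 2, 3), n=100, R=500, seed=20240926)
print(run_cell(cell).table.loc[("ML", "alpha")])
# mean 1.0009, mse 0.0194, ...
```

Narrative scripts for each capability live in `examples/`; the CLI exposes
`fit`, `analyze`, `simulate` and `reproduce-tables` (the full
4-configuration × 4-sample-size study) with `--seed`, `--reps`, loss/prior
hyperparameters and a YAML/JSON `--config`.

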