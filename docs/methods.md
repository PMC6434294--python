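# Methods

## Model

The three-parameter Fréchet (extreme value type-II) distribution has cdf
`F(x) = exp(−z^−α)` with `z = (x − η)/λ` on the open ray `x > η`; density,
quantile function `η + λ(−ln u)^{−1/α}`, log-likelihood

```
Ł = n log α + n α log λ − (α+1) Σ log(x_i − η) − Σ ((x_i − η)/λ)^−α ,
```

and all of its first, second and third partial derivatives are implemented
in closed form (`distribution.py`). The support is treated as strictly open:
the density and cdf are defined to be 0 at and below `η`, and standardized
powers whose exponent would underflow `exp` (|exponent| > ~745) return 0
rather than raising. The location may be any real number — for heavy-tailed
positive data the fitted `η` is often negative, acting as a shape device
rather than a physical threshold.

Every analytic derivative is defended in the test suite by central
finite-difference oracles (gradient vs. log-likelihood, Hessian vs.
gradient, third-derivative tensor vs. Hessian) at randomized parameter/data
draws, at relative tolerances 1e−5 / 1e−4 / 1e−3 with measured errors
several orders of magnitude smaller.

## Maximum likelihood

The likelihood is maximized by BFGS in unconstrained coordinates
`(log α, log λ, φ)` with `η = min(x) − exp(φ)`. This enforces `α, λ > 0` and
`η < min(x)` smoothly; no penalty is needed because `Ł → −∞` as
`η → min(x)⁻` (the exponential term dominates the `−(α+1) log w` blow-up),
so the maximizer is interior. The deterministic starting point places
`η₀ = min(x) − 0.1 (median − min)` and solves the two-quantile system of the
Fréchet quantile function at u = 0.25, 0.75 for `(α₀, λ₀)`; on failure the
optimizer restarts up to 5 times from jittered starts.

Tolerances: the optimizer targets gradient norm 1e−8 in the transformed
coordinates; the `converged` flag accepts `‖∇‖ ≤ 1e−5 · (1 + |Ł|)`. The
relative form is deliberate: an absolute 1e−8 sits below the float64
resolution of a likelihood of magnitude ~10², and would brand numerically
exact optima as failures. Non-convergence is always reported, never silent.

The observed Fisher information is the negative analytic Hessian at the fit;
its inverse `σ` must be positive definite (checked by eigenvalue) and feeds
both standard errors and the Lindley machinery.

## Lindley-approximated Bayes estimators

Posterior expectations under this likelihood have no closed form. Lindley's
second-order expansion about the MLE,

```
E[u(θ) | x] ≈ u + Σ u_i b_i + ½ Σ u_ij σ_ij + ½ Σ_k Λ_k Σ_i u_i σ_ik ,
b_i = Σ_j ρ_j σ_ij ,   Λ_k = Σ_ij L_ijk σ_ij ,
```

is applied to `u = e^{−kθ_p}` (LINEX loss) and `u = θ_p^{−k}` (general
entropy), under the noninformative prior `π ∝ 1/(αλη)`
(`ρ = (−1/α, −1/λ, −1/η)`) or a gamma(a, rate b) prior on the scale
(`ρ_λ = (a−1)/λ − b`). The contraction defining `Λ_k` is the unique one
making the expansion agree with direct posterior integration; it is verified
against a brute-force triple loop and, end to end, against quadrature of the
exact posterior.

**Two algebraic variants.** The bracket inside the loss transform is
exposed in two forms because the commonly typeset formulas for this family
are ambiguous about what the loss constant multiplies:

* `derived` — the expansion of the posterior expectation itself: for LINEX,
  `A = 1 − k b_p + (k²/2) σ_pp − (k/2) c_p` with `c_p = Σ_m Λ_m σ_mp`, and
  `θ̂_B = θ̂ − log(A)/k`; for GE,
  `B = 1 − (k/θ̂)(b_p + c_p/2) + k(k+1)/(2θ̂²) σ_pp`, `θ̂_B = θ̂ B^{−1/k}`.
  This variant satisfies the exact limit identities (LINEX k→0 and GE k=−1
  both give the Lindley posterior mean `θ̂ + b_p + c_p/2`), is monotone
  nonincreasing in k (LINEX), and is validated against numerical posterior
  integration (below).
* `as_printed` (default) — the bracket as typeset in the literature this
  package follows: the k-factor multiplies only the prior terms, the
  `σ_pp` correction enters with opposite sign and the `c_p/2` term without a
  k-factor. It reproduces the published simulation behavior of these
  estimators (e.g. the characteristic downward shift of the LINEX shape
  estimate) and is kept as the default for comparability.

A bracket at or below zero makes the estimator undefined; this raises a
named error at the single-estimator level, and in batch use
(`estimate_all`, the Monte Carlo engine) degrades that method to the ML
triple with a `bracket_failure` flag, counted per method. Nonpositive fitted
locations are flagged (`eta_nonpositive`, `ge_nonpositive_theta`); the
formulas are still evaluated as written, since `1/η` is finite for `η ≠ 0`.

**Hyperparameters.** The loss constant `k` and the gamma hyperparameters
`(a, b)` default to 1.0 each; a log warning is emitted whenever the defaults
are used, and every result records them. `k` is scale-sensitive: the LINEX
loss grows like `exp(k · error)` in the parameter's own units, so for data
with a large scale (the bundled survival times, `λ̂ ≈ 120`) `k = 1` is
extremely aggressive and the brackets often leave their domain — visibly
flagged, not hidden.

**Exact-posterior reference.** `posterior_loss_estimate` integrates the
exact posterior (likelihood × prior, normalized) on a tensor-product
Gauss–Legendre grid (40³ nodes) over a box of ±6 posterior standard
deviations around the MLE, clipped to `α, λ > 0` and `η < min(x)`, with the
log-posterior stabilized by its maximum and the LINEX expectation computed
relative to `e^{−kθ̂}`. On data simulated from Fréchet(1, 2, 3) the
derived-variant estimates agree with this reference to well within a tenth
of a posterior standard deviation at n = 200 and within half at n = 50, the
discrepancy shrinking with n. The location parameter is consistently the
weakest: its posterior is the most skewed, and on weakly informative draws
the n = 50 discrepancy can reach the order of one standard deviation — an
honest limit of a second-order expansion, which is why the quadrature
reference is part of the public API.

## Monte Carlo engine

A simulation cell is (true triple, n, R, seed, hyperparameters). Replicate
seeds are spawned from `numpy.random.SeedSequence(seed)`, so results are
bitwise reproducible and independent of execution order; uniforms come from
PCG64 and samples from the inverse transform (which guarantees `x > η`, so
no rejection step is needed). Non-convergent ML replicates are discarded and
counted — not resampled, to keep the estimand honest — and a cell with more
than 10% discards is flagged unreliable. Bayes bracket failures remove only
that method's replicate. Reported per method × parameter: mean estimate,
MSE about the truth, and Monte Carlo standard errors of both.

The full study (`reproduce_tables`) runs truths (1,2,3), (1,1,4),
(0.5,1.5,3), (1,2,4) at n ∈ {25, 50, 70, 100}. At R = 3000 it takes a few
minutes on one CPU; R = 50 is a seconds-level smoke scale. The acceptance
tests run the published-value spot checks at R = 500 (tolerances widened
proportionally, i.e. three Monte Carlo standard errors of the difference at
that replication count) and the monotonicity and efficiency checks at
R = 3000. Observed behavior worth knowing: at n = 25 the ML estimates
occasionally blow up (heavy-tailed, weakly identified location), inflating
MSEs, and 10–40% of as-printed Bayes brackets fail; both effects shrink
rapidly with n and are reported in the cell counts.

## Goodness of fit

The one-sample KS statistic uses the exact order-statistic form
`D = max_i max(i/n − F(x_(i)), F(x_(i)) − (i−1)/n)`; points at or below the
fitted location contribute `F = 0` and inflate D naturally. P-values use the
asymptotic Kolmogorov distribution of `√n D` and ignore the effect of
parameter estimation (the usual descriptive practice; noted in every report
footer). Report tables render at 4 decimals; CSVs keep full precision.

## Synthetic data and what the tests show

All simulated data come from the package's own inverse-transform sampler at
the four study configurations above — exact draws from the model, i.i.d.,
complete (no censoring), at the study's n ∈ {25..100}. Passing tests
therefore demonstrate correctness of the estimators and their stated
asymptotics *under the model*; they say nothing about robustness to
censoring, contamination, or misspecified tails, which real survival data
exhibit. The bundled 44 survival times are the one real-data check, and
there the heavy tail and small n push the Bayes machinery to its flagged
limits by design.

## Known limitations

* Lindley's approximation is anchored at the MLE: it inherits any ML
  pathology, degrades on weakly informative samples (especially for the
  location), and provides no internal error estimate — use the quadrature
  reference when in doubt.
* The noninformative prior `1/(αλη)` is improper and ill-behaved near
  `η = 0`; fitted locations near zero make `ρ_η = −1/η` explode.
* GE loss is defined for positive parameters; for negative fitted locations
  the estimator is evaluated formally and flagged.
* No censored-data likelihoods; no MCMC/Laplace alternatives.
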