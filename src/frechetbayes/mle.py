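"""Maximum-likelihood fitting of the three-parameter Frechet distribution.

The log-likelihood is maximized by BFGS in unconstrained transformed
coordinates ``(log alpha, log lambda, phi)`` with ``eta = min(x) - exp(phi)``,
which enforces ``alpha > 0``, ``lambda > 0`` and ``eta < min(x)`` smoothly.
The likelihood itself vanishes as ``eta`` approaches ``min(x)`` (the
exponential tail term dominates), so the maximizer is interior.

Also provides the observed Fisher information (negative analytic Hessian at
the fit) and its inverse, the sigma matrix feeding Lindley's approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .distribution import (
    FrechetParams,
    Sample,
    loglik,
    loglik_hessian,
    score,
)

__all__ = [
    "OptimizerOptions",
    "EstimationResult",
    "FisherInfo",
    "FisherInfoError",
    "default_init",
    "fit_mle",
    "observed_fisher",
]


@dataclass(frozen=True)
class OptimizerOptions:
    """BFGS settings for :func:`fit_mle`.

    ``gtol`` is the optimizer's gradient target in transformed coordinates;
    ``conv_tol`` is the (looser) gradient-norm threshold, relative to the
    likelihood scale, below which the result is flagged converged.
    """

    gtol: float = 1e-8
    conv_tol: float = 1e-5
    maxiter: int = 500
    restarts: int = 5
    init: FrechetParams | None = None


@dataclass(frozen=True)
class EstimationResult:
    """A fitted parameter triple plus diagnostics for one method."""

    method: str
    params: FrechetParams
    converged: bool
    iterations: int = 0
    final_grad_norm: float = float("nan")
    loglik: float = float("nan")
    warnings: tuple = ()
    meta: dict = field(default_factory=dict, compare=False)


class FisherInfoError(RuntimeError):
    """Observed information is singular or not positive definite."""

    def __init__(self, message: str, matrix: np.ndarray):
        super().__init__(message)
        self.matrix = matrix


@dataclass(frozen=True)
class FisherInfo:
    """Observed Fisher information and its inverse (the sigma matrix).

    ``info`` is the negative Hessian of the log-likelihood at the fitted
    parameters, ordered (alpha, lambda, eta); ``sigma`` is its inverse whose
    entries are the posterior-curvature weights of Lindley's approximation
    and whose diagonal approximates the ML estimator variances.
    """

    info: np.ndarray
    sigma: np.ndarray

    @property
    def std_errors(self) -> np.ndarray:
        d = np.diag(self.sigma)
        return np.sqrt(np.where(d > 0, d, np.nan))


def default_init(data: Sample) -> FrechetParams:
    """Deterministic starting triple from order statistics.

    The location starts a small margin below the sample minimum,
    ``eta0 = min - 0.1 (median - min)``; shape and scale then solve the
    two-quantile system of the Frechet quantile function at u = 0.25, 0.75
    applied to the shifted data.
    """
    x = data.values
    xmin = float(x.min())
    med = float(np.median(x))
    spread = med - xmin
    if spread <= 0:
        raise ValueError("data have no spread between minimum and median; "
                         "the three-parameter model is unidentifiable")
    eta0 = xmin - 0.1 * spread
    q25, q75 = np.quantile(x - eta0, [0.25, 0.75])
    if not q75 > q25 > 0:
        raise ValueError("degenerate interquartile range; cannot initialize")
    # q_u = lam * (-log u)^(-1/alpha)  =>  alpha from the quantile ratio
    c25, c75 = -np.log(0.25), -np.log(0.75)
    alpha0 = np.log(c25 / c75) / np.log(q75 / q25)
    lam0 = q25 * c25 ** (1.0 / alpha0)
    return FrechetParams(float(alpha0), float(lam0), float(eta0))


def _to_internal(params: FrechetParams, xmin: float) -> np.ndarray:
    gap = xmin - params.eta
    if gap <= 0:
        raise ValueError("initial eta must lie below min(data)")
    return np.array([np.log(params.alpha), np.log(params.lam), np.log(gap)])


def _from_internal(z: np.ndarray, xmin: float) -> FrechetParams:
    return FrechetParams(float(np.exp(z[0])), float(np.exp(z[1])),
                         float(xmin - np.exp(z[2])))


def _negloglik_and_grad(z: np.ndarray, data: Sample, xmin: float):
    with np.errstate(all="ignore"):
        a = np.exp(z[0])
        l = np.exp(z[1])
        gap = np.exp(z[2])
        eta = xmin - gap
        w = data.values - eta  # = (x - xmin) + gap > 0 always
        n = data.n
        logw = np.log(w)
        u = logw - z[1]
        t = np.exp(-a * u)
        ll = n * z[0] + n * a * z[1] - (a + 1.0) * logw.sum() - t.sum()
        d_a = n / a + n * z[1] - logw.sum() + (t * u).sum()
        d_l = n * a / l - (a / l) * t.sum()
        d_e = (a + 1.0) * (1.0 / w).sum() - a * (t / w).sum()
        # chain rule: d/dlog a = a * d/da; d eta/d phi = -gap
        grad = np.array([a * d_a, l * d_l, -gap * d_e])
    if not (np.isfinite(ll) and np.all(np.isfinite(grad))):
        # a wild line-search step under/overflowed; force backtracking
        return np.inf, np.zeros(3)
    return -ll, -grad


def fit_mle(
    data: Sample,
    init: FrechetParams | None = None,
    options: OptimizerOptions | None = None,
) -> EstimationResult:
    """Fit the three-parameter Frechet distribution by quasi-Newton ML.

    Parameters
    ----------
    data : Sample
        Observations; at least 4 are required (three parameters plus one
        degree of freedom).
    init : FrechetParams, optional
        Starting triple; defaults to :func:`default_init`.
    options : OptimizerOptions, optional
        Tolerances, iteration limits and restart count.

    Returns
    -------
    EstimationResult
        With ``method="ML"``; ``converged`` is False when no restart
        reached the gradient tolerance (never a silent success).
    """
    opts = options or OptimizerOptions()
    if data.n < 4:
        raise ValueError("need at least 4 observations to fit three parameters")
    start = init or opts.init or default_init(data)
    xmin = data.min

    rng = np.random.default_rng(0)
    z0 = _to_internal(start, xmin)
    best = None
    n_iter = 0
    for attempt in range(opts.restarts + 1):
        z_try = z0 if attempt == 0 else z0 + rng.normal(scale=0.3 * attempt, size=3)
        res = optimize.minimize(
            _negloglik_and_grad,
            z_try,
            args=(data, xmin),
            jac=True,
            method="BFGS",
            options={"gtol": opts.gtol, "maxiter": opts.maxiter},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
        gnorm = float(np.linalg.norm(best.jac))
        if gnorm <= opts.conv_tol * (1.0 + abs(best.fun)):
            break

    params = _from_internal(best.x, xmin)
    gnorm = float(np.linalg.norm(best.jac))
    converged = gnorm <= opts.conv_tol * (1.0 + abs(best.fun))
    warn = () if converged else ("no_convergence",)
    return EstimationResult(
        method="ML",
        params=params,
        converged=converged,
        iterations=n_iter,
        final_grad_norm=gnorm,
        loglik=float(-best.fun),
        warnings=warn,
        meta={"optimizer": "BFGS", "gtol": opts.gtol, "restarts_used": attempt},
    )


def observed_fisher(params: FrechetParams, data: Sample) -> FisherInfo:
    """Observed Fisher information (negative analytic Hessian) and its inverse.

    Raises
    ------
    FisherInfoError
        If the information matrix is singular or not positive definite;
        the offending matrix rides along for diagnostics.
    """
    info = -loglik_hessian(params, data)
    eig = np.linalg.eigvalsh(info)
    if eig.min() <= 0 or not np.all(np.isfinite(eig)):
        raise FisherInfoError(
            f"observed information not positive definite (eigenvalues {eig})", info
        )
    sigma = np.linalg.inv(info)
    sigma = 0.5 * (sigma + sigma.T)
    return FisherInfo(info=info, sigma=sigma)
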