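"""Three-parameter Frechet (extreme value type-II) distribution.

The distribution of maxima with cdf

    F(x; alpha, lambda, eta) = exp(-((x - eta)/lambda)^(-alpha)),   x > eta,

where ``alpha > 0`` is the shape, ``lambda > 0`` the scale and ``eta`` the
location (threshold).  The support is the open ray ``x > eta``; at and below
``eta`` the density and cdf are zero.  All log-likelihood derivatives used by
the estimation layers are computed here analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrechetParams",
    "Sample",
    "ParameterDomainError",
    "SupportViolationError",
    "pdf",
    "cdf",
    "quantile",
    "sample",
    "loglik",
    "score",
]

# exp(-z) underflows to exactly 0 for z beyond this; used to short-circuit
# rather than raise on extreme tail evaluations
_EXP_UNDERFLOW = 745.0


class ParameterDomainError(ValueError):
    """Raised when a parameter triple violates alpha > 0 or lambda > 0."""


class SupportViolationError(ValueError):
    """Raised when data fall outside the open support ``x > eta``."""


@dataclass(frozen=True)
class FrechetParams:
    """Parameter triple (shape, scale, location) of the Frechet distribution.

    Parameters
    ----------
    alpha : float
        Shape, dimensionless, must be positive.
    lam : float
        Scale, in the units of the data, must be positive.
    eta : float
        Location (left endpoint of the support), any real.
    """

    alpha: float
    lam: float
    eta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ParameterDomainError(f"shape alpha must be > 0, got {self.alpha}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ParameterDomainError(f"scale lambda must be > 0, got {self.lam}")
        if not np.isfinite(self.eta):
            raise ParameterDomainError(f"location eta must be finite, got {self.eta}")

    def as_array(self) -> np.ndarray:
        """Return the triple as an ndarray ordered (alpha, lambda, eta)."""
        return np.array([self.alpha, self.lam, self.eta], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "FrechetParams":
        a, l, e = (float(v) for v in theta)
        return cls(a, l, e)


@dataclass(frozen=True)
class Sample:
    """An i.i.d. univariate sample of positive spread, stored sorted-free.

    ``values`` keeps the original order; ``n`` is its length.
    """

    values: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).ravel()
        if arr.size < 1:
            raise ValueError("a sample needs at least one observation")
        if not np.all(np.isfinite(arr)):
            raise ValueError("sample contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def min(self) -> float:
        return float(self.values.min())

    @classmethod
    def from_iterable(cls, values: Iterable[float], **meta) -> "Sample":
        return cls(np.fromiter((float(v) for v in values), dtype=float), meta=dict(meta))


def _check_support(data: Sample, params: FrechetParams) -> np.ndarray:
    w = data.values - params.eta
    if np.any(w <= 0):
        raise SupportViolationError(
            f"all observations must exceed eta={params.eta}; min(data)={data.min}"
        )
    return w


def pdf(x, params: FrechetParams):
    """Density f(x) = (a/l) * z^(-a-1) * exp(-z^(-a)) with z = (x-eta)/l.

    Zero at and below the location; vectorized over ``x``.
    """
    x = np.asarray(x, dtype=float)
    z = (x - params.eta) / params.lam
    out = np.zeros_like(z)
    pos = z > 0
    zp = z[pos]
    with np.errstate(over="ignore", divide="ignore"):
        t = zp ** (-params.alpha)
        val = np.where(
            t > _EXP_UNDERFLOW,
            0.0,
            (params.alpha / params.lam) * zp ** (-params.alpha - 1.0) * np.exp(-t),
        )
    out[pos] = val
    return out if out.ndim else float(out)


def cdf(x, params: FrechetParams):
    """Distribution function exp(-((x-eta)/lambda)^(-alpha)), 0 below eta."""
    x = np.asarray(x, dtype=float)
    z = (x - params.eta) / params.lam
    out = np.zeros_like(z)
    pos = z > 0
    with np.errstate(over="ignore"):
        t = z[pos] ** (-params.alpha)
    out[pos] = np.where(t > _EXP_UNDERFLOW, 0.0, np.exp(-t))
    return out if out.ndim else float(out)


def quantile(u, params: FrechetParams):
    """Inverse cdf: eta + lambda * (-log u)^(-1/alpha) for u in (0, 1)."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("quantile argument must lie strictly inside (0, 1)")
    out = params.eta + params.lam * (-np.log(u)) ** (-1.0 / params.alpha)
    return out if out.ndim else float(out)


def sample(params: FrechetParams, n: int, seed) -> Sample:
    """Draw ``n`` i.i.d. variates by inverse-transform sampling.

    Uniform variates come from ``numpy.random.default_rng(seed)`` (PCG64);
    ``seed`` may be an int or a ``SeedSequence``/``Generator``.  Identical
    seeds give identical samples.
    """
    if n < 1:
        raise ValueError("sample size must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # open-interval uniforms: random() returns [0,1); flip to (0,1]
    u = 1.0 - rng.random(n)
    values = params.eta + params.lam * (-np.log(u)) ** (-1.0 / params.alpha)
    return Sample(values, meta={"params": params, "rng": "PCG64"})


# ---------------------------------------------------------------------------
# log-likelihood and its analytic derivatives
#
# With w_i = x_i - eta, u_i = log(w_i / lambda), t_i = (w_i/lambda)^(-alpha):
#   L = n log a + n a log l - (a+1) sum log w_i - sum t_i
# All first/second/third partials below follow from
#   dt/da = -u t,  dt/dl = (a/l) t,  dt/deta = (a/w) t,
#   du/dl = -1/l,  du/deta = -1/w.
# ---------------------------------------------------------------------------


def _wut(params: FrechetParams, data: Sample):
    w = _check_support(data, params)
    u = np.log(w / params.lam)
    t = np.exp(-params.alpha * u)
    return w, u, t


def loglik(params: FrechetParams, data: Sample) -> float:
    """Log-likelihood of the sample under the given parameter triple."""
    w, u, t = _wut(params, data)
    n = data.n
    a, l = params.alpha, params.lam
    return float(
        n * np.log(a) + n * a * np.log(l) - (a + 1.0) * np.log(w).sum() - t.sum()
    )


def score(params: FrechetParams, data: Sample) -> np.ndarray:
    """Gradient of the log-likelihood, ordered (alpha, lambda, eta)."""
    w, u, t = _wut(params, data)
    n = data.n
    a, l = params.alpha, params.lam
    d_a = n / a + n * np.log(l) - np.log(w).sum() + (t * u).sum()
    d_l = n * a / l - (a / l) * t.sum()
    d_e = (a + 1.0) * (1.0 / w).sum() - a * (t / w).sum()
    return np.array([d_a, d_l, d_e])


def loglik_hessian(params: FrechetParams, data: Sample) -> np.ndarray:
    """Analytic 3x3 Hessian of the log-likelihood, ordered (alpha, lambda, eta)."""
    w, u, t = _wut(params, data)
    n = data.n
    a, l = params.alpha, params.lam
    st = t.sum()
    H = np.empty((3, 3))
    H[0, 0] = -n / a**2 - (u * u * t).sum()
    H[0, 1] = H[1, 0] = n / l - (t * (1.0 - a * u)).sum() / l
    H[0, 2] = H[2, 0] = ((1.0 - t * (1.0 - a * u)) / w).sum()
    H[1, 1] = -n * a / l**2 + a * (1.0 - a) / l**2 * st
    H[1, 2] = H[2, 1] = -(a**2 / l) * (t / w).sum()
    H[2, 2] = (a + 1.0) * ((1.0 - a * t) / w**2).sum()
    return H


def loglik_third_derivatives(params: FrechetParams, data: Sample) -> np.ndarray:
    """Analytic symmetric 3x3x3 tensor of third log-likelihood partials.

    Index order (alpha, lambda, eta); the ten distinct values are computed
    in closed form and mirrored into all index permutations.
    """
    w, u, t = _wut(params, data)
    n = data.n
    a, l = params.alpha, params.lam
    st = t.sum()
    tw = (t / w).sum()
    tw2 = (t / w**2).sum()
    iw2 = (1.0 / w**2).sum()
    iw3 = (1.0 / w**3).sum()

    d_aaa = 2.0 * n / a**3 + (u**3 * t).sum()
    d_aal = (u * t * (2.0 - a * u)).sum() / l
    d_aae = (u * t * (2.0 - a * u) / w).sum()
    d_all = -n / l**2 + (t * (1.0 - 2.0 * a + a * (a - 1.0) * u)).sum() / l**2
    d_ale = -(a / l) * (t * (2.0 - a * u) / w).sum()
    d_aee = iw2 - (t * (2.0 * a + 1.0 - a * (a + 1.0) * u) / w**2).sum()
    d_lll = 2.0 * n * a / l**3 + a * (1.0 - a) * (a - 2.0) / l**3 * st
    d_lle = a**2 * (1.0 - a) / l**2 * tw
    d_lee = -(a**2 * (a + 1.0) / l) * tw2
    d_eee = 2.0 * (a + 1.0) * iw3 - a * (a + 1.0) * (a + 2.0) * (t / w**3).sum()

    L3 = np.zeros((3, 3, 3))
    vals = {
        (0, 0, 0): d_aaa,
        (0, 0, 1): d_aal,
        (0, 0, 2): d_aae,
        (0, 1, 1): d_all,
        (0, 1, 2): d_ale,
        (0, 2, 2): d_aee,
        (1, 1, 1): d_lll,
        (1, 1, 2): d_lle,
        (1, 2, 2): d_lee,
        (2, 2, 2): d_eee,
    }
    for (i, j, k), v in vals.items():
        for p in {(i, j, k), (i, k, j), (j, i, k), (j, k, i), (k, i, j), (k, j, i)}:
            L3[p] = v
    return L3
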