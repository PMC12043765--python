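"""First-hitting-time (FHT) distribution of a homogeneous gamma process.

Degradation is modelled as a gamma process D(t) with shape function
``alpha(t) = a t`` and rate-like scale ``beta``: increments over an
interval of length s are Gamma(a s, beta) and paths are nondecreasing.
The event time is the first time the process crosses a threshold c,

    T = inf{ t : D(t) >= c }.

Because the law of T depends on beta and c only through their product,
the threshold is fixed at c = 1 and beta carries the scale.  The cdf is
the regularized *upper* incomplete gamma ratio

    F_T(t) = Gamma(a t, beta) / Gamma(a t) = Q(a t, beta),

so survival is the gamma cdf S_T(t) = P(a t, beta), and the density is

    f_T(t) = d/dt Q(a t, beta) = -a * dP/dalpha(a t, beta),

evaluated through the shape derivatives in :mod:`gammafht.incgamma`.
An independent hypergeometric-series form of the density
(:func:`fht_pdf_series`) is retained as a cross-check oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .incgamma import _dP_dalpha_both

__all__ = [
    "GammaFHTParams",
    "SurvivalDataset",
    "fht_cdf",
    "fht_survival",
    "fht_pdf",
    "fht_logpdf",
    "fht_log_survival",
    "fht_pdf_series",
    "loglik",
    "mean_degradation",
    "mean_fht_approx",
]

_TINY = 1e-300


@dataclass(frozen=True)
class GammaFHTParams:
    """Gamma-process parameters: shape rate ``a`` (1/time) and scale ``beta``.

    The crossing threshold is fixed at c = 1; only the product beta*c is
    identifiable, so beta is the parameter of interest.
    """

    a: float
    beta: float

    def __post_init__(self):
        if not (math.isfinite(self.a) and self.a > 0):
            raise ValueError(f"a must be finite and > 0, got {self.a}")
        if not (math.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")


@dataclass
class SurvivalDataset:
    """Right-censored survival data with a leading-intercept design matrix.

    Attributes
    ----------
    times : observed times t_i > 0 (event or censoring time).
    status : event indicators, 1 = event observed, 0 = right-censored.
    X : n x (p+1) covariate matrix whose first column is identically 1.
    columns : names for the p covariate columns (excluding the intercept).
    """

    times: np.ndarray
    status: np.ndarray
    X: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status)
        self.X = np.asarray(self.X, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        n = self.times.shape[0]
        if self.status.shape != (n,) or self.X.shape[0] != n:
            raise ValueError("times, status and X must have matching lengths")
        if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
            raise ValueError("times must be finite and strictly positive")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must contain only 0 (censored) and 1 (event)")
        self.status = self.status.astype(int)
        if np.any(~np.isfinite(self.X)):
            raise ValueError("X must not contain missing/non-finite values")
        if self.X.ndim != 2 or not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("X must be 2-D with an all-ones first column")
        if not self.columns:
            self.columns = [f"x{j}" for j in range(1, self.X.shape[1])]
        if len(self.columns) != self.X.shape[1] - 1:
            raise ValueError("column names must match the covariate count")

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1] - 1


def _unpack(params):
    if isinstance(params, GammaFHTParams):
        return params.a, params.beta
    a, beta = params
    a = np.asarray(a, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(a <= 0) or np.any(~np.isfinite(a)):
        raise ValueError("a must be finite and > 0")
    if np.any(beta <= 0) or np.any(~np.isfinite(beta)):
        raise ValueError("beta must be finite and > 0")
    return a, beta


def fht_cdf(t, params, *, threshold: float = 1.0):
    """P(T <= t) = Q(a t, threshold * beta); t = 0 returns the limit 0.

    ``threshold`` exposes the general c > 0 form Q(a t, c beta); the model
    surface keeps c = 1.
    """
    a, beta = _unpack(params)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("t must be nonnegative")
    out = np.where(
        np.isinf(t),
        1.0,
        special.gammaincc(np.maximum(a * np.where(np.isinf(t), 1.0, t), _TINY),
                          threshold * beta),
    )
    out = np.where(t == 0, 0.0, out)
    return out if out.ndim else float(out)


def fht_survival(t, params, *, threshold: float = 1.0):
    """S(t) = P(a t, beta): computed as the complementary regularized gamma."""
    a, beta = _unpack(params)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("t must be nonnegative")
    out = np.where(
        np.isinf(t),
        0.0,
        special.gammainc(np.maximum(a * np.where(np.isinf(t), 1.0, t), _TINY),
                         threshold * beta),
    )
    out = np.where(t == 0, 1.0, out)
    return out if out.ndim else float(out)


def fht_pdf(t, params):
    """FHT density f(t) = -a * dP/dalpha(a t, beta), nonnegative."""
    a, beta = _unpack(params)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or np.any(~np.isfinite(t)):
        raise ValueError("t must be finite and strictly positive")
    alpha = a * t
    d1, _ = _dP_dalpha_both(np.asarray(alpha, dtype=float), np.asarray(beta, dtype=float))
    out = np.maximum(-(np.asarray(a) * d1.reshape(np.shape(alpha))), 0.0)
    return out if out.ndim else float(out)


def fht_logpdf(t, params):
    """log f(t); -inf where the density underflows."""
    a, beta = _unpack(params)
    dens = np.asarray(fht_pdf(t, params), dtype=float)
    with np.errstate(divide="ignore"):
        return np.log(dens)


def fht_log_survival(t, params):
    """log S(t); -inf where survival underflows."""
    s = np.asarray(fht_survival(t, params), dtype=float)
    with np.errstate(divide="ignore"):
        return np.log(s)


def fht_pdf_series(t, params, *, rtol: float = 1e-14, max_terms: int = 10_000,
                   dps: int = 30):
    """High-precision density via the generalized hypergeometric form.

    f(t) = a (psi0(at) - ln beta) P(at, beta)
           + a beta^{at} 2F2(at, at; at+1, at+1; -beta) / ((at)^2 Gamma(at)),

    evaluated with mpmath at ``dps`` decimal digits.  This route is an
    independent oracle for :func:`fht_pdf`; it is not used in fitting.
    """
    import mpmath as mp

    a, beta = _unpack(params)
    a = float(a)
    beta = float(beta)
    t = float(t)
    if t <= 0:
        raise ValueError("t must be > 0")
    with mp.workdps(dps):
        at = mp.mpf(a) * mp.mpf(t)
        b = mp.mpf(beta)
        P = mp.gammainc(at, 0, b, regularized=True)
        lead = a * (mp.digamma(at) - mp.log(b)) * P
        f22 = mp.hyper([at, at], [at + 1, at + 1], -b, maxterms=max_terms)
        tail = a * mp.power(b, at) * f22 / (at * at * mp.gamma(at))
        val = lead + tail
    return float(val)


def loglik(data: SurvivalDataset, a_i, beta_i) -> float:
    """Censored log-likelihood: sum of d_i log f(t_i) + (1-d_i) log S(t_i).

    May return -inf when a density or survival term underflows for some
    observation; callers treating this as an error should check finiteness.
    """
    a_i = np.asarray(a_i, dtype=float)
    beta_i = np.asarray(beta_i, dtype=float)
    if a_i.shape != (data.n,) or beta_i.shape != (data.n,):
        raise ValueError("a_i and beta_i must have length n")
    if np.any(np.isnan(a_i)) or np.any(np.isnan(beta_i)):
        raise ValueError("parameter vectors must not contain NaN")
    if np.any(a_i <= 0) or np.any(beta_i <= 0):
        raise ValueError("parameter vectors must be strictly positive")
    ev = data.status == 1
    total = 0.0
    if ev.any():
        total += float(np.sum(fht_logpdf(data.times[ev], (a_i[ev], beta_i[ev]))))
    if (~ev).any():
        total += float(np.sum(fht_log_survival(data.times[~ev], (a_i[~ev], beta_i[~ev]))))
    return total


def mean_degradation(t, params):
    """Expected degradation level E[D(t)] = a t / beta."""
    a, beta = _unpack(params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = a * t / beta
    return out if out.ndim else float(out)


def mean_fht_approx(params):
    """Approximate expected hitting time (beta + 1/2) / a for threshold 1."""
    a, beta = _unpack(params)
    return (beta + 0.5) / a
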