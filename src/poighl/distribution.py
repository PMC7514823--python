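"""Distribution functions for the Poisson generalized half logistic family.

The PoiGHL(alpha, lam, a) random variable is the minimum of ``M`` iid
generalized half logistic (GHL) variates, where ``M`` is zero-truncated
Poisson(lam).  Writing ``T(x) = tanh(alpha x / 2)`` (an algebraic rewrite of
``(1 - e^{-alpha x}) / (1 + e^{-alpha x})``), the GHL cdf is ``G(x) = T(x)^a``
and the PoiGHL cdf is

    F(x) = (1 - exp(-lam * G(x))) / (1 - exp(-lam)).

A change of variables central to the whole package: ``V = G(X)`` follows a
truncated exponential law with density ``lam * exp(-lam v) / (1 - exp(-lam))``
on (0, 1).  Expectations over X are computed by substituting
``x(v) = (2 / alpha) * atanh(v^{1/a})``, which removes both the infinite
domain and the ``x -> 0`` density singularity that occurs for ``a < 1``.

All exponentials go through ``expm1``/``log1p`` forms so that ``lam`` and
``alpha * x`` up to ~700 are handled without overflow or cancellation.
"""

from __future__ import annotations

from typing import Callable, Union

import numpy as np
from scipy import integrate

from .params import (
    DEFAULT_QUAD,
    GHLParams,
    LPoiGHLParams,
    PoiGHLParams,
    QuadratureSpec,
)

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "ghl_cdf",
    "ghl_logpdf",
    "ghl_pdf",
    "ghl_quantile",
    "cdf",
    "pdf",
    "logpdf",
    "sf",
    "hrf",
    "quantile",
    "sample",
    "bowley_skewness",
    "moors_kurtosis",
    "submodel",
    "lpoighl_cdf",
    "lpoighl_pdf",
    "density_decreasing_condition",
    "x_of_v",
    "logpdf_of_v",
    "expect",
]


def _check_nonneg(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    return x


# ---------------------------------------------------------------------------
# GHL baseline (also the lam -> 0 limit of PoiGHL)

def ghl_cdf(x: ArrayLike, alpha: float, a: float) -> ArrayLike:
    """GHL cdf G(x) = tanh(alpha x / 2)^a."""
    x = _check_nonneg(x)
    return np.tanh(alpha * x / 2.0) ** a


def ghl_logpdf(x: ArrayLike, alpha: float, a: float) -> ArrayLike:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be positive")
    t = alpha * x
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            np.log(2.0 * a * alpha)
            - t
            + (a - 1.0) * np.log(-np.expm1(-t))
            - (a + 1.0) * np.log1p(np.exp(-t))
        )
    if np.ndim(out) == 0:
        return float(out)
    return out


def ghl_pdf(x: ArrayLike, alpha: float, a: float) -> ArrayLike:
    return np.exp(ghl_logpdf(x, alpha, a))


def ghl_quantile(prob: ArrayLike, alpha: float, a: float) -> ArrayLike:
    prob = np.asarray(prob, dtype=float)
    if np.any((prob <= 0) | (prob >= 1)):
        raise ValueError("prob must lie in (0, 1)")
    return 2.0 / alpha * np.arctanh(prob ** (1.0 / a))


# ---------------------------------------------------------------------------
# PoiGHL

def cdf(x: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    """PoiGHL cdf; F(0) = 0 and F is nondecreasing on [0, inf)."""
    x = _check_nonneg(x)
    g = np.tanh(p.alpha * x / 2.0) ** p.a
    out = np.expm1(-p.lam * g) / np.expm1(-p.lam)
    if np.ndim(out) == 0:
        return float(out)
    return out


def sf(x: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    """Survival function 1 - F, computed without cancellation in the tail."""
    x = _check_nonneg(x)
    g = np.tanh(p.alpha * x / 2.0) ** p.a
    # (e^{-lam g} - e^{-lam}) / (1 - e^{-lam})
    out = (np.exp(-p.lam * g) - np.exp(-p.lam)) / (-np.expm1(-p.lam))
    if np.ndim(out) == 0:
        return float(out)
    return out


def logpdf(x: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    """Log density.  At x = 0 the density diverges for a < 1 (+inf is
    returned), is ``alpha lam / (2 (1 - e^{-lam}))`` for a = 1, and 0 for
    a > 1 (-inf is returned)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be positive")
    alpha, lam, a = p.astuple()
    t = alpha * x
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            np.log(2.0 * a * alpha * lam)
            - t
            + (a - 1.0) * np.log(-np.expm1(-t))
            - (a + 1.0) * np.log1p(np.exp(-t))
            - lam * np.tanh(t / 2.0) ** a
            - np.log(-np.expm1(-lam))
        )
    # limits at the origin
    if a < 1.0:
        out = np.where(x == 0.0, np.inf, out)
    elif a == 1.0:
        lim = np.log(alpha * lam / (2.0 * (-np.expm1(-lam))))
        out = np.where(x == 0.0, lim, out)
    else:
        out = np.where(x == 0.0, -np.inf, out)
    if np.ndim(out) == 0:
        return float(out)
    return out


def pdf(x: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    out = np.exp(logpdf(x, p))
    if np.ndim(out) == 0:
        return float(out)
    return out


def hrf(x: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    """Hazard rate f / S; shares the x -> 0 limits of the density."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(logpdf(x, p) - np.log(sf(x, p)))
    if np.ndim(out) == 0:
        return float(out)
    return out


def quantile(prob: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    """Closed-form quantile xi(p) = (2/alpha) atanh(W_lam(p)^{1/a}) with
    W_lam(p) = -log(1 - p (1 - e^{-lam})) / lam."""
    prob = np.asarray(prob, dtype=float)
    if np.any((prob <= 0) | (prob >= 1)):
        raise ValueError("prob must lie in (0, 1)")
    alpha, lam, a = p.astuple()
    w = -np.log1p(prob * np.expm1(-lam)) / lam
    out = 2.0 / alpha * np.arctanh(w ** (1.0 / a))
    if np.ndim(out) == 0:
        return float(out)
    return out


def sample(n: int, p: PoiGHLParams, seed: int) -> np.ndarray:
    """Inverse-transform sampling driven by a counter-based Philox stream,
    so the same (seed, n) yields the same draws on every platform."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    u = rng.random(n)
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return np.asarray(quantile(u, p))


def bowley_skewness(p: PoiGHLParams) -> float:
    """Quartile-based skewness (xi(3/4) - 2 xi(1/2) + xi(1/4)) / IQR."""
    q1, q2, q3 = (quantile(q, p) for q in (0.25, 0.5, 0.75))
    return (q3 - 2.0 * q2 + q1) / (q3 - q1)


def moors_kurtosis(p: PoiGHLParams) -> float:
    """Octile-based kurtosis (xi(7/8)-xi(5/8)+xi(3/8)-xi(1/8)) / (xi(6/8)-xi(2/8))."""
    e = {k: quantile(k / 8.0, p) for k in range(1, 8)}
    return (e[7] - e[5] + e[3] - e[1]) / (e[6] - e[2])


def submodel(name: str, p: PoiGHLParams):
    """Restrict PoiGHL to one of its sub-/limit models.

    ``hlp`` fixes a = 1 (half logistic Poisson), ``ghl`` is the exact
    lam -> 0 limit, ``hl`` applies both restrictions.  The GHL restriction is
    returned as its own parameter object so no tiny-lam cancellation occurs.
    """
    if name == "hlp":
        return PoiGHLParams(p.alpha, p.lam, 1.0)
    if name == "ghl":
        return GHLParams(p.alpha, p.a)
    if name == "hl":
        return GHLParams(p.alpha, 1.0)
    raise ValueError(f"unknown sub-model {name!r}; expected 'hlp', 'ghl' or 'hl'")


def density_decreasing_condition(p: PoiGHLParams) -> bool:
    """Sufficient parameter region for a monotonically decreasing density:
    lam > 2 together with 2/lam < a < 1."""
    return p.lam > 2.0 and (2.0 / p.lam) < p.a < 1.0


# ---------------------------------------------------------------------------
# Log-PoiGHL (Y = sigma log X)

def _lpoighl_s(y: ArrayLike, q: LPoiGHLParams) -> np.ndarray:
    return np.exp((np.asarray(y, dtype=float) - q.mu) / q.sigma)


def lpoighl_cdf(y: ArrayLike, q: LPoiGHLParams) -> ArrayLike:
    s = _lpoighl_s(y, q)
    out = np.expm1(-q.lam * np.tanh(s / 2.0) ** q.a) / np.expm1(-q.lam)
    if np.ndim(out) == 0:
        return float(out)
    return out


def lpoighl_pdf(y: ArrayLike, q: LPoiGHLParams) -> ArrayLike:
    s = _lpoighl_s(y, q)
    t = np.tanh(s / 2.0)
    with np.errstate(invalid="ignore", over="ignore"):
        dens = (
            q.lam
            * np.exp(-q.lam * t**q.a)
            / (-np.expm1(-q.lam))
            * q.a
            * t ** (q.a - 1.0)
            * 0.5
            * (1.0 - t**2)
            * s
            / q.sigma
        )
    # s -> inf gives 0 * inf; the density vanishes in that tail
    dens = np.where(np.isnan(dens), 0.0, dens)
    if np.ndim(dens) == 0:
        return float(dens)
    return dens


# ---------------------------------------------------------------------------
# Truncated-exponential substitution backbone

def x_of_v(v: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    """Inverse of V = G(X): x(v) = (2/alpha) atanh(v^{1/a})."""
    v = np.asarray(v, dtype=float)
    return 2.0 / p.alpha * np.arctanh(v ** (1.0 / p.a))


def logpdf_of_v(v: ArrayLike, p: PoiGHLParams) -> ArrayLike:
    """log f(x(v)) evaluated directly in v, stable down to v -> 0.

    Uses f(x) = c(G(x)) G'(x) with c the truncated-exponential density and
    G'(x(v)) = (a alpha / 2) v^{(a-1)/a} (1 - v^{2/a}).
    """
    v = np.asarray(v, dtype=float)
    alpha, lam, a = p.astuple()
    with np.errstate(divide="ignore"):
        out = (
            np.log(lam)
            - np.log(-np.expm1(-lam))
            - lam * v
            + np.log(a * alpha / 2.0)
            + (a - 1.0) / a * np.log(v)
            + np.log1p(-(v ** (2.0 / a)))
        )
    if np.ndim(out) == 0:
        return float(out)
    return out


def expect(
    g: Callable[[np.ndarray], np.ndarray],
    p: PoiGHLParams,
    quad: QuadratureSpec = DEFAULT_QUAD,
    v_lower: float = 0.0,
    v_upper: float = 1.0,
) -> float:
    """Compute ``int g(x) f(x) dx`` over {x : G(x) in (v_lower, v_upper)} via
    the truncated-exponential substitution (the normative quadrature route)."""
    lam = p.lam
    norm = -np.expm1(-lam)

    def integrand(v: float) -> float:
        x = x_of_v(v, p)
        return float(g(np.asarray(x))) * lam * np.exp(-lam * v) / norm

    val, _ = integrate.quad(
        integrand,
        v_lower,
        v_upper,
        epsabs=quad.abs_tol,
        epsrel=quad.rel_tol,
        limit=quad.max_subdivisions,
    )
    return val
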