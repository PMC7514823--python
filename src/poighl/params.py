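"""Parameter containers and numerical-control specs.

The PoiGHL family arises by taking the minimum of a zero-truncated-Poisson
number of independent generalized half logistic (GHL) variates.  Its three
parameters are

* ``alpha`` -- scale-rate of the GHL baseline (inverse time units),
* ``lam``   -- rate of the zero-truncated Poisson mixing law (dimensionless),
* ``a``     -- GHL shape (dimensionless).

The ``lam -> 0`` limit is the GHL distribution and is represented by its own
restricted parameter object rather than a tiny ``lam`` (which would suffer
catastrophic cancellation in ``1 - exp(-lam)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _check_positive(name: str, value: float) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")


@dataclass(frozen=True)
class PoiGHLParams:
    """Parameters (alpha, lam, a) of the three-parameter PoiGHL distribution."""

    alpha: float
    lam: float
    a: float

    def __post_init__(self) -> None:
        _check_positive("alpha", self.alpha)
        _check_positive("lam", self.lam)
        _check_positive("a", self.a)

    def astuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.lam, self.a)


@dataclass(frozen=True)
class GHLParams:
    """Generalized half logistic parameters: the lam -> 0 limit of PoiGHL.

    cdf G(x) = ((1 - e^{-alpha x}) / (1 + e^{-alpha x}))^a = tanh(alpha x / 2)^a.
    ``a = 1`` is the plain half logistic (HL) distribution.
    """

    alpha: float
    a: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("alpha", self.alpha)
        _check_positive("a", self.a)


@dataclass(frozen=True)
class LPoiGHLParams:
    """Log-PoiGHL parameters: Y = sigma * log X with alpha = exp(-mu / sigma).

    ``mu`` is a location on the log-time axis, ``sigma`` a dispersion; ``lam``
    and ``a`` retain their PoiGHL meanings.
    """

    lam: float
    a: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        _check_positive("lam", self.lam)
        _check_positive("a", self.a)
        _check_positive("sigma", self.sigma)
        if not math.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")

    def to_poighl(self) -> PoiGHLParams:
        return PoiGHLParams(math.exp(-self.mu / self.sigma), self.lam, self.a)


@dataclass(frozen=True)
class QuadratureSpec:
    """Tolerances for the adaptive quadratures used throughout the package."""

    abs_tol: float = 1e-10
    rel_tol: float = 1e-10
    max_subdivisions: int = 200

    def __post_init__(self) -> None:
        for name, tol in (("abs_tol", self.abs_tol), ("rel_tol", self.rel_tol)):
            if not (0 < tol <= 1e-3):
                raise ValueError(f"{name} must lie in (0, 1e-3], got {tol!r}")
        if self.max_subdivisions < 1:
            raise ValueError("max_subdivisions must be positive")


@dataclass(frozen=True)
class SeriesSpec:
    """Truncation control for the double/triple series evaluators."""

    max_terms: int = 200
    tail_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_terms < 10:
            raise ValueError("max_terms must be at least 10")
        if not (0 < self.tail_tol < 1):
            raise ValueError("tail_tol must lie in (0, 1)")


DEFAULT_QUAD = QuadratureSpec()
DEFAULT_SERIES = SeriesSpec()
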