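"""Maximum-likelihood fitting of PoiGHL and its sub-models, with standard
errors from the observed information, likelihood-ratio tests, information
criteria and goodness-of-fit statistics.

Optimization runs in log-parameter space (unconstrained) with the analytic
score, quasi-Newton steps and a deterministic multi-start grid; the best
start by final log-likelihood wins.  The observed information is a
symmetrized central-difference Hessian of the log-likelihood at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .distribution import cdf as poighl_cdf
from .distribution import ghl_cdf
from .params import GHLParams, PoiGHLParams

__all__ = [
    "FitResult",
    "GofStats",
    "LRTestResult",
    "ExistenceDiagnostics",
    "loglik",
    "score",
    "fit_mle",
    "confint",
    "lr_test",
    "gof_stats",
    "mle_existence_diagnostics",
    "MODELS",
]

MODELS = ("poighl", "hlp", "ghl", "hl")

_PARAM_NAMES = {
    "poighl": ("alpha", "lam", "a"),
    "hlp": ("alpha", "lam"),
    "ghl": ("alpha", "a"),
    "hl": ("alpha",),
}

# nested pairs (null, alternative) with the difference in dimension
_NESTED = {
    ("hlp", "poighl"): 1,
    ("ghl", "poighl"): 1,
    ("hl", "poighl"): 2,
    ("hl", "ghl"): 1,
    ("hl", "hlp"): 1,
}


def _check_data(data) -> np.ndarray:
    x = np.asarray(data, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(
            f"data must be strictly positive; offending indices: {bad.tolist()}"
        )
    return x


def _theta_of(params) -> tuple[str, np.ndarray]:
    if isinstance(params, PoiGHLParams):
        return "poighl", np.array(params.astuple())
    if isinstance(params, GHLParams):
        if params.a == 1.0:
            return "hl", np.array([params.alpha])
        return "ghl", np.array([params.alpha, params.a])
    raise TypeError(f"unsupported parameter object {params!r}")


def _ll_terms(x: np.ndarray, alpha: float):
    """Shared building blocks: t, e^{-t}, log(1-e^{-t}), log(1+e^{-t}), T."""
    t = alpha * x
    et = np.exp(-t)
    log1m = np.log(-np.expm1(-t))
    log1p_ = np.log1p(et)
    T = np.tanh(t / 2.0)
    return t, et, log1m, log1p_, T


def _loglik_theta(model: str, theta: np.ndarray, x: np.ndarray) -> float:
    n = x.size
    if model in ("poighl", "hlp"):
        alpha, lam = theta[0], theta[1]
        a = theta[2] if model == "poighl" else 1.0
        _, _, log1m, log1p_, T = _ll_terms(x, alpha)
        return float(
            n * np.log(2.0 * a * alpha * lam)
            - n * np.log(-np.expm1(-lam))
            - alpha * np.sum(x)
            + (a - 1.0) * np.sum(log1m)
            - (a + 1.0) * np.sum(log1p_)
            - lam * np.sum(T**a)
        )
    alpha = theta[0]
    a = theta[1] if model == "ghl" else 1.0
    _, _, log1m, log1p_, _ = _ll_terms(x, alpha)
    return float(
        n * np.log(2.0 * a * alpha)
        - alpha * np.sum(x)
        + (a - 1.0) * np.sum(log1m)
        - (a + 1.0) * np.sum(log1p_)
    )


def _score_theta(model: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = x.size
    if model in ("poighl", "hlp"):
        alpha, lam = theta[0], theta[1]
        a = theta[2] if model == "poighl" else 1.0
        t, et, log1m, log1p_, T = _ll_terms(x, alpha)
        w1 = x * et / (-np.expm1(-t))          # x e^{-t} / (1 - e^{-t})
        w2 = x * et / (1.0 + et)
        dT_dalpha = 2.0 * x * et / (1.0 + et) ** 2
        d_alpha = (
            n / alpha
            - np.sum(x)
            + (a - 1.0) * np.sum(w1)
            + (a + 1.0) * np.sum(w2)
            - lam * a * np.sum(T ** (a - 1.0) * dT_dalpha)
        )
        d_lam = n / lam - n * np.exp(-lam) / (-np.expm1(-lam)) - np.sum(T**a)
        if model == "hlp":
            return np.array([d_alpha, d_lam])
        d_a = (
            n / a
            + np.sum(log1m)
            - np.sum(log1p_)
            - lam * np.sum(T**a * np.log(T))
        )
        return np.array([d_alpha, d_lam, d_a])
    alpha = theta[0]
    a = theta[1] if model == "ghl" else 1.0
    t, et, log1m, log1p_, _ = _ll_terms(x, alpha)
    w1 = x * et / (-np.expm1(-t))
    w2 = x * et / (1.0 + et)
    d_alpha = n / alpha - np.sum(x) + (a - 1.0) * np.sum(w1) + (a + 1.0) * np.sum(w2)
    if model == "hl":
        return np.array([d_alpha])
    d_a = n / a + np.sum(log1m) - np.sum(log1p_)
    return np.array([d_alpha, d_a])


def loglik(data, params: Union[PoiGHLParams, GHLParams]) -> float:
    """Log-likelihood of a positive sample under PoiGHL (or a GHL restriction)."""
    x = _check_data(data)
    model, theta = _theta_of(params)
    return _loglik_theta(model, theta, x)


def score(data, params: Union[PoiGHLParams, GHLParams]) -> np.ndarray:
    """Analytic score (gradient of the log-likelihood in the natural
    parameters, ordered as the parameter object's fields)."""
    x = _check_data(data)
    model, theta = _theta_of(params)
    return _score_theta(model, theta, x)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one sample."""

    model: str
    params: Union[PoiGHLParams, GHLParams]
    loglik: float
    n: int
    vcov: np.ndarray
    se: np.ndarray
    aic: float
    bic: float
    caic: float
    converged: bool
    n_starts: int
    best_start: tuple
    param_names: tuple = field(default=())
    vcov_reliable: bool = True

    @property
    def k(self) -> int:
        return len(self.param_names)

    def theta(self) -> np.ndarray:
        return np.array([getattr(self.params, name) for name in self.param_names])

    def cdf(self, x):
        if isinstance(self.params, PoiGHLParams):
            return poighl_cdf(x, self.params)
        return ghl_cdf(x, self.params.alpha, self.params.a)


def _params_from_theta(model: str, theta: np.ndarray):
    if model == "poighl":
        return PoiGHLParams(*theta)
    if model == "hlp":
        return PoiGHLParams(theta[0], theta[1], 1.0)
    if model == "ghl":
        return GHLParams(theta[0], theta[1])
    return GHLParams(theta[0], 1.0)


def _default_starts(model: str, x: np.ndarray) -> list[tuple]:
    a_scale = (1.0 / np.mean(x), 1.0 / np.median(x))
    lam0 = (0.5, 2.0, 8.0)
    a0 = (0.5, 1.0, 2.0)
    if model == "poighl":
        return [(al, l, a) for al in a_scale for l in lam0 for a in a0]
    if model == "hlp":
        return [(al, l) for al in a_scale for l in lam0]
    if model == "ghl":
        return [(al, a) for al in a_scale for a in a0]
    return [(al,) for al in a_scale]


_LOG_BOUNDS = (-20.0, 20.0)


def _observed_information(model: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Symmetrized central-difference Hessian of -loglik at theta."""
    k = theta.size
    H = np.empty((k, k))
    h = np.maximum(1e-4, 1e-4 * np.abs(theta))

    def f(t):
        with np.errstate(all="ignore"):
            return -_loglik_theta(model, t, x)

    for i in range(k):
        for j in range(i, k):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (
                4.0 * h[i] * h[j]
            )
    return 0.5 * (H + H.T)


def fit_mle(
    data,
    model: str = "poighl",
    starts: Optional[Sequence[tuple]] = None,
    seed: Optional[int] = None,
) -> FitResult:
    """Fit a model by multi-start maximum likelihood.

    Parameters
    ----------
    data : positive sample
    model : one of ``poighl``, ``hlp``, ``ghl``, ``hl``
    starts : optional iterable of natural-parameter start tuples; defaults to
        a deterministic grid built from the sample scale.
    seed : optional; adds four random log-jittered starts around the grid.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    x = _check_data(data)
    names = _PARAM_NAMES[model]
    k = len(names)
    if x.size < k + 2:
        raise ValueError(f"need at least {k + 2} observations to fit {model}")
    start_list = [tuple(s) for s in starts] if starts is not None else _default_starts(model, x)
    if seed is not None:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
        base = np.log(np.asarray(start_list[0], dtype=float))
        for _ in range(4):
            start_list.append(tuple(np.exp(base + rng.normal(0.0, 1.0, k))))

    def nll_lp(lp):
        with np.errstate(all="ignore"):
            val = -_loglik_theta(model, np.exp(lp), x)
        return val if np.isfinite(val) else 1e300

    def grad_lp(lp):
        theta = np.exp(lp)
        with np.errstate(all="ignore"):
            g = -_score_theta(model, theta, x) * theta  # chain rule d/dlog
        return np.where(np.isfinite(g), g, 0.0)

    best = None
    best_start = start_list[0]
    for s in start_list:
        lp0 = np.clip(np.log(np.asarray(s, dtype=float)), *_LOG_BOUNDS)
        try:
            res = optimize.minimize(
                nll_lp, lp0, jac=grad_lp, method="L-BFGS-B",
                bounds=[_LOG_BOUNDS] * k,
                options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
            )
        except FloatingPointError:  # pragma: no cover - defensive
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12 or (
            abs(res.fun - best.fun) <= 1e-12
            and np.linalg.norm(res.x) < np.linalg.norm(best.x)
        ):
            best, best_start = res, s
    if best is None:
        raise RuntimeError(f"all {len(start_list)} starts failed for model {model}")

    # simplex polish guards against quasi-Newton stalls on likelihood ridges
    polish = optimize.minimize(
        nll_lp, best.x, method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-12, "fatol": 1e-13},
    )
    if polish.fun < best.fun:
        best = polish

    theta = np.exp(np.clip(best.x, *_LOG_BOUNDS))
    ll = -float(best.fun)
    at_boundary = bool(np.any(np.abs(best.x) > _LOG_BOUNDS[1] - 1e-6))
    converged = bool(np.isfinite(ll)) and not at_boundary

    H = _observed_information(model, theta, x)
    reliable = True
    try:
        cond = np.linalg.cond(H)
        if not np.isfinite(cond) or cond > 1e10:
            reliable = False
        vcov = np.linalg.pinv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        vcov = np.full((k, k), np.nan)
        reliable = False
    diag = np.diag(vcov).copy()
    if np.any(diag < 0):
        reliable = False
    se = np.sqrt(np.where(diag > 0, diag, np.nan))

    n = x.size
    aic = 2.0 * k - 2.0 * ll
    bic = k * np.log(n) - 2.0 * ll
    caic = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    return FitResult(
        model=model,
        params=_params_from_theta(model, theta),
        loglik=ll,
        n=n,
        vcov=vcov,
        se=se,
        aic=aic,
        bic=bic,
        caic=caic,
        converged=converged,
        n_starts=len(start_list),
        best_start=tuple(best_start),
        param_names=names,
        vcov_reliable=reliable,
    )


def confint(fit: FitResult, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Asymptotic normal confidence intervals theta_hat +/- z * se."""
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if not fit.vcov_reliable:
        warnings.warn("covariance matrix flagged unreliable; intervals are too")
    z = stats.norm.ppf(0.5 + level / 2.0)
    theta = fit.theta()
    return {
        name: (theta[i] - z * fit.se[i], theta[i] + z * fit.se[i])
        for i, name in enumerate(fit.param_names)
    }


@dataclass(frozen=True)
class LRTestResult:
    stat_w: float
    df: int
    p_value: float
    null_fit: FitResult
    alt_fit: FitResult


def lr_test(data, null_model: str, alt_model: str = "poighl", **fit_kwargs) -> LRTestResult:
    """Likelihood-ratio test w = -2 (l_null - l_alt), chi-square reference.

    The GHL null sits on the lam -> 0 boundary of PoiGHL; the chi-square
    reference is the conventional one and slightly conservative there.
    """
    if (null_model, alt_model) not in _NESTED:
        raise ValueError(f"{null_model!r} is not nested in {alt_model!r}")
    f0 = fit_mle(data, null_model, **fit_kwargs)
    f1 = fit_mle(data, alt_model, **fit_kwargs)
    w = max(-2.0 * (f0.loglik - f1.loglik), -1e-8)
    df = _NESTED[(null_model, alt_model)]
    p = float(stats.chi2.sf(max(w, 0.0), df))
    return LRTestResult(stat_w=w, df=df, p_value=p, null_fit=f0, alt_fit=f1)


@dataclass(frozen=True)
class GofStats:
    ks: float
    ks_p: float
    ad: float
    cvm: float


def gof_stats(data, params: Union[PoiGHLParams, GHLParams]) -> GofStats:
    """Kolmogorov-Smirnov, Anderson-Darling and Cramer-von Mises statistics
    from the probability integral transform u_(i) = F(x_(i)).

    The KS p-value uses the asymptotic Kolmogorov distribution.
    """
    x = np.sort(_check_data(data))
    if isinstance(params, PoiGHLParams):
        u = np.asarray(poighl_cdf(x, params), dtype=float)
    else:
        u = np.asarray(ghl_cdf(x, params.alpha, params.a), dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        warnings.warn("PIT values at 0/1 clipped to [1e-12, 1 - 1e-12]")
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
    n = u.size
    i = np.arange(1, n + 1)
    ks = float(max(np.max(i / n - u), np.max(u - (i - 1) / n)))
    ks_p = float(stats.kstwobign.sf(np.sqrt(n) * ks))
    ad = float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))
    cvm = float(1.0 / (12.0 * n) + np.sum((u - (2 * i - 1) / (2.0 * n)) ** 2))
    return GofStats(ks=ks, ks_p=ks_p, ad=ad, cvm=cvm)


@dataclass(frozen=True)
class ExistenceDiagnostics:
    """Score-equation existence/uniqueness diagnostics at candidate values.

    ``shape_root_bracket`` brackets the shape score root when lam < 1;
    ``poisson_rate_condition`` is mean(G^a), with a root in lam guaranteed
    when it is below 1/2; the alpha score always has a root when a >= 1.
    """

    alpha_root_applicable: bool
    poisson_rate_condition: float
    poisson_rate_root_guaranteed: bool
    shape_bracket_applicable: bool
    shape_root_bracket: Optional[tuple[float, float]]


def mle_existence_diagnostics(data, p_candidate: PoiGHLParams) -> ExistenceDiagnostics:
    x = _check_data(data)
    alpha, lam, a = p_candidate.astuple()
    T = np.tanh(alpha * x / 2.0)
    cond = float(np.mean(T**a))
    s = float(np.sum(np.log((1.0 + np.exp(-alpha * x)) / (-np.expm1(-alpha * x)))))
    if lam < 1.0:
        bracket = (x.size / s, x.size / ((1.0 - lam) * s))
        applicable = True
    else:
        bracket = None
        applicable = False
    return ExistenceDiagnostics(
        alpha_root_applicable=a >= 1.0,
        poisson_rate_condition=cond,
        poisson_rate_root_guaranteed=cond < 0.5,
        shape_bracket_applicable=applicable,
        shape_root_bracket=bracket,
    )
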