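"""Parametric survival families, maximum-likelihood fitting, AIC selection,
and proportional-hazards adjustment.

Parameterizations (fixed here and used everywhere in the package):

* exponential   S(t) = exp(-rate * t)
* weibull       S(t) = exp(-(t/scale)^shape)
* loglogistic   S(t) = 1 / (1 + (t/scale)^shape)
* lognormal     S(t) = 1 - Phi((ln t - mu) / sigma)
* gompertz      S(t) = exp(-(rate/shape) * (exp(shape * t) - 1))

All scale/shape/rate parameters are strictly positive; lognormal ``mu`` is
unrestricted.  Comparator strategies are derived from a fitted reference
curve via proportional hazards: S_adj(t) = S_base(t)^HR.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .data import PseudoIPD

__all__ = [
    "FAMILIES", "PARAM_NAMES", "SurvivalFit", "AdjustedSurvival",
    "log_sf", "sf", "log_hazard", "sample_times", "true_median",
    "loglik", "fit_mle", "fit_all", "select_by_aic", "apply_hr", "survival_at",
]

FAMILIES = ("exponential", "weibull", "loglogistic", "lognormal", "gompertz")

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
    "gompertz": ("rate", "shape"),
}


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise ValueError(
            f"unknown family {family!r}; choose one of {', '.join(FAMILIES)}")


def _check_params(family: str, params: dict) -> tuple:
    _check_family(family)
    names = PARAM_NAMES[family]
    missing = set(names) - set(params)
    if missing:
        raise ValueError(f"{family} is missing parameter(s): {sorted(missing)}")
    vals = tuple(float(params[k]) for k in names)
    for name, v in zip(names, vals):
        if not np.isfinite(v):
            raise ValueError(f"{family} parameter {name}={v} is not finite")
        if name != "mu" and v <= 0:
            raise ValueError(f"{family} parameter {name}={v} must be > 0")
    return vals


def log_sf(family: str, params: dict, t):
    """log S(t); vectorized over t (t >= 0)."""
    vals = _check_params(family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if family == "exponential":
        (rate,) = vals
        return -rate * t
    if family == "weibull":
        scale, shape = vals
        return -((t / scale) ** shape)
    if family == "loglogistic":
        scale, shape = vals
        with np.errstate(divide="ignore"):
            z = shape * (np.log(t) - math.log(scale))
        return -np.logaddexp(0.0, z)
    if family == "lognormal":
        mu, sigma = vals
        with np.errstate(divide="ignore"):
            z = (np.log(t) - mu) / sigma
        return special.log_ndtr(-z)
    # gompertz
    rate, shape = vals
    return -(rate / shape) * np.expm1(shape * t)


def sf(family: str, params: dict, t):
    """Survival function S(t)."""
    return np.exp(log_sf(family, params, t))


def log_hazard(family: str, params: dict, t):
    """log h(t) = log f(t) - log S(t); requires t > 0."""
    vals = _check_params(family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard requires strictly positive times")
    if family == "exponential":
        (rate,) = vals
        return np.full_like(t, math.log(rate))
    if family == "weibull":
        scale, shape = vals
        return (math.log(shape) - math.log(scale)
                + (shape - 1.0) * (np.log(t) - math.log(scale)))
    if family == "loglogistic":
        scale, shape = vals
        z = shape * (np.log(t) - math.log(scale))
        # h = (shape/scale)(t/scale)^{shape-1} / (1 + (t/scale)^shape)
        return (math.log(shape) - math.log(scale)
                + (shape - 1.0) * (np.log(t) - math.log(scale))
                - np.logaddexp(0.0, z))
    if family == "lognormal":
        mu, sigma = vals
        z = (np.log(t) - mu) / sigma
        log_pdf = -0.5 * z * z - 0.5 * math.log(2 * math.pi) \
            - math.log(sigma) - np.log(t)
        return log_pdf - special.log_ndtr(-z)
    rate, shape = vals
    return math.log(rate) + shape * t


def sample_times(family: str, params: dict, n: int, rng: np.random.Generator):
    """Draw n event times by inverting S(t) = U, U ~ Uniform(0,1)."""
    vals = _check_params(family, params)
    u = rng.uniform(size=int(n))
    if family == "exponential":
        (rate,) = vals
        return -np.log(u) / rate
    if family == "weibull":
        scale, shape = vals
        return scale * (-np.log(u)) ** (1.0 / shape)
    if family == "loglogistic":
        scale, shape = vals
        return scale * ((1.0 - u) / u) ** (1.0 / shape)
    if family == "lognormal":
        mu, sigma = vals
        return np.exp(mu + sigma * special.ndtri(1.0 - u))
    rate, shape = vals
    return np.log1p(-(shape / rate) * np.log(u)) / shape


def true_median(family: str, params: dict) -> float:
    """Closed-form median survival time of the family."""
    vals = _check_params(family, params)
    if family == "exponential":
        return math.log(2) / vals[0]
    if family == "weibull":
        scale, shape = vals
        return scale * math.log(2) ** (1.0 / shape)
    if family == "loglogistic":
        return vals[0]
    if family == "lognormal":
        return math.exp(vals[0])
    rate, shape = vals
    return math.log1p(shape / rate * math.log(2)) / shape


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalFit:
    """A fitted parametric survival model."""

    family: str
    params: dict
    loglik: float
    n_params: int
    aic: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.aic is None:
            object.__setattr__(self, "aic",
                               2.0 * self.n_params - 2.0 * self.loglik)

    def sf(self, t):
        return sf(self.family, self.params, t)

    def log_sf(self, t):
        return log_sf(self.family, self.params, t)

    def __call__(self, t):
        return self.sf(t)


@dataclass(frozen=True)
class AdjustedSurvival:
    """Proportional-hazards adjustment of a fitted curve:
    S_adj(t) = S_base(t)^hazard_ratio."""

    base: SurvivalFit
    hazard_ratio: float
    endpoint: str = ""
    strategy: str = ""

    def __post_init__(self):
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")

    def sf(self, t):
        return np.exp(self.hazard_ratio * self.base.log_sf(t))

    def log_sf(self, t):
        return self.hazard_ratio * self.base.log_sf(t)

    def __call__(self, t):
        return self.sf(t)


def loglik(family: str, params: dict, ipd: PseudoIPD) -> float:
    """Censored log-likelihood: sum_events log h(t_i) + sum_all log S(t_i)."""
    t = ipd.times
    if np.any(t <= 0):
        raise ValueError("log-likelihood requires strictly positive times")
    ll = float(np.sum(log_sf(family, params, t)))
    ev = ipd.events.astype(bool)
    if ev.any():
        ll += float(np.sum(log_hazard(family, params, t[ev])))
    return ll


def _starts(family: str, ipd: PseudoIPD) -> list[np.ndarray]:
    """Moment-based starting values on the optimizer (log) scale."""
    t = ipd.times
    d = max(ipd.n_events, 1)
    rate0 = d / float(t.sum())
    ev_t = t[ipd.events.astype(bool)]
    log_t = np.log(ev_t if ev_t.size else t)
    med = float(np.exp(np.median(log_t)))
    sd = float(np.std(log_t))
    sd = max(sd, 0.2)
    if family == "exponential":
        base = np.array([math.log(rate0)])
        return [base, base + 0.7, base - 0.7]
    if family == "weibull":
        base = np.array([math.log(1.0 / rate0), 0.0])
        return [base, base + [0.0, 0.5], base + [0.3, -0.5]]
    if family == "loglogistic":
        base = np.array([math.log(med), math.log(1.5)])
        return [base, base + [0.0, 0.6], base + [0.4, -0.6]]
    if family == "lognormal":
        base = np.array([math.log(med), math.log(sd)])
        return [base, base + [0.0, 0.5], base + [0.5, -0.3]]
    base = np.array([math.log(rate0), math.log(0.05)])
    return [base, base + [0.0, 2.0], base + [0.5, -2.0]]


def _from_theta(family: str, theta: np.ndarray) -> dict:
    names = PARAM_NAMES[family]
    vals = [theta[i] if n == "mu" else math.exp(theta[i])
            for i, n in enumerate(names)]
    return dict(zip(names, vals))


def fit_mle(family: str, ipd: PseudoIPD) -> SurvivalFit:
    """Maximum-likelihood fit of one family.

    Optimizes on log-transformed parameters (positivity enforced) with three
    moment-based starts plus a polishing restart at the best point.
    """
    _check_family(family)
    if ipd.n_events < 1:
        raise ValueError(
            f"cannot fit {family}: no events in the data (all censored)")

    def neg_ll(theta):
        try:
            params = _from_theta(family, theta)
            val = loglik(family, params, ipd)
        except (ValueError, OverflowError, FloatingPointError):
            return np.inf
        if not np.isfinite(val):
            return np.inf
        return -val

    best = None
    diagnostics = []
    with np.errstate(over="ignore", invalid="ignore"):
        for x0 in _starts(family, ipd):
            res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-10,
                                             "maxiter": 4000})
            diagnostics.append((x0, res.fun, res.success))
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is not None:
            # polishing restart: Nelder-Mead from the incumbent optimum
            res = optimize.minimize(neg_ll, best.x, method="Nelder-Mead",
                                    options={"xatol": 1e-12, "fatol": 1e-12,
                                             "maxiter": 4000})
            if np.isfinite(res.fun) and res.fun <= best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"MLE for {family} failed to converge; starts/objectives tried: "
            f"{[(list(np.round(x, 3)), f) for x, f, _ in diagnostics]}")
    params = _from_theta(family, best.x)
    ll = -float(best.fun)
    return SurvivalFit(family=family, params=params, loglik=ll,
                       n_params=len(PARAM_NAMES[family]))


def fit_all(ipd: PseudoIPD, families=FAMILIES) -> list[SurvivalFit]:
    """Fit every requested family to the same data."""
    return [fit_mle(f, ipd) for f in families]


def select_by_aic(fits: list[SurvivalFit]) -> SurvivalFit:
    """Minimum-AIC fit.  Exact ties: fewer parameters win; residual ties go
    to the fixed family order exponential < weibull < loglogistic <
    lognormal < gompertz."""
    if not fits:
        raise ValueError("select_by_aic needs at least one fit")
    order = {f: i for i, f in enumerate(FAMILIES)}
    return min(fits, key=lambda f: (f.aic, f.n_params, order[f.family]))


def apply_hr(base: SurvivalFit, hr: float, endpoint: str = "",
             strategy: str = "") -> AdjustedSurvival:
    """Proportional-hazards adjustment S_adj = S_base^hr (hr > 0)."""
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    return AdjustedSurvival(base=base, hazard_ratio=float(hr),
                            endpoint=endpoint, strategy=strategy)


def survival_at(curve, t):
    """Evaluate a SurvivalFit / AdjustedSurvival / callable at time(s) t >= 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("times must be nonnegative")
    out = curve.sf(t_arr) if hasattr(curve, "sf") else curve(t_arr)
    return float(out) if np.ndim(out) == 0 else np.asarray(out)


def fits_to_frame(fits: list[SurvivalFit], selected: SurvivalFit | None = None):
    """Fit summary table: family,param,estimate,loglik,aic,selected."""
    import pandas as pd

    rows = []
    for f in fits:
        for name, val in f.params.items():
            rows.append({"family": f.family, "param": name, "estimate": val,
                         "loglik": f.loglik, "aic": f.aic,
                         "selected": selected is not None
                         and f.family == selected.family})
    return pd.DataFrame(rows)
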