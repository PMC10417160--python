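"""Parametric survival families and censored maximum-likelihood fitting.

Six families are supported (exponential, Weibull, gamma, log-normal,
log-logistic, Gompertz), parameterized the way the survival-analysis
literature writes them:

==============  =================  =============================================
family          parameters         survival function S(t)
==============  =================  =============================================
exponential     rate               exp(-rate * t)
weibull         shape, scale       exp(-(t/scale)^shape)
gamma           shape, rate        1 - GammaCDF(t; shape, rate)
lognormal       meanlog, sdlog     1 - Phi((ln t - meanlog) / sdlog)
loglogistic     shape, scale       1 / (1 + (t/scale)^shape)
gompertz        shape, rate        exp(-(rate/shape) * (exp(shape*t) - 1))
==============  =================  =============================================

Gompertz hazard is h(t) = rate * exp(shape * t); the shape is restricted
to be positive so that S(t) -> 0 (no cure fraction).  Time is measured in
months throughout the package.

All distributional evaluations are delegated to ``scipy.stats``; this
module only fixes the parameterization and the censored likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "SurvivalDistribution",
    "IPDRecord",
    "FitResult",
    "survival_at",
    "hazard_at",
    "median_survival",
    "fit_mle",
    "rank_fits",
    "cycle_transition_prob",
]

#: canonical family order (used for deterministic tie-breaking in rank_fits)
FAMILIES = ("exponential", "weibull", "gamma", "lognormal", "loglogistic", "gompertz")

PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "rate"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
}

#: parameters that must be strictly positive (all of them, for these families)
_POSITIVE = {name for names in PARAM_NAMES.values() for name in names}

#: survival floor applied before divisions (conditional survival in deep tails)
S_FLOOR = 1e-12


@dataclass(frozen=True)
class SurvivalDistribution:
    """A parametric survival curve, e.g. ``SurvivalDistribution("lognormal", {"meanlog": 2.763, "sdlog": 0.971})``."""

    family: str
    params: dict

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        names = PARAM_NAMES[self.family]
        got = tuple(self.params)
        if set(got) != set(names):
            raise ValueError(
                f"{self.family} needs parameters {names}, got {got}"
            )
        for name, value in self.params.items():
            if name in _POSITIVE and not value > 0:
                raise ValueError(
                    f"{self.family} parameter {name!r} must be > 0, got {value}"
                )
        # normalize ordering to the canonical one
        object.__setattr__(self, "params", {k: float(self.params[k]) for k in names})

    @property
    def param_values(self) -> tuple[float, ...]:
        return tuple(self.params.values())

    def frozen(self):
        """The equivalent frozen ``scipy.stats`` distribution."""
        p = self.params
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["rate"])
        if self.family == "weibull":
            return stats.weibull_min(c=p["shape"], scale=p["scale"])
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=1.0 / p["rate"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sdlog"], scale=math.exp(p["meanlog"]))
        if self.family == "loglogistic":
            return stats.fisk(c=p["shape"], scale=p["scale"])
        # gompertz: scipy's c = rate/shape, scale = 1/shape
        return stats.gompertz(c=p["rate"] / p["shape"], scale=1.0 / p["shape"])

    # convenience evaluators
    def survival(self, t):
        return survival_at(self, t)

    def hazard(self, t):
        return hazard_at(self, t)

    def median(self) -> float:
        return median_survival(self)


@dataclass(frozen=True)
class IPDRecord:
    """One (possibly censored) time-to-event observation, in months."""

    time: float
    event: bool

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")


@dataclass
class FitResult:
    distribution: SurvivalDistribution
    loglik: float
    aic: float
    bic: float
    n: int
    converged: bool
    stderr: dict = field(default_factory=dict)


def survival_at(dist: SurvivalDistribution, t):
    """S(t); vectorized over ``t``.  Times must be >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = dist.frozen().sf(t)
    return out if out.ndim else float(out)


def hazard_at(dist: SurvivalDistribution, t):
    """Instantaneous hazard f(t)/S(t), vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    fz = dist.frozen()
    out = fz.pdf(t) / np.maximum(fz.sf(t), S_FLOOR)
    return out if out.ndim else float(out)


def median_survival(dist: SurvivalDistribution) -> float:
    """Time t with S(t) = 0.5 (closed forms via the scipy quantile function)."""
    return float(dist.frozen().isf(0.5))


def cycle_transition_prob(dist: SurvivalDistribution, t: float, u: float) -> float:
    """Probability of leaving the curve's event-free set during the cycle ending at t.

    tp(t) = 1 - S(t) / S(t - u), the discrete-time hazard of a cohort that
    reached t - u.  For the first cycle (t == u) this is 1 - S(u).  The
    denominator is floored at ``S_FLOOR``; in a fully depleted tail the
    transition is treated as absorbing (returns 1).
    """
    if u <= 0:
        raise ValueError("cycle length u must be positive")
    if t < u:
        raise ValueError("t must be >= u (cycle ends at t, starts at t - u)")
    s_prev = survival_at(dist, t - u)
    if s_prev <= S_FLOOR:
        return 1.0
    tp = 1.0 - survival_at(dist, t) / s_prev
    return float(min(max(tp, 0.0), 1.0))


# ---------------------------------------------------------------------------
# maximum likelihood fitting of right-censored data
# ---------------------------------------------------------------------------


def _as_arrays(data: Sequence[IPDRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in data], dtype=float)
    events = np.array([r.event for r in data], dtype=bool)
    return times, events


def _neg_loglik(log_params: np.ndarray, family: str, times, events) -> float:
    params = dict(zip(PARAM_NAMES[family], np.exp(log_params)))
    try:
        fz = SurvivalDistribution(family, params).frozen()
    except (ValueError, OverflowError):
        return 1e300
    with np.errstate(all="ignore"):
        ll = np.sum(fz.logpdf(times[events])) + np.sum(fz.logsf(times[~events]))
    return 1e300 if not np.isfinite(ll) else -float(ll)


def _initial_params(family: str, times, events) -> dict:
    """Deterministic moment/quantile-based starting values (no random restarts)."""
    ev = times[events]
    total_time = float(np.sum(times))
    rate0 = max(len(ev), 1) / max(total_time, 1e-12)
    if family == "exponential":
        return {"rate": rate0}
    # use event times (falling back on all times) for shape/scale moments
    sample = ev if len(ev) >= 5 else times
    sample = sample[sample > 0]
    if len(sample) == 0:
        sample = np.array([1.0])
    m, s = float(np.mean(sample)), float(np.std(sample) or np.mean(sample) / 2)
    logm, logs = float(np.mean(np.log(sample))), float(np.std(np.log(sample)) or 0.5)
    if family == "weibull":
        return {"shape": 1.2, "scale": m}
    if family == "gamma":
        shape0 = max((m / s) ** 2, 0.1)
        return {"shape": shape0, "rate": shape0 / m}
    if family == "lognormal":
        return {"meanlog": logm, "sdlog": logs}
    if family == "loglogistic":
        return {"shape": 1.2, "scale": math.exp(logm)}
    return {"shape": 0.05, "rate": rate0}  # gompertz


def fit_mle(data: Sequence[IPDRecord], family: str) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    The optimizer is L-BFGS-B on log-transformed parameters with fixed,
    data-derived starting values, so the result is deterministic.  Standard
    errors come from the numerical Hessian of the log-parameter likelihood
    mapped back by the delta method.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(data) < 10:
        raise ValueError(f"need at least 10 records to fit, got {len(data)}")
    times, events = _as_arrays(data)
    if not events.any():
        raise ValueError("all records censored: likelihood is degenerate")

    names = PARAM_NAMES[family]
    init = _initial_params(family, times, events)
    # positivity-constrained parameters are optimized on the log scale;
    # meanlog (location of log-time, may be negative) stays on its natural scale
    if family == "lognormal":
        res = optimize.minimize(
            lambda x: _neg_loglik_lognormal(x, times, events),
            x0=np.array([init["meanlog"], math.log(init["sdlog"])]),
            method="L-BFGS-B",
        )
        meanlog, sdlog = res.x[0], math.exp(res.x[1])
        dist = SurvivalDistribution("lognormal", {"meanlog": meanlog, "sdlog": sdlog})
        jac = np.array([1.0, sdlog])
        hess_fn = lambda x: _neg_loglik_lognormal(x, times, events)  # noqa: E731
    else:
        x0 = np.log([init[n] for n in names])
        res = optimize.minimize(
            _neg_loglik, x0=x0, args=(family, times, events), method="L-BFGS-B"
        )
        values = np.exp(res.x)
        dist = SurvivalDistribution(family, dict(zip(names, values)))
        jac = values  # d(param)/d(log param)
        hess_fn = lambda x: _neg_loglik(x, family, times, events)  # noqa: E731

    stderr = {}
    try:
        hess = approx_hess(res.x, hess_fn)
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)) * np.abs(jac)
        stderr = dict(zip(names, se.tolist()))
    except np.linalg.LinAlgError:
        pass

    loglik = -float(res.fun)
    k = len(names)
    n = len(data)
    return FitResult(
        distribution=dist,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        bic=k * math.log(n) - 2 * loglik,
        n=n,
        converged=bool(res.success),
        stderr=stderr,
    )


def _neg_loglik_lognormal(x: np.ndarray, times, events) -> float:
    """Log-normal likelihood with meanlog on the natural scale (can be negative)."""
    meanlog, sdlog = x[0], math.exp(x[1])
    fz = stats.lognorm(s=sdlog, scale=math.exp(meanlog))
    with np.errstate(all="ignore"):
        ll = np.sum(fz.logpdf(times[events])) + np.sum(fz.logsf(times[~events]))
    return 1e300 if not np.isfinite(ll) else -float(ll)


def rank_fits(fits: Iterable[FitResult]) -> list[FitResult]:
    """Sort fits ascending by AIC, ties by BIC, then by canonical family order."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are not on the same data (n values {sorted(ns)})")
    return sorted(
        fits, key=lambda f: (f.aic, f.bic, FAMILIES.index(f.distribution.family))
    )


def selection_table(fits: Iterable[FitResult]) -> pd.DataFrame:
    """Model-selection table (family, loglik, AIC, BIC), best fit first."""
    ranked = rank_fits(fits)
    return pd.DataFrame(
        {
            "family": [f.distribution.family for f in ranked],
            "params": [str(f.distribution.params) for f in ranked],
            "loglik": [f.loglik for f in ranked],
            "aic": [f.aic for f in ranked],
            "bic": [f.bic for f in ranked],
            "converged": [f.converged for f in ranked],
        }
    )
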