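"""Synthetic time-to-event data, digitized-curve emulation and random configs.

The published analysis starts from digitized trial KM curves; no
patient-level data are public.  Everything the test-suite and the
worked examples need is therefore generated here: censored samples from
any of the six parametric families, step-function KM curves, noisy
"digitized" point sets (emulating graph-digitizer extraction error),
and randomized-but-valid two-arm model configurations for property
tests.  Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelBundle, load_default_config
from .distributions import IPDRecord, SurvivalDistribution
from .markov import ModelConfig
from .reconstruct import CurvePoint, clean_curve

__all__ = ["SimulationSpec", "simulate_ipd", "digitize_km", "random_model_config"]


@dataclass(frozen=True)
class SimulationSpec:
    """A censored sampling plan: distribution, sample size and censoring.

    ``censoring`` is one of ``none``, ``administrative`` (cutoff at
    ``t_max``) or ``random_exponential`` (independent exponential
    censoring with ``censor_rate``).
    """

    distribution: SurvivalDistribution
    n: int
    censoring: str = "none"
    t_max: float | None = None
    censor_rate: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.censoring not in ("none", "administrative", "random_exponential"):
            raise ValueError(f"unknown censoring scheme {self.censoring!r}")
        if self.censoring == "administrative" and not (self.t_max and self.t_max > 0):
            raise ValueError("administrative censoring needs t_max > 0")
        if self.censoring == "random_exponential" and not (
            self.censor_rate and self.censor_rate > 0
        ):
            raise ValueError("random_exponential censoring needs censor_rate > 0")


def simulate_ipd(spec: SimulationSpec) -> list[IPDRecord]:
    """Draw event times by inverse-CDF sampling and apply the censoring plan."""
    rng = np.random.default_rng(spec.seed)
    t = spec.distribution.frozen().ppf(rng.uniform(size=spec.n))
    if spec.censoring == "none":
        return [IPDRecord(float(x), True) for x in t]
    if spec.censoring == "administrative":
        cutoff = np.full(spec.n, spec.t_max)
    else:
        cutoff = rng.exponential(1.0 / spec.censor_rate, size=spec.n)
    observed = np.minimum(t, cutoff)
    return [
        IPDRecord(float(x), bool(e)) for x, e in zip(observed, t <= cutoff)
    ]


def digitize_km(
    curve: list[CurvePoint],
    n_points: int,
    jitter_sd: float = 0.0,
    seed: int = 0,
    placement: str = "event_weighted",
) -> list[CurvePoint]:
    """Emulate manual digitization of a KM step function.

    Samples ``n_points`` time positions — by default weighted towards
    where the curve drops, the way a human digitizer places points —
    reads the step function there, adds truncated Gaussian jitter of
    standard deviation ``jitter_sd`` to the survival values, and repairs
    the result with :func:`hcc_cea.reconstruct.clean_curve`.
    """
    if n_points < 2:
        raise ValueError("need at least 2 digitization points")
    if placement not in ("event_weighted", "uniform"):
        raise ValueError(f"unknown placement {placement!r}")
    rng = np.random.default_rng(seed)
    t = np.array([p.time for p in curve])
    s = np.array([p.survival for p in curve])
    t_max = t[-1]
    if placement == "uniform" or len(t) < 3:
        times = np.linspace(0.0, t_max, n_points)
    else:
        # stratify on the curve's drop mass: one point wherever the
        # cumulative survival drop crosses the next 1/n quantile, so point
        # spacing on the survival axis is ~ total_drop / n_points
        drops = np.maximum(-np.diff(s), 0.0)
        cum = np.cumsum(drops)
        levels = (np.arange(n_points - 2) + 0.5) * cum[-1] / (n_points - 2)
        seg = np.searchsorted(cum, levels)
        inner = t[np.clip(seg + 1, 1, len(t) - 1)]
        times = np.unique(np.concatenate([[0.0], inner, [t_max]]))
    # read the step function (right-continuous) at the sampled times
    idx = np.searchsorted(t, times, side="right") - 1
    values = s[np.clip(idx, 0, len(s) - 1)]
    if jitter_sd > 0:
        values = np.clip(values + rng.normal(0.0, jitter_sd, size=len(values)), 0, 1)
    return clean_curve([CurvePoint(float(a), float(b)) for a, b in zip(times, values)])


def random_model_config(seed: int = 0) -> ModelBundle:
    """A randomized, always-valid two-arm configuration for property tests.

    Starts from the packaged configuration and redraws survival
    parameters, costs and utilities within plausible ranges, keeping
    every validation invariant satisfied.
    """
    rng = np.random.default_rng(seed)
    bundle = load_default_config()
    raw = bundle.raw

    def rand_dist():
        family = rng.choice(["exponential", "weibull", "gamma", "lognormal",
                             "loglogistic", "gompertz"])
        if family == "exponential":
            return {"family": "exponential", "rate": float(rng.uniform(0.02, 0.3))}
        if family == "weibull":
            return {"family": "weibull", "shape": float(rng.uniform(0.7, 2.5)),
                    "scale": float(rng.uniform(3, 30))}
        if family == "gamma":
            return {"family": "gamma", "shape": float(rng.uniform(0.7, 3)),
                    "rate": float(rng.uniform(0.05, 0.5))}
        if family == "lognormal":
            return {"family": "lognormal", "meanlog": float(rng.uniform(0.5, 3)),
                    "sdlog": float(rng.uniform(0.4, 1.3))}
        if family == "loglogistic":
            return {"family": "loglogistic", "shape": float(rng.uniform(1.1, 3)),
                    "scale": float(rng.uniform(3, 20))}
        return {"family": "gompertz", "shape": float(rng.uniform(0.02, 0.2)),
                "rate": float(rng.uniform(0.02, 0.2))}

    for arm in ("sintilimab_ibi305", "sorafenib"):
        os_spec = rand_dist()
        raw["survival"][arm]["os"] = os_spec
        raw["survival"][arm]["pfs"] = rand_dist()

    for entry in raw["costs"].values():
        v = float(rng.uniform(20, 3000))
        entry.update(value=v, low=0.8 * v, high=1.2 * v)
    for entry in raw["utilities"].values():
        v = float(rng.uniform(0.3, 0.95))
        entry.update(value=v, low=max(0.0, 0.8 * v), high=min(1.0, 1.2 * v))
    for arm_events in raw["adverse_events"]["incidence"].values():
        for entry in arm_events.values():
            v = float(rng.uniform(0.0, 0.3))
            entry.update(value=v, low=0.8 * v, high=min(1.0, 1.2 * v) if v else 0.0)
    for name, prop in raw["subsequent_treatment"]["proportion"].items():
        raw["subsequent_treatment"]["proportion"][name] = float(rng.uniform(0, 1))

    # revalidate through the public loader to guarantee the invariants
    import io, yaml  # noqa: PLC0415

    from .config import load_config

    return load_config(io.StringIO(yaml.safe_dump(raw)))
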