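"""One-way, threshold and probabilistic sensitivity analyses.

Every uncertain input is described by a :class:`ParamSpec`: a name, one
or more binding paths into the raw configuration tree, a base value with
a low/high span, and the distribution family used in the probabilistic
analysis (gamma for costs, beta for probabilities and utilities, on
moment-matched parameters with the low-high span read as a 95%
interval).  Survival-curve parameters carry no published uncertainty
range and are excluded throughout, i.e. held fixed at their fitted
values.

Multi-field parameters (the intervention's regimen acquisition cost is
the sum of two drug prices) are perturbed by scaling every bound field
by ``value / base``, which reduces to plain assignment for single-field
parameters.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ModelBundle, build_strategies
from .markov import evaluate_strategy, icer

__all__ = [
    "ParamSpec",
    "TornadoEntry",
    "tornado_params",
    "psa_params",
    "one_way",
    "threshold_price_reduction",
    "sample_param",
    "run_psa",
    "ceac",
    "ce_plane",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamSpec:
    name: str
    bindings: tuple[str, ...]
    base: float
    low: float
    high: float
    psa_family: str = "fixed"  # beta | gamma | fixed
    #: original value of each bound field (for proportional scaling)
    field_bases: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: requires low <= base <= high")
        if self.psa_family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"{self.name}: unknown psa_family {self.psa_family!r}")

    def apply(self, raw: dict, value: float) -> None:
        scale = value / self.base if self.base != 0 else 0.0
        for path, base_v in zip(self.bindings, self.field_bases):
            _set_path(raw, path, base_v * scale)


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _get_path(raw: dict, path: str):
    node = raw
    for part in path.split("."):
        try:
            node = node[part]
        except (KeyError, TypeError):
            raise KeyError(f"binding path {path!r} does not resolve (at {part!r})")
    return node

def _set_path(raw: dict, path: str, value: float) -> None:
    parts = path.split(".")
    node = _get_path(raw, ".".join(parts[:-1])) if len(parts) > 1 else raw
    if parts[-1] not in node:
        raise KeyError(f"binding path {path!r} does not resolve (at {parts[-1]!r})")
    node[parts[-1]] = float(value)


def _spec(raw: dict, name: str, paths: list[str], family: str,
          rel: float = 0.2) -> ParamSpec:
    """A ParamSpec whose base/low/high come from the bound config entries.

    Single-path parameters inherit the entry's printed low/high span;
    multi-path ones sum the entries and use the summed spans.
    """
    entries = [_get_path(raw, p.rsplit(".", 1)[0]) for p in paths]
    base = sum(e["value"] for e in entries)
    low = sum(e.get("low", e["value"] * (1 - rel)) for e in entries)
    high = sum(e.get("high", e["value"] * (1 + rel)) for e in entries)
    if base < 0:
        low, high = min(low, high), max(low, high)
    return ParamSpec(
        name=name,
        bindings=tuple(paths),
        base=base,
        low=low,
        high=high,
        psa_family=family,
        field_bases=tuple(e["value"] for e in entries),
    )


def _drug_key(raw: dict, drug: str, scenario: str) -> str:
    if scenario == "medicare" and f"{drug}_medicare" in raw["costs"]:
        return f"{drug}_medicare"
    return drug


def _shared_params(bundle: ModelBundle, scenario: str) -> list[ParamSpec]:
    raw = bundle.raw
    so_key = _drug_key(raw, "sorafenib", scenario)
    params = [
        _spec(raw, "sorafenib drug cost", [f"costs.{so_key}.value"], "gamma"),
        _spec(raw, "regorafenib drug cost", ["costs.regorafenib.value"], "gamma"),
        _spec(raw, "follow-up cost", ["costs.followup.value"], "gamma"),
        _spec(raw, "laboratory cost", ["costs.laboratory.value"], "gamma"),
        _spec(raw, "administration cost", ["costs.administration.value"], "gamma"),
        _spec(raw, "utility of SD", ["utilities.sd.value"], "beta"),
        _spec(raw, "utility of PD", ["utilities.pd.value"], "beta"),
    ]
    ae = raw["adverse_events"]
    for arm, events in ae["incidence"].items():
        for ev in events:
            params.append(
                _spec(raw, f"incidence of {ev} ({arm})",
                      [f"adverse_events.incidence.{arm}.{ev}.value"], "beta")
            )
    for ev in ae["costs"]:
        params.append(
            _spec(raw, f"cost of {ev}", [f"adverse_events.costs.{ev}.value"], "gamma")
        )
    for ev in ae["disutilities"]:
        params.append(
            _spec(raw, f"disutility of {ev}",
                  [f"adverse_events.disutilities.{ev}.value"], "beta")
        )
    return params


def tornado_params(bundle: ModelBundle, scenario: str = "medicare") -> list[ParamSpec]:
    """Default one-way parameter set; the regimen acquisition cost of the
    intervention (sintilimab + IBI305) is varied as a single parameter."""
    raw = bundle.raw
    si_key = _drug_key(raw, "sintilimab", scenario)
    regimen = _spec(
        raw,
        "sintilimab + IBI305 drug cost",
        [f"costs.{si_key}.value", "costs.ibi305.value"],
        "gamma",
    )
    return [regimen] + _shared_params(bundle, scenario)


def psa_params(bundle: ModelBundle, scenario: str = "medicare") -> list[ParamSpec]:
    """Default probabilistic parameter set; regimen components sampled
    separately (each has its own printed uncertainty span)."""
    raw = bundle.raw
    si_key = _drug_key(raw, "sintilimab", scenario)
    return [
        _spec(raw, "sintilimab drug cost", [f"costs.{si_key}.value"], "gamma"),
        _spec(raw, "IBI305 drug cost", ["costs.ibi305.value"], "gamma"),
    ] + _shared_params(bundle, scenario)


def _evaluate_icer(bundle: ModelBundle, scenario: str) -> float:
    sb, so = build_strategies(bundle, scenario)
    res = icer(
        evaluate_strategy(sb, bundle.config), evaluate_strategy(so, bundle.config)
    )
    return float("nan") if res.icer is None else res.icer


def one_way(
    bundle: ModelBundle,
    params: list[ParamSpec] | None = None,
    scenario: str = "medicare",
) -> list[TornadoEntry]:
    """Vary each parameter to its low and high bound, all others at base;
    entries come back sorted by ICER spread, widest first."""
    if params is None:
        params = tornado_params(bundle, scenario)
    entries = []
    for p in params:
        work = bundle.copy()
        p.apply(work.raw, p.low)
        at_low = _evaluate_icer(work, scenario)
        p.apply(work.raw, p.high)
        at_high = _evaluate_icer(work, scenario)
        entries.append(TornadoEntry(p.name, at_low, at_high))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def threshold_price_reduction(
    bundle: ModelBundle,
    wtp: float | None = None,
    scenario: str = "medicare",
    tol: float = 1.0,
) -> float:
    """Fractional cut to the intervention's drug-acquisition costs at which
    the ICER meets the willingness-to-pay threshold.

    Bisection on a multiplier m in [0, 1] applied to the sintilimab and
    IBI305 per-cycle prices until |ICER(m) - wtp| < ``tol`` $/QALY;
    returns 1 - m.  If the base-case ICER is already at or below the
    threshold the reduction is 0.
    """
    if wtp is None:
        wtp = bundle.config.wtp
    if _evaluate_icer(bundle, scenario) <= wtp:
        return 0.0
    raw0 = bundle.raw
    si_key = _drug_key(raw0, "sintilimab", scenario)
    paths = [f"costs.{si_key}.value", "costs.ibi305.value"]
    bases = [_get_path(raw0, p) for p in paths]

    def icer_at(m: float) -> float:
        work = bundle.copy()
        for p, b in zip(paths, bases):
            _set_path(work.raw, p, b * m)
        return _evaluate_icer(work, scenario)

    lo, hi = 0.0, 1.0
    if icer_at(lo) > wtp:  # even a free regimen stays above threshold
        return 1.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        val = icer_at(mid)
        if abs(val - wtp) < tol:
            return 1.0 - mid
        if val > wtp:
            hi = mid
        else:
            lo = mid
    return 1.0 - 0.5 * (lo + hi)


def sample_param(spec: ParamSpec, rng: np.random.Generator, size=None):
    """Draw from the parameter's probabilistic distribution.

    Beta and gamma are moment-matched to mean = base and
    sd = (high - low) / 3.92 (the low-high span read as a 95% interval).
    Negative beta-bound quantities (disutilities) are sampled on their
    absolute value and negated.  An infeasible beta moment match falls
    back to uniform(low, high) with a logged warning.
    """
    if spec.psa_family == "fixed":
        return np.full(size, spec.base) if size else spec.base
    sd = (spec.high - spec.low) / 3.92
    if sd <= 0:
        return np.full(size, spec.base) if size else spec.base
    if spec.psa_family == "gamma":
        shape = (spec.base / sd) ** 2
        return rng.gamma(shape, sd**2 / spec.base, size)
    # beta
    sign = -1.0 if spec.base < 0 else 1.0
    m = abs(spec.base)
    var = sd**2
    if not 0 < m < 1 or var >= m * (1 - m):
        log.warning(
            "%s: beta moment match infeasible (mean %.4g, sd %.4g); "
            "falling back to uniform(low, high)", spec.name, m, sd,
        )
        return rng.uniform(spec.low, spec.high, size)
    nu = m * (1 - m) / var - 1
    return sign * rng.beta(m * nu, (1 - m) * nu, size)


def run_psa(
    bundle: ModelBundle,
    params: list[ParamSpec] | None = None,
    n: int = 10_000,
    seed: int = 42,
    scenario: str = "medicare",
) -> pd.DataFrame:
    """Probabilistic sensitivity analysis: ``n`` joint draws of every
    parameter, model rebuilt and evaluated per draw.

    Returns one row per draw with the sampled parameter values, both
    arms' discounted totals, and the incremental cost and QALYs.
    Survival-curve parameters are held fixed.  A single seeded generator
    consumes the parameters in their listed order, so runs are exactly
    reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = psa_params(bundle, scenario)
    rng = np.random.default_rng(seed)
    samples = {p.name: np.atleast_1d(sample_param(p, rng, n)) for p in params}

    work = bundle.copy()
    rows = np.empty((n, 6))
    for i in range(n):
        for p in params:
            p.apply(work.raw, float(samples[p.name][i]))
        sb, so = build_strategies(work, scenario)
        out_sb = evaluate_strategy(sb, work.config)
        out_so = evaluate_strategy(so, work.config)
        rows[i] = (
            out_sb.total_cost, out_sb.total_qalys,
            out_so.total_cost, out_so.total_qalys,
            out_sb.total_cost - out_so.total_cost,
            out_sb.total_qalys - out_so.total_qalys,
        )
    df = pd.DataFrame(
        rows,
        columns=["cost_sb", "qaly_sb", "cost_so", "qaly_so", "incr_cost", "incr_qaly"],
    )
    for name, vals in samples.items():
        df[name] = vals
    return df


def ceac(draws: pd.DataFrame, wtp_grid) -> pd.DataFrame:
    """Probability of positive net monetary benefit at each WTP value."""
    if len(draws) == 0:
        raise ValueError("no draws")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    nmb = (
        wtp_grid[:, None] * draws["incr_qaly"].to_numpy()[None, :]
        - draws["incr_cost"].to_numpy()[None, :]
    )
    return pd.DataFrame(
        {"wtp": wtp_grid, "prob_cost_effective": (nmb > 0).mean(axis=1)}
    )


def ce_plane(draws: pd.DataFrame, wtp: float) -> pd.DataFrame:
    """Scatter of incremental (QALY, cost) pairs with an NMB-positive flag."""
    if len(draws) == 0:
        raise ValueError("no draws")
    out = draws[["incr_qaly", "incr_cost"]].copy()
    out["nmb_positive"] = wtp * out["incr_qaly"] - out["incr_cost"] > 0
    return out
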