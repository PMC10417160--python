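"""Three-state Markov cohort model for first-line advanced-HCC therapy.

States are stable disease (SD, progression-free and on first-line
treatment), progressive disease (PD, on second-line management) and
death.  The whole cohort starts in SD; PD is one-way (no return to SD).
Cycle-specific transition probabilities are read off the fitted OS and
PFS curves as discrete conditional hazards, tp(t) = 1 - S(t)/S(t-u),
with the structure

    P(SD -> death) = tp_os,   P(SD -> PD) = max(0, tp_pfs - tp_os),
    P(PD -> death) = tp_os,   remainders stay put.

This choice pins the cohort exactly to the fitted curves: the dead
fraction equals 1 - S_os(k u) and SD occupancy equals S_pfs(k u)
whenever the SD->PD floor does not bind (a partitioned-survival
equivalence, used as an internal consistency oracle by the tests).

Costs and QALYs accrue per cycle with a half-cycle (trapezoid)
correction and per-cycle discounting; grade >=3 adverse events enter
once, at model start, as one-time costs and QALY decrements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache

import numpy as np
import pandas as pd

from .distributions import S_FLOOR, SurvivalDistribution, survival_at

__all__ = [
    "DAYS_PER_MONTH",
    "ModelConfig",
    "AdverseEventSpec",
    "StrategySpec",
    "CohortTrace",
    "StrategyOutcome",
    "Dominance",
    "IncrementalResult",
    "transition_matrix",
    "run_cohort",
    "evaluate_strategy",
    "icer",
]

DAYS_PER_MONTH = 30.4375  # 365.25 / 12


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings: 21-day cycles over a 10-year horizon, 5%/year
    discounting of costs and utilities, WTP = 3x 2021 Chinese GDP per capita."""

    cycle_days: float = 21.0
    horizon_years: float = 10.0
    discount_rate_annual: float = 0.05
    half_cycle_correction: bool = True
    wtp: float = 38334.0

    def __post_init__(self):
        if not 0 <= self.discount_rate_annual < 1:
            raise ValueError("discount rate must be in [0, 1)")
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def n_cycles(self) -> int:
        """Whole cycles covering the horizon (the last cycle is kept whole)."""
        return math.ceil(self.horizon_years * 12.0 / self.cycle_length_months - 1e-9)

    def discount_factors(self) -> np.ndarray:
        """Per-cycle factors (1+r)^(-k u / 12) for cycles k = 1..N."""
        k = np.arange(1, self.n_cycles + 1)
        years = k * self.cycle_length_months / 12.0
        return (1.0 + self.discount_rate_annual) ** (-years)


@dataclass(frozen=True)
class AdverseEventSpec:
    """A grade >=3 adverse event: probability of occurrence over the treatment
    course, one-time management cost, and one-time QALY decrement."""

    name: str
    incidence: float
    one_time_cost: float
    disutility: float  # <= 0

    def __post_init__(self):
        if not 0 <= self.incidence <= 1:
            raise ValueError(f"AE {self.name}: incidence must be in [0, 1]")
        if self.one_time_cost < 0:
            raise ValueError(f"AE {self.name}: cost must be >= 0")
        if self.disutility > 0:
            raise ValueError(f"AE {self.name}: disutility must be <= 0")


@dataclass(frozen=True)
class StrategySpec:
    """One treatment arm: survival curves plus per-cycle cost structure.

    While progression-free (SD) the arm pays its regimen drug cost, any
    administration cost, and follow-up + laboratory monitoring.  In PD it
    pays the second-line drug cost (see ``pd_drug_accrual``) plus the same
    monitoring costs.
    """

    name: str
    os: SurvivalDistribution
    pfs: SurvivalDistribution
    drug_cost_sd_per_cycle: float
    admin_cost_sd_per_cycle: float = 0.0
    followup_cost_per_cycle: float = 0.0
    lab_cost_per_cycle: float = 0.0
    subsequent_tx_proportion: float = 1.0
    subsequent_tx_cost_per_cycle: float = 0.0
    pd_drug_accrual: str = "all"  # "all": full price over PD; "proportional": x proportion
    utility_sd: float = 0.76
    utility_pd: float = 0.68
    adverse_events: tuple[AdverseEventSpec, ...] = ()

    def __post_init__(self):
        for attr in ("utility_sd", "utility_pd"):
            if not 0 <= getattr(self, attr) <= 1:
                raise ValueError(f"{attr} must be in [0, 1]")
        if not 0 <= self.subsequent_tx_proportion <= 1:
            raise ValueError("subsequent_tx_proportion must be in [0, 1]")
        if self.pd_drug_accrual not in ("all", "proportional"):
            raise ValueError("pd_drug_accrual must be 'all' or 'proportional'")
        for attr in (
            "drug_cost_sd_per_cycle",
            "admin_cost_sd_per_cycle",
            "followup_cost_per_cycle",
            "lab_cost_per_cycle",
            "subsequent_tx_cost_per_cycle",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        object.__setattr__(self, "adverse_events", tuple(self.adverse_events))

    @property
    def sd_cost_per_cycle(self) -> float:
        return (
            self.drug_cost_sd_per_cycle
            + self.admin_cost_sd_per_cycle
            + self.followup_cost_per_cycle
            + self.lab_cost_per_cycle
        )

    @property
    def pd_cost_per_cycle(self) -> float:
        w = (
            self.subsequent_tx_proportion
            if self.pd_drug_accrual == "proportional"
            else 1.0
        )
        return (
            w * self.subsequent_tx_cost_per_cycle
            + self.followup_cost_per_cycle
            + self.lab_cost_per_cycle
        )

    @property
    def ae_one_time_cost(self) -> float:
        return sum(ae.incidence * ae.one_time_cost for ae in self.adverse_events)

    @property
    def ae_one_time_qaly(self) -> float:
        return sum(ae.incidence * ae.disutility for ae in self.adverse_events)


@dataclass
class CohortTrace:
    """State occupancy and (discounted) flows per cycle.

    Arrays ``sd``, ``pd``, ``dead`` have length n_cycles + 1 (cycle 0 =
    model start); the flow arrays have length n_cycles (cycle k covers
    (k-1, k]).  One-time adverse-event burdens are kept separate.
    """

    config: ModelConfig
    sd: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    cost_cycle: np.ndarray
    cost_disc: np.ndarray
    qaly_cycle: np.ndarray
    qaly_disc: np.ndarray
    ly_cycle: np.ndarray
    ly_disc: np.ndarray
    ae_cost: float = 0.0
    ae_qaly: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        u = self.config.cycle_length_months
        k = np.arange(1, self.config.n_cycles + 1)
        return pd.DataFrame(
            {
                "cycle": k,
                "t_months": k * u,
                "sd": self.sd[1:],
                "pd": self.pd[1:],
                "dead": self.dead[1:],
                "cost_cycle": self.cost_cycle,
                "cost_disc": self.cost_disc,
                "qaly_cycle": self.qaly_cycle,
                "qaly_disc": self.qaly_disc,
            }
        )


@dataclass(frozen=True)
class StrategyOutcome:
    name: str
    total_cost: float
    total_qalys: float
    total_lys: float


class Dominance(str, Enum):
    DOMINANT = "dominant"  # cheaper and more effective
    DOMINATED = "dominated"  # costlier and less effective
    TRADEOFF = "tradeoff"


@dataclass(frozen=True)
class IncrementalResult:
    incr_cost: float
    incr_qaly: float
    icer: float | None
    dominance: Dominance


def transition_matrix(
    strategy: StrategySpec, cycle_index: int, config: ModelConfig
) -> np.ndarray:
    """Row-stochastic 3x3 matrix (states ordered SD, PD, death) for one cycle."""
    if cycle_index < 1:
        raise ValueError("cycle_index starts at 1")
    u = config.cycle_length_months
    t = cycle_index * u
    tp_os, tp_pfs = _cycle_probs(strategy.os, strategy.pfs, t, u)
    sd_to_pd = max(0.0, tp_pfs - tp_os)
    m = np.array(
        [
            [1.0 - tp_pfs, sd_to_pd, tp_os],
            [0.0, 1.0 - tp_os, tp_os],
            [0.0, 0.0, 1.0],
        ]
    )
    # the SD row can drift from 1 by the floor on SD->PD; renormalize into SD->SD
    m[0, 0] = 1.0 - m[0, 1] - m[0, 2]
    return m


def _cycle_probs(os_dist, pfs_dist, t, u):
    s_os0 = max(survival_at(os_dist, t - u), S_FLOOR)
    s_pfs0 = max(survival_at(pfs_dist, t - u), S_FLOOR)
    tp_os = min(max(1.0 - survival_at(os_dist, t) / s_os0, 0.0), 1.0)
    tp_pfs = min(max(1.0 - survival_at(pfs_dist, t) / s_pfs0, 0.0), 1.0)
    return tp_os, tp_pfs


@lru_cache(maxsize=512)
def _occupancy_cached(
    os_key: tuple, pfs_key: tuple, u: float, n_cycles: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    os_dist = SurvivalDistribution(os_key[0], dict(os_key[1]))
    pfs_dist = SurvivalDistribution(pfs_key[0], dict(pfs_key[1]))
    sd = np.empty(n_cycles + 1)
    pd_ = np.empty(n_cycles + 1)
    dead = np.empty(n_cycles + 1)
    sd[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
    ts = np.arange(n_cycles + 1) * u
    s_os = np.asarray(survival_at(os_dist, ts))
    s_pfs = np.asarray(survival_at(pfs_dist, ts))
    for k in range(1, n_cycles + 1):
        tp_os = min(max(1.0 - s_os[k] / max(s_os[k - 1], S_FLOOR), 0.0), 1.0)
        tp_pfs = min(max(1.0 - s_pfs[k] / max(s_pfs[k - 1], S_FLOOR), 0.0), 1.0)
        sd_to_pd = max(0.0, tp_pfs - tp_os)
        sd[k] = sd[k - 1] * (1.0 - sd_to_pd - tp_os)
        pd_[k] = sd[k - 1] * sd_to_pd + pd_[k - 1] * (1.0 - tp_os)
        dead[k] = dead[k - 1] + (sd[k - 1] + pd_[k - 1]) * tp_os
    return sd, pd_, dead


def _dist_key(d: SurvivalDistribution) -> tuple:
    return (d.family, tuple(d.params.items()))


def run_cohort(strategy: StrategySpec, config: ModelConfig) -> CohortTrace:
    """Iterate the cohort from (1, 0, 0) over the horizon and accumulate flows."""
    n = config.n_cycles
    u = config.cycle_length_months
    sd, pd_, dead = _occupancy_cached(
        _dist_key(strategy.os), _dist_key(strategy.pfs), u, n
    )

    if config.half_cycle_correction:
        sd_w = 0.5 * (sd[:-1] + sd[1:])
        pd_w = 0.5 * (pd_[:-1] + pd_[1:])
    else:
        sd_w, pd_w = sd[1:], pd_[1:]

    disc = config.discount_factors()
    u_years = u / 12.0
    cost_cycle = sd_w * strategy.sd_cost_per_cycle + pd_w * strategy.pd_cost_per_cycle
    qaly_cycle = (sd_w * strategy.utility_sd + pd_w * strategy.utility_pd) * u_years
    ly_cycle = (sd_w + pd_w) * u_years

    return CohortTrace(
        config=config,
        sd=sd.copy(),
        pd=pd_.copy(),
        dead=dead.copy(),
        cost_cycle=cost_cycle,
        cost_disc=cost_cycle * disc,
        qaly_cycle=qaly_cycle,
        qaly_disc=qaly_cycle * disc,
        ly_cycle=ly_cycle,
        ly_disc=ly_cycle * disc,
        ae_cost=strategy.ae_one_time_cost,
        ae_qaly=strategy.ae_one_time_qaly,
    )


def evaluate_strategy(strategy: StrategySpec, config: ModelConfig) -> StrategyOutcome:
    """Discounted totals for one arm (adverse-event one-time burden included)."""
    trace = run_cohort(strategy, config)
    return StrategyOutcome(
        name=strategy.name,
        total_cost=float(np.sum(trace.cost_disc) + trace.ae_cost),
        total_qalys=float(np.sum(trace.qaly_disc) + trace.ae_qaly),
        total_lys=float(np.sum(trace.ly_disc)),
    )


def icer(
    intervention: StrategyOutcome, comparator: StrategyOutcome
) -> IncrementalResult:
    """Incremental cost-effectiveness of ``intervention`` over ``comparator``."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qalys - comparator.total_qalys
    if d_qaly == 0:
        dom = Dominance.DOMINANT if d_cost < 0 else Dominance.TRADEOFF
        if d_cost > 0:
            dom = Dominance.DOMINATED
        return IncrementalResult(d_cost, d_qaly, None, dom)
    if d_qaly > 0 and d_cost < 0:
        dom = Dominance.DOMINANT
    elif d_qaly < 0 and d_cost > 0:
        dom = Dominance.DOMINATED
    else:
        dom = Dominance.TRADEOFF
    return IncrementalResult(d_cost, d_qaly, d_cost / d_qaly, dom)
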