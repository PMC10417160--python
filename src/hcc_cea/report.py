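"""Scenario reports: the two-pricing-scenario base-case workflow.

A :class:`ScenarioReport` wraps the cohort-model outputs for one pricing
scenario without recomputation — the report numbers ARE the
``evaluate_strategy`` outputs — plus the incremental block and a
cost-effectiveness decision at the configured willingness-to-pay.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

from .config import SCENARIOS, ModelBundle, build_strategies
from .markov import IncrementalResult, StrategyOutcome, evaluate_strategy, icer

__all__ = ["ScenarioReport", "run_scenario", "run_scenarios"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioReport:
    scenario: str
    intervention: StrategyOutcome
    comparator: StrategyOutcome
    incremental: IncrementalResult
    wtp: float

    @property
    def cost_effective(self) -> bool:
        return self.incremental.icer is not None and self.incremental.icer <= self.wtp

    @property
    def decision(self) -> str:
        name = self.intervention.name
        if self.incremental.dominance.value == "dominant":
            return f"{name} dominates (cheaper and more effective): cost-effective"
        if self.incremental.dominance.value == "dominated":
            return f"{name} is dominated (costlier and less effective): not cost-effective"
        if self.incremental.icer is None:
            return f"equal effectiveness; decide on cost alone (incr cost {self.incremental.incr_cost:+.2f})"
        verdict = "cost-effective" if self.cost_effective else "not cost-effective"
        return (
            f"ICER ${self.incremental.icer:,.2f}/QALY vs WTP ${self.wtp:,.0f}/QALY: "
            f"{name} is {verdict}"
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "strategies": {
                out.name: {
                    "cost": out.total_cost,
                    "qalys": out.total_qalys,
                    "lys": out.total_lys,
                }
                for out in (self.intervention, self.comparator)
            },
            "incremental": {
                "cost": self.incremental.incr_cost,
                "qalys": self.incremental.incr_qaly,
                "icer": self.incremental.icer,
                "dominance": self.incremental.dominance.value,
            },
            "wtp": self.wtp,
            "decision": self.decision,
        }

    def summary(self) -> str:
        lines = [f"[{self.scenario}]"]
        for out in (self.intervention, self.comparator):
            lines.append(
                f"  {out.name:20s} cost ${out.total_cost:>10,.2f}   "
                f"QALYs {out.total_qalys:6.2f}   LYs {out.total_lys:6.2f}"
            )
        inc = self.incremental
        icer_txt = f"${inc.icer:,.2f}/QALY" if inc.icer is not None else "undefined"
        lines.append(
            f"  incremental          cost ${inc.incr_cost:>10,.2f}   "
            f"QALYs {inc.incr_qaly:6.2f}   ICER {icer_txt}"
        )
        lines.append(f"  {self.decision}")
        return "\n".join(lines)


def run_scenario(bundle: ModelBundle, scenario: str) -> ScenarioReport:
    """Evaluate both arms under one pricing scenario."""
    sb, so = build_strategies(bundle, scenario)
    out_sb = evaluate_strategy(sb, bundle.config)
    out_so = evaluate_strategy(so, bundle.config)
    log.info(
        "scenario=%s config_hash=%s cycles=%d",
        scenario,
        hashlib.sha256(bundle.dump().encode()).hexdigest()[:12],
        bundle.config.n_cycles,
    )
    return ScenarioReport(
        scenario=scenario,
        intervention=out_sb,
        comparator=out_so,
        incremental=icer(out_sb, out_so),
        wtp=bundle.config.wtp,
    )


def run_scenarios(bundle: ModelBundle) -> dict[str, ScenarioReport]:
    """The full base-case workflow: list-price and post-insurance scenarios."""
    return {scenario: run_scenario(bundle, scenario) for scenario in SCENARIOS}
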