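"""Cohort model: transition structure, conservation, oracles, ICER logic."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import integrate, stats

from hcc_cea.config import build_strategies
from hcc_cea.distributions import SurvivalDistribution, survival_at
from hcc_cea.markov import (
    DAYS_PER_MONTH,
    Dominance,
    ModelConfig,
    StrategyOutcome,
    StrategySpec,
    evaluate_strategy,
    icer,
    run_cohort,
    transition_matrix,
)
from hcc_cea.synth import random_model_config

CONFIG = ModelConfig()


def simple_strategy(**overrides) -> StrategySpec:
    base = dict(
        name="test",
        os=SurvivalDistribution("lognormal", {"meanlog": 2.763, "sdlog": 0.971}),
        pfs=SurvivalDistribution("lognormal", {"meanlog": 1.60, "sdlog": 1.03}),
        drug_cost_sd_per_cycle=1000.0,
        followup_cost_per_cycle=50.0,
        lab_cost_per_cycle=100.0,
        subsequent_tx_cost_per_cycle=800.0,
    )
    base.update(overrides)
    return StrategySpec(**base)


class TestModelConfig:
    def test_canonical_cycle_structure(self):
        assert CONFIG.cycle_length_months == pytest.approx(21 / DAYS_PER_MONTH)
        assert CONFIG.cycle_length_months == pytest.approx(0.6899, abs=5e-5)
        assert CONFIG.n_cycles == 174

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(discount_rate_annual=1.2)
        with pytest.raises(ValueError):
            ModelConfig(cycle_days=0)


class TestTransitionMatrix:
    def test_rows_stochastic_every_cycle(self):
        s = simple_strategy()
        for k in (1, 10, 100, 174):
            m = transition_matrix(s, k, CONFIG)
            assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all() and (m <= 1).all()

    def test_equal_exponential_hazards_no_progression(self):
        """With OS and PFS both exponential at the same rate, leaving SD can
        only mean dying: P(SD -> PD) = 0 at every cycle."""
        d = SurvivalDistribution("exponential", {"rate": 0.1})
        s = simple_strategy(os=d, pfs=d)
        for k in (1, 7, 50):
            assert transition_matrix(s, k, CONFIG)[0, 1] == 0.0

    def test_first_cycle_against_normal_cdf(self):
        """Sorafenib arm, cycle 1: SD-exit probability equals 1 - S_pfs(u)
        evaluated directly through the normal CDF."""
        u = CONFIG.cycle_length_months
        s = simple_strategy(
            os=SurvivalDistribution("loglogistic", {"shape": 1.68, "scale": 10.57}),
            pfs=SurvivalDistribution("lognormal", {"meanlog": 1.115, "sdlog": 0.781}),
        )
        m = transition_matrix(s, 1, CONFIG)
        tp_pfs_expected = stats.norm.cdf((math.log(u) - 1.115) / 0.781)
        assert m[0, 1] + m[0, 2] == pytest.approx(tp_pfs_expected, rel=1e-12)

    def test_absorbing_death(self):
        m = transition_matrix(simple_strategy(), 3, CONFIG)
        assert m[2].tolist() == [0.0, 0.0, 1.0]


class TestCohortTrace:
    def test_occupancy_conserved_and_monotone(self):
        trace = run_cohort(simple_strategy(), CONFIG)
        total = trace.sd + trace.pd + trace.dead
        assert np.allclose(total, 1.0, atol=1e-12)
        assert np.all(np.diff(trace.dead) >= -1e-15)
        assert np.all(np.diff(trace.sd) <= 1e-15)

    def test_death_curve_telescopes_onto_fitted_os(self):
        """Markov-vs-partitioned-survival equivalence: the cohort's dead
        fraction at cycle k is exactly 1 - S_os(k u)."""
        s = simple_strategy()
        trace = run_cohort(s, CONFIG)
        u = CONFIG.cycle_length_months
        ts = np.arange(CONFIG.n_cycles + 1) * u
        assert np.allclose(trace.dead, 1.0 - survival_at(s.os, ts), atol=1e-10)

    def test_sd_occupancy_on_fitted_pfs_when_floor_slack(self):
        s = simple_strategy()
        u = CONFIG.cycle_length_months
        ts = np.arange(CONFIG.n_cycles + 1) * u
        # verify the floor never binds for these curves, then the identity
        tp_os = 1 - survival_at(s.os, ts[1:]) / survival_at(s.os, ts[:-1])
        tp_pfs = 1 - survival_at(s.pfs, ts[1:]) / survival_at(s.pfs, ts[:-1])
        assert (tp_pfs >= tp_os - 1e-12).all()
        trace = run_cohort(s, CONFIG)
        assert np.allclose(trace.sd, survival_at(s.pfs, ts), atol=1e-10)

    def test_zero_costs_and_utilities_zero_totals(self):
        s = simple_strategy(
            drug_cost_sd_per_cycle=0.0,
            followup_cost_per_cycle=0.0,
            lab_cost_per_cycle=0.0,
            subsequent_tx_cost_per_cycle=0.0,
            utility_sd=0.0,
            utility_pd=0.0,
        )
        out = evaluate_strategy(s, CONFIG)
        assert out.total_cost == 0.0 and out.total_qalys == 0.0
        assert out.total_lys > 0

    def test_cost_is_homogeneous_in_cost_inputs(self):
        s = simple_strategy()
        halved = dataclasses.replace(
            s,
            drug_cost_sd_per_cycle=s.drug_cost_sd_per_cycle / 2,
            followup_cost_per_cycle=s.followup_cost_per_cycle / 2,
            lab_cost_per_cycle=s.lab_cost_per_cycle / 2,
            subsequent_tx_cost_per_cycle=s.subsequent_tx_cost_per_cycle / 2,
        )
        assert evaluate_strategy(halved, CONFIG).total_cost == pytest.approx(
            evaluate_strategy(s, CONFIG).total_cost / 2, rel=1e-12
        )

    def test_undiscounted_full_utility_qalys_match_os_integral(self):
        """With no discounting and utility 1 everywhere, total QALYs are the
        restricted mean survival time of the OS curve over the horizon."""
        cfg = ModelConfig(discount_rate_annual=0.0)
        s = simple_strategy(utility_sd=1.0, utility_pd=1.0)
        out = evaluate_strategy(s, cfg)
        horizon = cfg.n_cycles * cfg.cycle_length_months
        rmst_months, _ = integrate.quad(
            lambda t: float(survival_at(s.os, t)), 0, horizon, limit=200
        )
        # trapezoid on the cycle grid vs exact integral: agreement well
        # within one half-cycle of survival area
        assert out.total_qalys == pytest.approx(
            rmst_months / 12.0, abs=0.5 * cfg.cycle_length_months / 12.0
        )

    def test_exponential_life_expectancy_closed_form(self):
        """Discount 0, horizon >> 1/rate: mean life-years approach 1/rate."""
        rate = 0.1  # per month -> mean 10 months
        d = SurvivalDistribution("exponential", {"rate": rate})
        cfg = ModelConfig(discount_rate_annual=0.0, horizon_years=80)
        out = evaluate_strategy(simple_strategy(os=d, pfs=d), cfg)
        assert out.total_lys * 12 == pytest.approx(1 / rate, rel=0.01)

    def test_adverse_events_enter_once(self):
        from hcc_cea.markov import AdverseEventSpec

        s = simple_strategy(
            adverse_events=(
                AdverseEventSpec("hypertension", 0.14, 155.56, -0.016),
                AdverseEventSpec("platelet", 0.08, 332.15, -0.146),
            )
        )
        base = evaluate_strategy(dataclasses.replace(s, adverse_events=()), CONFIG)
        with_ae = evaluate_strategy(s, CONFIG)
        assert with_ae.total_cost - base.total_cost == pytest.approx(
            0.14 * 155.56 + 0.08 * 332.15
        )
        assert with_ae.total_qalys - base.total_qalys == pytest.approx(
            0.14 * -0.016 + 0.08 * -0.146
        )


class TestRandomStrategies:
    @pytest.mark.parametrize("seed", range(12))
    def test_invariants_hold_for_random_configurations(self, seed):
        bundle = random_model_config(seed)
        for strat in bundle.strategies("list_price"):
            trace = run_cohort(strat, bundle.config)
            assert np.allclose(trace.sd + trace.pd + trace.dead, 1.0, atol=1e-12)
            assert np.all(np.diff(trace.dead) >= -1e-15)
            ts = (
                np.arange(bundle.config.n_cycles + 1)
                * bundle.config.cycle_length_months
            )
            assert np.allclose(
                trace.dead, 1.0 - survival_at(strat.os, ts), atol=1e-10
            )


class TestIcer:
    def test_arithmetic(self):
        a = StrategyOutcome("a", 44635.28, 1.30, 1.8)
        b = StrategyOutcome("b", 27083.10, 0.97, 1.4)
        res = icer(a, b)
        assert res.incr_cost == pytest.approx(17552.18)
        assert res.incr_qaly == pytest.approx(0.33)
        assert res.icer == pytest.approx(53188.42, abs=0.5)
        assert res.dominance is Dominance.TRADEOFF

    def test_dominance_flags(self):
        cheap_good = StrategyOutcome("x", 100.0, 2.0, 2.0)
        dear_bad = StrategyOutcome("y", 200.0, 1.0, 1.0)
        assert icer(cheap_good, dear_bad).dominance is Dominance.DOMINANT
        assert icer(dear_bad, cheap_good).dominance is Dominance.DOMINATED

    def test_equal_effectiveness_undefined_icer(self):
        a = StrategyOutcome("a", 100.0, 1.0, 1.0)
        b = StrategyOutcome("b", 90.0, 1.0, 1.0)
        res = icer(a, b)
        assert res.icer is None and res.dominance is Dominance.DOMINATED
        assert icer(b, a).dominance is Dominance.DOMINANT


class TestPricingScenarios:
    def test_insurance_prices_lower_costs_both_arms(self, bundle):
        list_sb, list_so = build_strategies(bundle, "list_price")
        med_sb, med_so = build_strategies(bundle, "medicare")
        cfg = bundle.config
        assert (
            evaluate_strategy(med_sb, cfg).total_cost
            < evaluate_strategy(list_sb, cfg).total_cost
        )
        assert (
            evaluate_strategy(med_so, cfg).total_cost
            < evaluate_strategy(list_so, cfg).total_cost
        )

    def test_insurance_raises_icer(self, bundle):
        def icer_of(scn):
            sb, so = build_strategies(bundle, scn)
            return icer(
                evaluate_strategy(sb, bundle.config),
                evaluate_strategy(so, bundle.config),
            ).icer

        assert icer_of("medicare") > icer_of("list_price")
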