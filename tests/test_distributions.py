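"""Survival families: closed forms, transition probabilities, censored MLE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcc_cea.distributions import (
    FAMILIES,
    FitResult,
    IPDRecord,
    SurvivalDistribution,
    cycle_transition_prob,
    fit_mle,
    median_survival,
    rank_fits,
    survival_at,
)
from hcc_cea.synth import SimulationSpec, simulate_ipd

from conftest import FAMILY_EXAMPLES

U = 21 / 30.4375  # months per cycle


def test_survival_function_known_values():
    lnorm = SurvivalDistribution("lognormal", {"meanlog": 2.763, "sdlog": 0.971})
    assert survival_at(lnorm, math.exp(2.763)) == pytest.approx(0.5, abs=1e-12)
    llog = SurvivalDistribution("loglogistic", {"shape": 1.68, "scale": 10.57})
    assert survival_at(llog, 10.57) == pytest.approx(0.5, abs=1e-12)
    expo = SurvivalDistribution("exponential", {"rate": 0.1})
    assert survival_at(expo, 0.0) == 1.0
    # explicit closed form for the log-logistic at an off-median point
    t = 24.0
    assert survival_at(llog, t) == pytest.approx(
        1.0 / (1.0 + (t / 10.57) ** 1.68), rel=1e-12
    )


@pytest.mark.parametrize(
    "dist, expected",
    [
        (SurvivalDistribution("lognormal", {"meanlog": 1.115, "sdlog": 0.781}), math.exp(1.115)),
        (SurvivalDistribution("loglogistic", {"shape": 1.68, "scale": 10.57}), 10.57),
        (SurvivalDistribution("weibull", {"shape": 1.0, "scale": 2.0}), 2.0 * math.log(2.0)),
        (SurvivalDistribution("exponential", {"rate": 0.25}), math.log(2.0) / 0.25),
    ],
)
def test_median_closed_forms(dist, expected):
    assert median_survival(dist) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("family", FAMILIES)
def test_median_is_half_survival_point(family):
    dist = SurvivalDistribution(family, FAMILY_EXAMPLES[family])
    assert survival_at(dist, median_survival(dist)) == pytest.approx(0.5, abs=1e-9)


@pytest.mark.parametrize(
    "family, params",
    [
        ("lognormal", {"meanlog": 1.0, "sdlog": -0.5}),
        ("weibull", {"shape": 0.0, "scale": 2.0}),
        ("exponential", {"rate": -1.0}),
        ("weibull", {"shape": 1.0}),  # missing parameter
        ("notafamily", {"rate": 1.0}),
    ],
)
def test_invalid_parameters_rejected(family, params):
    with pytest.raises(ValueError):
        SurvivalDistribution(family, params)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(FAMILIES),
    a=st.floats(0.3, 3.0),
    b=st.floats(0.05, 20.0),
)
def test_survival_monotone_non_increasing(family, a, b):
    names = {
        "exponential": {"rate": b},
        "weibull": {"shape": a, "scale": b},
        "gamma": {"shape": a, "rate": b},
        "lognormal": {"meanlog": a, "sdlog": b},
        "loglogistic": {"shape": a, "scale": b},
        "gompertz": {"shape": a, "rate": b},
    }
    dist = SurvivalDistribution(family, names[family])
    grid = np.linspace(0.0, 120.0, 1000)
    s = survival_at(dist, grid)
    assert s[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((s >= 0) & (s <= 1))


@pytest.mark.parametrize("family", FAMILIES)
def test_transition_prob_telescoping(family):
    """Product of per-cycle survival over K cycles equals S(K u) to 1e-10."""
    dist = SurvivalDistribution(family, FAMILY_EXAMPLES[family])
    K = 50
    prod = 1.0
    for k in range(1, K + 1):
        prod *= 1.0 - cycle_transition_prob(dist, k * U, U)
    assert prod == pytest.approx(float(survival_at(dist, K * U)), abs=1e-10)


def test_transition_prob_exponential_memoryless():
    dist = SurvivalDistribution("exponential", {"rate": 0.2})
    expected = 1.0 - math.exp(-0.2 * U)
    for t in (U, 5 * U, 50 * U):
        assert cycle_transition_prob(dist, t, U) == pytest.approx(expected, rel=1e-12)


def test_transition_prob_first_cycle_identity():
    dist = SurvivalDistribution("lognormal", {"meanlog": 2.763, "sdlog": 0.971})
    assert cycle_transition_prob(dist, U, U) == pytest.approx(
        1.0 - float(survival_at(dist, U)), rel=1e-12
    )


def test_transition_prob_depleted_tail_absorbs():
    dist = SurvivalDistribution("weibull", {"shape": 3.0, "scale": 1.0})
    assert cycle_transition_prob(dist, 4000.0, U) == 1.0


def test_fit_exponential_matches_closed_form_mle():
    spec = SimulationSpec(
        SurvivalDistribution("exponential", {"rate": 0.15}), n=500, seed=3
    )
    data = simulate_ipd(spec)
    fit = fit_mle(data, "exponential")
    analytic = sum(r.event for r in data) / sum(r.time for r in data)
    assert fit.distribution.params["rate"] == pytest.approx(analytic, rel=1e-5)
    assert fit.converged


def test_fit_requires_events_and_size():
    with pytest.raises(ValueError, match="at least 10"):
        fit_mle([IPDRecord(1.0, True)] * 5, "exponential")
    with pytest.raises(ValueError, match="censored"):
        fit_mle([IPDRecord(1.0, False)] * 20, "exponential")


@pytest.mark.parametrize("family", FAMILIES)
def test_fit_recovers_generating_parameters(family):
    """At n = 2000 the MLE lands within 3 standard errors of the truth."""
    truth = FAMILY_EXAMPLES[family]
    dist = SurvivalDistribution(family, truth)
    data = simulate_ipd(SimulationSpec(dist, n=2000, seed=11))
    fit = fit_mle(data, family)
    assert fit.converged
    for name, true_val in truth.items():
        se = fit.stderr.get(name, 0.0)
        assert se > 0, f"no standard error for {name}"
        assert abs(fit.distribution.params[name] - true_val) <= 3 * se, (
            f"{family}.{name}: {fit.distribution.params[name]:.4f} vs {true_val} "
            f"(se {se:.4f})"
        )


def test_fit_recovery_lognormal_frozen_tolerance():
    """Uncensored log-normal sample, trial-scale parameters: the recovered
    meanlog/sdlog sit within 3 asymptotic SEs (0.06 / 0.05 at n = 2000)."""
    dist = SurvivalDistribution("lognormal", {"meanlog": 2.763, "sdlog": 0.971})
    fit = fit_mle(simulate_ipd(SimulationSpec(dist, n=2000, seed=5)), "lognormal")
    assert fit.distribution.params["meanlog"] == pytest.approx(2.763, abs=0.06)
    assert fit.distribution.params["sdlog"] == pytest.approx(0.971, abs=0.05)


def test_fit_recovery_loglogistic_under_censoring():
    """~30% administrative censoring at 24 months leaves both parameters
    recoverable within the stated tolerances."""
    dist = SurvivalDistribution("loglogistic", {"shape": 1.68, "scale": 10.57})
    data = simulate_ipd(
        SimulationSpec(dist, n=2000, censoring="administrative", t_max=24.0, seed=7)
    )
    frac_censored = 1 - sum(r.event for r in data) / len(data)
    assert 0.2 < frac_censored < 0.4
    fit = fit_mle(data, "loglogistic")
    assert fit.distribution.params["shape"] == pytest.approx(1.68, abs=0.12)
    assert fit.distribution.params["scale"] == pytest.approx(10.57, abs=0.5)


def test_rank_fits_orders_by_aic_then_bic():
    def fr(family, aic, bic):
        return FitResult(
            distribution=SurvivalDistribution(family, FAMILY_EXAMPLES[family]),
            loglik=0.0, aic=aic, bic=bic, n=100, converged=True,
        )

    ranked = rank_fits([fr("weibull", 510.2, 1), fr("gamma", 498.7, 1),
                        fr("lognormal", 505.1, 1)])
    assert [f.aic for f in ranked] == [498.7, 505.1, 510.2]
    ranked = rank_fits([fr("weibull", 900.0, 900.1), fr("gamma", 900.0, 899.9)])
    assert ranked[0].bic == 899.9
    with pytest.raises(ValueError):
        rank_fits([])
    bad = [fr("weibull", 1, 1),
           FitResult(ranked[0].distribution, 0.0, 1, 1, n=50, converged=True)]
    with pytest.raises(ValueError, match="same data"):
        rank_fits(bad)


@pytest.mark.parametrize(
    "family", ["lognormal", "loglogistic"]
)  # the two families the trial curves use
@pytest.mark.parametrize("seed", [1, 2, 3])
def test_model_selection_recovers_generating_family(family, seed):
    """Fitting all six families to n = 2000 samples ranks the truth first."""
    truth = {"lognormal": {"meanlog": 1.6, "sdlog": 1.03},
             "loglogistic": {"shape": 1.68, "scale": 10.57}}[family]
    data = simulate_ipd(
        SimulationSpec(SurvivalDistribution(family, truth), n=2000, seed=seed)
    )
    fits = [fit_mle(data, fam) for fam in FAMILIES]
    assert rank_fits(fits)[0].distribution.family == family


def test_aic_bic_definitions():
    dist = SurvivalDistribution("weibull", FAMILY_EXAMPLES["weibull"])
    fit = fit_mle(simulate_ipd(SimulationSpec(dist, n=200, seed=1)), "weibull")
    assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
    assert fit.bic == pytest.approx(2 * math.log(200) - 2 * fit.loglik)
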