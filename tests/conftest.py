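import pytest

from hcc_cea import load_default_config
from hcc_cea.distributions import SurvivalDistribution


@pytest.fixture(scope="session")
def bundle():
    return load_default_config()


@pytest.fixture()
def fresh_bundle():
    return load_default_config()


#: the four fitted trial curves (arm, endpoint) -> distribution
TRIAL_CURVES = {
    ("sintilimab_ibi305", "os"): SurvivalDistribution(
        "lognormal", {"meanlog": 2.763, "sdlog": 0.971}
    ),
    ("sintilimab_ibi305", "pfs"): SurvivalDistribution(
        "lognormal", {"meanlog": 1.60, "sdlog": 1.03}
    ),
    ("sorafenib", "os"): SurvivalDistribution(
        "loglogistic", {"shape": 1.68, "scale": 10.57}
    ),
    ("sorafenib", "pfs"): SurvivalDistribution(
        "lognormal", {"meanlog": 1.115, "sdlog": 0.781}
    ),
}

#: one representative parameter set per family, used in recovery tests
FAMILY_EXAMPLES = {
    "exponential": {"rate": 0.12},
    "weibull": {"shape": 1.4, "scale": 12.0},
    "gamma": {"shape": 1.8, "rate": 0.15},
    "lognormal": {"meanlog": 2.763, "sdlog": 0.971},
    "loglogistic": {"shape": 1.68, "scale": 10.57},
    "gompertz": {"shape": 0.08, "rate": 0.04},
}
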