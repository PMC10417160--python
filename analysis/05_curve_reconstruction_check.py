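#!/usr/bin/env python
"""End-to-end validation of the curve-reconstruction + refitting path.

The canonical pipeline consumes the already-fitted survival parameters;
this script demonstrates the alternative path used when only a
published KM figure is available.  For each of the four fitted trial
curves it simulates a trial-sized cohort, digitizes its KM step
function (120 points, slight jitter), reconstructs pseudo-IPD with
3-monthly numbers at risk, fits all six parametric families, and ranks
them by AIC.  Finding: the refitted parameters sit close to the inputs
and the generating family ranks first for the three log-normal curves;
for the sorafenib OS curve (n = 191, heavy censoring) the log-normal
edges out the true log-logistic by under one AIC point — the two
families are near-indistinguishable at that sample size, which is
itself a faithful picture of what curve refitting can and cannot
resolve.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from hcc_cea.distributions import FAMILIES, SurvivalDistribution, fit_mle, rank_fits
from hcc_cea.reconstruct import RiskTableEntry, km_estimate, reconstruct_ipd
from hcc_cea.synth import SimulationSpec, digitize_km, simulate_ipd

OUT = Path(__file__).resolve().parents[1] / "results"

CURVES = {
    "sb_os": ("lognormal", {"meanlog": 2.763, "sdlog": 0.971}, 380, 101),
    "sb_pfs": ("lognormal", {"meanlog": 1.60, "sdlog": 1.03}, 380, 102),
    "so_os": ("loglogistic", {"shape": 1.68, "scale": 10.57}, 191, 103),
    "so_pfs": ("lognormal", {"meanlog": 1.115, "sdlog": 0.781}, 191, 104),
}
FOLLOW_UP_MONTHS = 30.0  # administrative cutoff of the emulated trial


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for label, (family, params, n, seed) in CURVES.items():
        truth = SurvivalDistribution(family, params)
        data = simulate_ipd(
            SimulationSpec(truth, n=n, censoring="administrative",
                           t_max=FOLLOW_UP_MONTHS, seed=seed)
        )
        km = km_estimate(data)
        points = digitize_km(km, n_points=120, jitter_sd=0.005, seed=1)
        span = np.arange(0.0, FOLLOW_UP_MONTHS + 1e-9, 3.0)
        risk = [
            RiskTableEntry(float(t), sum(1 for r in data if r.time >= t))
            for t in span
        ]
        pseudo = reconstruct_ipd(points, risk)
        fits = rank_fits([fit_mle(pseudo, fam) for fam in FAMILIES])
        best = fits[0]
        rows.append(
            {
                "curve": label,
                "true_family": family,
                "best_family": best.distribution.family,
                "recovered": best.distribution.family == family,
                "true_params": str(params),
                "fit_params": str(
                    {k: round(v, 3) for k, v in best.distribution.params.items()}
                ),
                "aic_margin": fits[1].aic - fits[0].aic,
            }
        )
        print(
            f"{label}: true {family} -> best {best.distribution.family} "
            f"(AIC margin {fits[1].aic - fits[0].aic:.1f}), "
            f"params {rows[-1]['fit_params']}"
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "curve_refit.csv", index=False)
    print(f"wrote {OUT / 'curve_refit.csv'}")


if __name__ == "__main__":
    main()
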