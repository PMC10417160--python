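# Canonical model inputs: sintilimab + IBI305 (bevacizumab biosimilar)
# versus sorafenib, first-line unresectable HCC, Chinese payer
# perspective, 2021 USD.  Costs are per 21-day cycle; "medicare" entries
# are the prices after National Basic Medical Insurance coverage.
# low/high spans (base +/- 20%) are used by the one-way sensitivity
# analysis and, read as 95% intervals, by the probabilistic one.
model:
  cycle_days: 21
  horizon_years: 10
  discount_rate_annual: 0.05
  half_cycle_correction: true
  wtp: 38334
  # "all": the PD state accrues the full second-line drug price (the
  # convention the published base-case totals imply); "proportional":
  # weight it by the observed subsequent-treatment proportions below.
  pd_drug_accrual: all

survival:
  sintilimab_ibi305:
    os: {family: lognormal, meanlog: 2.763, sdlog: 0.971}
    pfs: {family: lognormal, meanlog: 1.60, sdlog: 1.03}
  sorafenib:
    os: {family: loglogistic, shape: 1.68, scale: 10.57}
    pfs: {family: lognormal, meanlog: 1.115, sdlog: 0.781}

costs:  # $ per cycle
  sintilimab: {value: 340.848, low: 272.848, high: 408.848}
  sintilimab_medicare: {value: 119.2968, low: 102.2544, high: 136.3392}
  ibi305: {value: 1644.5916, low: 1315.5916, high: 1973.5916}
  sorafenib: {value: 1259.244, low: 1007.244, high: 1511.244}
  sorafenib_medicare: {value: 629.622, low: 539.676, high: 719.568}
  regorafenib: {value: 800.2827, low: 685.9566, high: 914.6088}  # insured price
  followup: {value: 59.2, low: 47.36, high: 71.04}
  laboratory: {value: 157.5, low: 126.0, high: 189.0}
  administration: {value: 69.81, low: 55.85, high: 83.77}

# administration cost is charged while on first-line treatment (SD) for
# the intravenous regimen only; sorafenib is oral
admin_cost_arms: [sintilimab_ibi305]

utilities:
  sd: {value: 0.76, low: 0.608, high: 0.912}
  pd: {value: 0.68, low: 0.544, high: 0.816}

adverse_events:  # grade >= 3, one-time costs ($) and QALY decrements
  costs:
    ppe: {value: 16.63, low: 13.30, high: 19.95}
    platelet: {value: 332.15, low: 265.72, high: 398.58}
    hypertension: {value: 155.56, low: 124.45, high: 186.68}
  disutilities:
    ppe: {value: -0.15, low: -0.18, high: -0.12}
    platelet: {value: -0.146, low: -0.175, high: -0.117}
    hypertension: {value: -0.016, low: -0.019, high: -0.013}
  incidence:
    sintilimab_ibi305:
      hypertension: {value: 0.14, low: 0.112, high: 0.168}
      platelet: {value: 0.08, low: 0.064, high: 0.096}
    sorafenib:
      ppe: {value: 0.12, low: 0.096, high: 0.144}
      hypertension: {value: 0.06, low: 0.048, high: 0.072}
      platelet: {value: 0.03, low: 0.024, high: 0.036}

subsequent_treatment:
  drug: regorafenib
  proportion:
    sintilimab_ibi305: 0.29  # 109/380 received second-line therapy
    sorafenib: 0.47          # 89/191
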