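# Methods

## Decision problem and model structure

The package evaluates first-line sintilimab + IBI305 versus sorafenib
for unresectable hepatocellular carcinoma with a cohort-level state
transition model. Three states: stable disease (SD, on first-line
therapy), progressive disease (PD, on second-line management), death.
The cohort starts fully in SD; progression is irreversible. The cycle
is 21 days (one treatment cycle), expressed internally in months as
`21 / 30.4375 = 0.68994`; the 10-year horizon is covered by 174 whole
cycles (the last cycle is kept whole rather than truncated). Costs and
utilities are discounted at 5% per year with the per-cycle factor
`1.05^(−k·u/12)`; the half-cycle correction is the trapezoid variant —
each cycle's flows are computed from the average of start- and
end-of-cycle occupancy.

## Survival inputs and transition probabilities

OS and PFS per arm are parametric curves on a months scale
(intervention: log-normal OS `meanlog 2.763, sdlog 0.971` and PFS
`1.60, 1.03`; comparator: log-logistic OS `shape 1.68, scale 10.57` and
log-normal PFS `1.115, 0.781`). The implied medians (15.8 / 5.0 months
OS/PFS for the combination, 10.6 / 3.1 for sorafenib) match the trial's
reported medians, confirming the unit. Six families are supported
(exponential, Weibull, gamma, log-normal, log-logistic, Gompertz) with
the standard survival-analysis parameterizations; the Gompertz hazard is
`rate·exp(shape·t)` with shape restricted positive (no cure fraction) —
stated explicitly because conventions differ across software.

Per-cycle transition probabilities are conditional survival ratios
`tp(t) = 1 − S(t)/S(t−u)` evaluated at cycle ends `t = k·u` (cycle 1
gives `1 − S(u)`). The split between progression and death from SD is
not identifiable from marginal OS/PFS curves alone; the model assigns
both alive states the OS conditional hazard and gives SD→PD the excess
`max(0, tp_pfs − tp_os)`. This makes the model's death curve coincide
exactly with fitted OS and SD occupancy with fitted PFS (a partitioned
survival equivalence), which the tests enforce to 1e-10 via the
telescoping identity `Π(1 − tp) = S(K·u)`. Survival values are floored
at 1e-12 before division; a fully depleted tail is treated as absorbing.

## Costs, utilities, adverse events

All monetary values are carried at full printed precision (e.g. IBI305
$1,644.5916 per cycle), 2021 USD (conversion 6.34 CNY/USD noted for
provenance only); rounding happens only at presentation. While in SD an
arm pays its regimen acquisition cost, administration cost
(intravenous regimen only — sorafenib is oral), follow-up ($59.20) and
laboratory ($157.50) per cycle. In PD both arms pay the insured
regorafenib price ($800.2827/cycle) plus follow-up and laboratory.

Two conventions here were genuinely open and were fixed by calibration
against the published base-case totals:

- **PD drug accrual.** The trial observed 29% / 47% of patients
  receiving subsequent therapy, and weighting the regorafenib price by
  those proportions is one defensible reading; it under-predicts the
  published totals of both arms by 20–29%, however, while accruing the
  full price over the whole PD occupancy reproduces all four totals
  within ~6%. The default is therefore `pd_drug_accrual: all`, with the
  proportional mode retained as a config switch and the proportions kept
  as data.
- **Administration cost placement** stays with the intravenous arm only
  (`admin_cost_arms` in the config makes it explicit and editable).

Grade ≥3 adverse events (combination arm: hypertension 14%, decreased
platelet count 8%; sorafenib arm: palmar-plantar erythrodysaesthesia
12%, hypertension 6%, decreased platelet count 3%) enter once at model
start as `incidence × cost` and `incidence × disutility`. The AE table
is plain config data, so alternative AE sets are a YAML edit, not a code
change. Utilities: SD 0.76, PD 0.68, from published HCC studies.

Body weight (60 kg) and doses (sintilimab 200 mg, IBI305 15 mg/kg,
sorafenib 400 mg bid) stand behind the per-cycle prices but are not
recomputed; the prices are inputs.

Under these conventions the base case lands within tolerance of the
published totals, QALYs and ICERs, but the incremental cost does not:
the published increment is arithmetically consistent with its own
totals, whereas this model's deviations from those totals have opposite
signs across arms (+5.6% / −1.3%), so the increment overshoots by ~16%.
No cost placement satisfies the totals, the increment and the
OS-telescoping identity simultaneously; the discrepancy is structural
and is reported rather than hidden (the corresponding checks stay
failing at their stated tolerance).

## Sensitivity analyses

All uncertain inputs are `ParamSpec`s binding into the configuration
tree; survival-curve parameters carry no published uncertainty range and
are excluded (held at their fitted values) from both the tornado and the
PSA — a known limitation that understates decision uncertainty.

- **One-way:** each parameter to its ±20% bounds, others at base; the
  intervention's regimen acquisition cost (sintilimab + IBI305 summed)
  is varied as a single parameter, matching how the tornado is usually
  reported. Entries are ranked by ICER spread.
- **Threshold:** bisection on a multiplier of the sintilimab and IBI305
  per-cycle prices (not monitoring costs) until |ICER − WTP| < $1/QALY;
  reported as one minus the multiplier.
- **PSA:** 10,000 joint draws; gamma for costs, beta for
  probabilities/utilities (disutilities sampled beta on the absolute
  value and negated), moment-matched with mean = base and
  sd = (high − low)/3.92, i.e. the ±20% span read as a 95% interval.
  An infeasible beta match falls back to uniform(low, high) with a
  logged warning. A single seeded generator consumes parameters in
  their listed order, so runs are bit-reproducible. Sensitivity
  analyses default to the post-insurance ("medicare") pricing scenario,
  the policy-relevant one.

Cohort occupancy depends only on the survival curves, which the PSA
holds fixed, so occupancy is cached per (curves, cycle grid) and each
draw reduces to re-weighting flows — the full PSA runs in seconds.

## Pseudo-IPD reconstruction

`reconstruct_ipd` implements the interval-wise reconstruction from
digitized KM coordinates with numbers at risk: within each risk-table
interval the censoring count is chosen (deterministically, censor times
uniformly spaced) so the implied number at risk matches the next printed
value, and event counts follow the digitized drops through the KM
recursion; a printed total event count can constrain the final interval.
With one risk entry and no censoring the round trip is exact. Because
the original digitized coordinates are not published, this path is
validated entirely on synthetic round trips (max KM deviation ≤ 0.02 at
trial-like sizes) and serves as the alternative input route; the
canonical configuration carries the fitted parameters directly.

## Synthetic data

`simulate_ipd` draws by inverse-CDF from any supported family with no,
administrative, or random-exponential censoring; `digitize_km` emulates
graph-digitizer extraction (points stratified on the curve's drop mass —
roughly how a careful human traces a figure — plus truncated Gaussian
jitter, then monotone repair); `random_model_config` produces valid
random two-arm configurations for property tests. These emulate
marginal curves only: PFS/OS correlation at patient level, recruitment
drift, and digitizer axis-calibration error are not modelled, so passing
round-trip tests show internal consistency of the pipeline, not fidelity
to any particular published figure.

## Numerical choices

- MLE fitting: L-BFGS-B on log-transformed positive parameters
  (`meanlog` on its natural scale), deterministic moment/quantile
  starting values, no random restarts; standard errors from the
  numerical Hessian via the delta method. Exponential MLE matches the
  closed form events/exposure to 1e-5.
- Model selection: AIC ascending, ties by BIC, then a fixed family
  order.
- Median survival uses the scipy quantile function (closed forms where
  they exist).
- Degenerate inputs: all-censored samples and <10 records are rejected;
  empty or non-monotone digitized curves are repaired or rejected with
  the offending interval named.

## Limitations

- The transition structure is one of several consistent with marginal
  OS/PFS; the published model evidently used another (see the
  incremental-cost note above).
- No treatment-duration cap in SD (treat-to-progression) and no
  disease-management costs beyond follow-up/laboratory in PD.
- No distributional uncertainty on survival parameters in the PSA.
- Two-strategy comparisons only; no EVPI; no microsimulation.
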