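# dietmm

A probabilistic multimorbidity Markov cohort model for evaluating the
lifetime cost-effectiveness of brief dietary intervention in primary care.

Brief advice in primary care raises fruit-and-vegetable consumption by about
0.5 portions/day, which translates into small relative risk reductions in
the incidence of four chronic conditions — diabetes mellitus (DM), coronary
heart disease (CHD), stroke (STR) and colorectal cancer (CRC). `dietmm`
asks whether a universal (or age-targeted) strategy of delivering that
advice to healthy adults is worth its cost from a health-care perspective.

## The model

Healthy adults aged 30+ enter an annual-cycle Markov model whose 33 states
are every combination of the four physical conditions crossed with
(reversible) depression status — 2⁴ × 2 = 32 alive states — plus absorbing
Death. Physical disease is progressive (at most one new condition per
cycle, no remission); depression status is re-sampled each cycle from the
prevalence of the destination physical state. The cohort is advanced for
70 cycles, stratified by sex and single year of age, until everyone has
died or exited at age 100.

The intervention multiplies the incidence probabilities out of the healthy
At Risk state by relative risks RR_c (defaults: DM 0.965, CHD 0.959,
STR 0.975, CRC 0.997) for its first 5 cycles, in the eligible age range,
and charges a fixed cost per eligible participant-year (base case £35, one
family-practice consultation).

Uncertainty is fully probabilistic. For each simulation the model draws

- transition probabilities *p* ~ Beta(k+1, n−k+1) from event/denominator
  counts (beta-binomial sampling),
- state costs from a gamma distribution matched to the stratum mean and SD,
- utilities from a beta distribution matched to the mean and SE,

and runs both arms on the same draw (common random numbers), so
per-simulation increments isolate the intervention effect. Outcomes per
1,000 entrants include life-years by morbidity count, new incidences,
QALYs (half-cycle corrected, discounted at 3.5% with a 1.5% sensitivity),
costs (3.5%), net health benefit NHB = ΔQALY − ΔCost/λ at λ = £30,000 per
QALY, and cost-effectiveness acceptability curves.

Because the original stratified inputs come from a primary-care database
that cannot be redistributed, the package ships a synthetic-data generator
(`dietmm.synthetic_cprd`) that reproduces the qualitative structure of such
data — incidence and mortality rising with age, cost and mortality rising
with morbidity, depression prevalence elevated in disease states, utilities
declining with age and morbidity — with per-condition incidence levels
calibrated so that a standard-care run reproduces the benchmark crude
incidence rates (DM 6.5, CHD 7.6, STR 4.1, CRC 1.0 per 1,000
condition-free person-years).

## Worked example

```bash
dietmm generate-data --seed 1 --out inputs/        # six CSVs + provenance
dietmm run --inputs inputs/ --out base/ --sims 200 --seed 1
```

prints

```
intervention: NHB -0.90 (-1.35 to -0.43) QALYs/1,000; P(cost-effective at £30,000) = 0.0%
```

and `dietmm report --run-dir base/` shows the per-1,000 increments
(intervention − standard care), e.g.:

```
                         mean        lo95        hi95  prob_positive
ly_healthy             22.744      21.751      23.814          1.000
inc_DM                 -0.458      -0.490      -0.425          0.000
inc_CHD                -0.548      -0.589      -0.515          0.000
cost_intervention 153,272.386 153,019.904 153,491.132          1.000
d_cost_other      -21,414.730 -30,573.484 -13,070.472          0.000
d_cost_total      131,857.657 122,534.949 140,164.980          1.000
d_qaly_3_5              3.492       3.235       3.829          1.000
nhb                    -0.903      -1.350      -0.426          0.000
```

Read: the intervention buys ~22.7 extra disease-free life-years and ~3.5
QALYs per 1,000 entrants, at ~£153k of intervention cost per 1,000, partly
offset by ~£21k saved in other health care — a net health benefit just
below zero at £30,000/QALY, i.e. a universal strategy at one consultation
per year is unlikely to be cost-effective in this synthetic world. (With
synthetic inputs the uncertainty intervals reflect only the synthetic
strata sizes, so they are narrower than a real-data analysis would give.)

`dietmm sweep-cost` varies the annual unit cost (presets £7/£35/£70) and
`dietmm sweep-age` restricts eligibility to selected age bands (e.g.
50–74), where cost-effectiveness improves; `dietmm ceac` exports an
acceptability curve from saved per-simulation deltas.

Python API: `generate_bundle` / `read_bundle` → `run_psa(bundle, Scenario(),
EffectModel.default(), n_sims, seed)` → `CEAResult` with `per_sim`,
`summary`, `ceac` and `p_cost_effective`. See `docs/methods.md` for the
model's assumptions and numerical conventions.

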