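# Methods

## Model structure

The model is a discrete-time (annual-cycle) cohort state-transition model
on 33 states: every subset of {diabetes mellitus, coronary heart disease,
stroke, colorectal cancer} crossed with depression status (32 alive
states), plus absorbing Death. States are indexed canonically by
(morbidity count, condition order, depression flag) with Death last, and
serialized as labels such as `AT_RISK`, `DM+CHD|DEP`, `DEATH`.

Physical disease is progressive: the condition set can only grow, and at
most one condition is acquired per cycle. Annual incidence probabilities
are of order 1% or less, so simultaneous acquisitions are a second-order
effect; treating per-condition probabilities as competing risks within a
cycle keeps each transition row directly parameterizable from per-condition
incidence tables. Depression is reversible: after the physical/death part
of the transition is resolved, the destination's depression status is drawn
from the depression prevalence of the destination physical state, i.e.
depression occupancy tracks state-specific prevalence rather than carrying
its own incidence/remission rates. Deaths are resolved before depression,
so depression status cannot change in the cycle of death.

A transition row out of an alive state with per-condition probabilities
p_c and death probability p_d is:

- Death: p_d;
- acquire condition c: (1 − p_d) · p_c, split between the depressed and
  non-depressed destination by that state's prevalence;
- remain in the same physical state: (1 − p_d) · (1 − Σ p_c), split the
  same way.

If Σ p_c exceeds 1 (possible only with extreme inputs) the row is
renormalized with a runtime warning. Rows sum to 1 to machine precision
and place mass only on legal successors.

The intervention multiplies the incidence probabilities out of the At Risk
state (both depression statuses) by the per-condition relative risk, only
while the cycle index is within the intervention duration (5 years in the
base case) and the participant's current age is inside the eligibility
range. RR acts multiplicatively on the annual probability rather than on a
rate transform; at probabilities ≤ ~1% the difference is far below
reporting precision. Transition rows out of every other state are
bit-identical between arms.

## Cohort mechanics, half-cycle correction and discounting

The cohort is stratified by sex and single year of age; everyone enters At
Risk and non-depressed. Each cycle the cohort ages one year; occupancy
that would pass age 100 exits the model after its final cycle (the engine
can instead pool occupancy at the terminal age, `exit_at_max_age=False`,
which lets long runs approximate an infinite horizon for closed-form
checks). Occupancy is conserved to 1e−9 relative: alive + cumulative
deaths + cumulative exits = entrants, checked every run.

Half-cycle correction is implemented as trapezoidal occupancy credit: cycle
t credits half the start occupancy (valued at the start age) plus half the
end occupancy (valued at the end age, clamped to 100), and is discounted at
(1 + r)^−(t − 0.5). One convention covers life-years, QALYs and costs.
Under this convention a two-state alive/dead model with constant annual
death probability p and no discounting has life expectancy
(1 − p)/p + 1/2, which the engine reproduces to 1e−9 (an oracle test).
Costs are discounted at 3.5% only; QALYs at 3.5% with a 1.5% sensitivity
rate accumulated in the same pass. Intervention cost accrues as
unit_cost × the trapezoidal At-Risk, age-eligible occupancy during the
intervention cycles — participants who develop disease or die stop accruing
it, a choice the printed totals cannot adjudicate exactly; it is the
stricter of the two readings and is localized in one code path.

## Parameter uncertainty

Each PSA iteration draws one joint parameter set:

- transition probabilities (incidence, mortality, depression prevalence):
  Beta(k+1, n−k+1) from the stratum's event count k and denominator n.
  The uniform prior keeps zero-event strata sampleable; its expected value
  is (k+1)/(n+2).
- costs: gamma with shape (mean/sd)² and scale sd²/mean (method of
  moments); degenerate inputs (mean or sd zero) pass through unchanged.
- utilities: beta with ν = m(1−m)/se² − 1, α = mν, β = (1−m)ν; se = 0
  passes the mean through; infeasible moments (se² ≥ m(1−m)) are an error.
- intervention relative risks: fixed at their configured means by default.
  The published per-simulation RR ranges are far narrower than the
  0.13–0.87 portions/day CI would imply, so the exact sampling scheme
  behind them is not recoverable; fidelity to the printed means was
  preferred over speculation. A `portion_sampled` mode is provided that
  draws the portion increment d ~ Normal(0.5, (0.87−0.13)/(2·1.96))
  truncated at zero and applies RR_c = (per-portion RR_c)^d.

Every sampler has a deterministic expected-value mode returning its
analytic mean, used for calibration and oracle tests.

Both arms of a simulation share one draw (common random numbers), so
per-simulation increments, sign probabilities and percentile intervals are
within-pair quantities; an independent-arms mode exists as a sensitivity.
Summaries are means and 2.5/97.5 percentiles over simulations; the
probability cost-effective is the fraction of simulations with NHB > 0 at
the threshold (ties count as not cost-effective); the CEAC grid defaults to
£2,500–£100,000 in £2,500 steps.

## Synthetic input generator

The generator emulates the structure of stratified primary-care database
estimates; its defaults define the study conditions:

- Cohort: 129,396 men (mean entry age 51) and 133,308 women (mean 54),
  262,704 in total, ages discretized from a gamma distribution (shape 4)
  on [30, 100] with the scale solved so the discrete mean matches; counts
  apportioned by largest remainder so totals are exact.
- Incidence: per-condition level at age 30 rising log-linearly with
  age-band midpoint (doubling every 12/10/9/10 years for DM/CHD/STR/CRC),
  with mild male/female ratios (1.2/1.8/1.1/1.2 applied symmetrically);
  independent of conditions already held.
- Mortality: Gompertz-like, 0.0008 at age 30 doubling every 8 years,
  male/female ratio 1.4, multiplied per condition held (DM 1.6, CHD 2.0,
  STR 2.5, CRC 3.5), capped at 0.95.
- Depression prevalence: 0.08 + 0.05 per physical condition, capped at 0.6.
- Costs: £300 base + £1,200 per condition + £600 for depression, inflated
  1.5%/year of band midpoint over 30; sd = 0.8 × mean.
- Utilities: 0.94 at age 30 − 0.0025/year of age − decrements
  (DM 0.06, CHD 0.08, STR 0.12, CRC 0.10, depression 0.15), clipped to
  [0.01, 1]; se defaults to 0.1 · m(1 − m), floored at 1e−4.
- Denominators: proportional to a plausible occupancy share of the band's
  entrants (floor 50), so beta-binomial uncertainty is realistic but
  finite; event counts are the rounded expected counts, making the bundle
  deterministic given its config (an optional `count_noise` flag draws
  them binomially instead).

Per-condition incidence levels are calibrated by iterative proportional
scaling: generate the bundle, run standard care in expected-value mode,
compare crude incidence per 1,000 condition-free person-years with the
targets (DM 6.5, CHD 7.6, STR 4.1, CRC 1.0), and rescale each level by
target/achieved until all are within tolerance (default 5%, typically 3–4
iterations). The packaged default levels are pre-calibrated; re-running
calibration on them is a fixed point. The crude-rate denominator is
person-years free of the specific condition (states not containing it),
applied consistently in calibration, reporting and the acceptance script.

What the generator does not emulate: real stratified estimates have
condition-dependent incidence (comorbidity raises risk), richer age shapes
than log-linear, cost skew beyond a constant coefficient of variation, and
far smaller denominators in rare strata. Consequently the synthetic
uncertainty intervals are much narrower than a real-data analysis would
produce, and passing tests demonstrate correct model mechanics and
calibrated aggregate incidence — not reproduction of the original
database's joint distributions or of headline incremental outcomes that
depend on them.

## Numerical and design notes

- Small strata interact with the Beta(1,1) prior: a stratum with k = 0 and
  n = 50 has expected probability 1/52 regardless of the generating rate.
  Calibration absorbs this at the aggregate level.
- Terminal age band is 90–100 (11 years) to avoid a sparse single-year
  band; bands are the canonical partition 30–39 … 80–89, 90–100.
- Problem sizes: the packaged analyses use the full 262,704-entrant cohort;
  one arm-run takes ~30 ms, so the default 2,000-simulation PSA runs in a
  few minutes and the test suite uses 10–200 simulations.
- Ties and degenerate inputs: NHB at λ ≤ 0 is an error; a cohort with zero
  entrants fails validation; `n_sims < 40` warns that percentile intervals
  are unstable.
- CSV round-trips are exact: floats are written at 17 significant digits
  and parsed with round-trip precision.
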