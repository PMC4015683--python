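"""Age-structured Markov cohort engine.

One call to :func:`run_arm` advances the whole entering cohort (stratified
by sex and single year of age) through annual cycles under one parameter
draw and one scenario (intervention or standard care), and accumulates the
outcomes the economic analysis needs.

Within a cycle the transition out of an alive state is composed as:

1. death with the state's annual mortality probability;
2. conditional on survival, at most one new physical condition is acquired,
   as competing risks over the per-condition annual probabilities (scaled by
   the intervention relative risk when the scenario is active, the cycle is
   within the intervention duration, the origin is the At Risk state and the
   current age is eligible);
3. depression status of the destination is resampled from the destination
   physical state's depression prevalence (depression is reversible).

Quantities are credited with a half-cycle correction: each cycle credits the
trapezoid (average) of start and end occupancy, and cycle t is discounted by
(1 + r)^-(t - 0.5).  The cohort ages one year per cycle; occupancy that
would pass age 100 exits the model after receiving its final-cycle credit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_inputs import (
    AGE_BANDS,
    MAX_AGE,
    MIN_AGE,
    N_AGES,
    SEXES,
    BundleArrays,
    InputBundle,
    band_index,
    bundle_to_arrays,
)
from .sampling import ParameterDraw
from .state_space import (
    CONDITIONS,
    N_ALIVE,
    N_STATES,
    HealthState,
    enumerate_states,
    physical_set_index,
    state_index,
)

__all__ = [
    "Scenario",
    "RunConfig",
    "RunResult",
    "STANDARD_CARE",
    "transition_row",
    "run_arm",
    "crude_incidence",
]


@dataclass(frozen=True)
class Scenario:
    """One comparator arm.

    The base-case intervention runs for five annual cycles at a unit cost of
    one family-practice consultation (£35) per eligible participant-year,
    with eligibility open to the whole 30-100 age range.
    """

    name: str = "intervention"
    rr_active: bool = True
    duration: int = 5
    unit_cost: float = 35.0
    eligible_age: tuple[int, int] = (MIN_AGE, MAX_AGE)
    threshold: float = 30_000.0

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.unit_cost < 0:
            raise ValueError("unit_cost must be non-negative")
        lo, hi = self.eligible_age
        if not (MIN_AGE <= lo <= hi <= MAX_AGE):
            raise ValueError(f"eligible_age {self.eligible_age} outside [30, 100]")


STANDARD_CARE = Scenario(name="standard_care", rr_active=False, unit_cost=0.0)


@dataclass(frozen=True)
class RunConfig:
    """Engine settings.

    70 annual cycles carry a cohort entering at ages 30+ to death or age
    100.  Costs are discounted at 3.5%; QALYs at 3.5% with a 1.5%
    sensitivity.  ``exit_at_max_age=False`` pools occupancy at the terminal
    age instead of exiting, which lets long runs approximate an infinite
    horizon for closed-form checks.
    """

    n_cycles: int = 70
    discount_cost: float = 0.035
    discount_qaly: float = 0.035
    discount_qaly_alt: float = 0.015
    exit_at_max_age: bool = True


@dataclass
class RunResult:
    """Per-arm accumulators for one draw (absolute counts, not per 1,000)."""

    life_years_by_morbidity: dict[int, float]
    life_years_depressed: float
    total_life_years: float
    new_incidences: dict[str, float]
    person_years_free: dict[str, float]
    qaly_3_5: float
    qaly_1_5: float
    cost_intervention: float
    cost_other: float
    n_entered: float
    deaths: float = 0.0
    exits: float = 0.0
    conservation_gap: float = 0.0


# ---------------------------------------------------------------------------
# Static structure tables (canonical state order)
# ---------------------------------------------------------------------------

_STATES = enumerate_states()
_ALIVE = _STATES[:N_ALIVE]
# alive state index -> physical-set index (state i = 2*p + depressed)
_PHYS_OF = np.array([physical_set_index(s.physical) for s in _ALIVE])
_MORB = np.array([len(s.physical) for s in _ALIVE])
_DEPRESSED = np.array([s.depressed for s in _ALIVE])
_HAS_COND = np.array(
    [[c in s.physical for c in CONDITIONS] for s in _ALIVE]
)  # (32, 4)
# physical-set index reached by acquiring condition j from alive state i
_ACQ_DEST = np.full((N_ALIVE, 4), -1, dtype=int)
for _i, _s in enumerate(_ALIVE):
    for _j, _c in enumerate(CONDITIONS):
        if _c not in _s.physical:
            _ACQ_DEST[_i, _j] = physical_set_index(_s.physical | {_c})
_AT_RISK = np.array([len(s.physical) == 0 for s in _ALIVE])  # indices 0, 1
_SEX_IDX = {s: i for i, s in enumerate(SEXES)}
_BAND_OF_AGE = np.array([band_index(a) for a in range(MIN_AGE, MAX_AGE + 1)])


def _build_matrix(draw: ParameterDraw, band_i: int, sex_i: int,
                  rr_applied: bool) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix (32 alive rows x 33 columns, Death last) and the
    (32, 4) matrix of per-cycle flows into each condition's states."""
    inc = draw.incidence_p[:, :, band_i, sex_i]  # (32, 4), NaN where held
    p_death = draw.mortality_p[:, band_i, sex_i]  # (32,)
    prev = draw.depression_prev[:, band_i, sex_i]  # (16,)

    M = np.zeros((N_ALIVE, N_STATES))
    inc_flow = np.zeros((N_ALIVE, 4))
    for i in range(N_ALIVE):
        surv = 1.0 - p_death[i]
        M[i, N_ALIVE] = p_death[i]
        q = inc[i].copy()
        if rr_applied and _AT_RISK[i]:
            q = q * draw.rr[:, band_i]
        q = np.where(np.isnan(q), 0.0, q)
        total = q.sum()
        if total > 1.0:
            warnings.warn(
                f"competing incidence probabilities sum to {total:.3f} > 1 "
                f"for state {_ALIVE[i].label}; renormalizing",
                RuntimeWarning,
            )
            q /= total
            total = 1.0
        for j in range(4):
            if q[j] <= 0.0:
                continue
            dest_p = _ACQ_DEST[i, j]
            mass = surv * q[j]
            M[i, 2 * dest_p + 1] += mass * prev[dest_p]
            M[i, 2 * dest_p] += mass * (1.0 - prev[dest_p])
            inc_flow[i, j] = mass
        stay_p = _PHYS_OF[i]
        stay_mass = surv * (1.0 - total)
        M[i, 2 * stay_p + 1] += stay_mass * prev[stay_p]
        M[i, 2 * stay_p] += stay_mass * (1.0 - prev[stay_p])
    return M, inc_flow


def transition_row(
    draw: ParameterDraw,
    state: HealthState,
    age: int,
    sex: str | int,
    scenario: Scenario,
    cycle: int,
) -> np.ndarray:
    """One row of the transition matrix for ``state`` at the given age, sex,
    scenario and cycle (1-based).  Sums to 1 to machine precision."""
    if state.is_death:
        row = np.zeros(N_STATES)
        row[N_ALIVE] = 1.0
        return row
    if not (MIN_AGE <= age <= MAX_AGE):
        raise ValueError(f"age {age} outside [30, 100]")
    sex_i = _SEX_IDX[sex] if isinstance(sex, str) else int(sex)
    band_i = band_index(age)
    lo, hi = scenario.eligible_age
    rr_applied = (
        scenario.rr_active and cycle <= scenario.duration and lo <= age <= hi
    )
    M, _ = _build_matrix(draw, band_i, sex_i, rr_applied)
    return M[state_index(state)]


def run_arm(
    draw: ParameterDraw,
    bundle: InputBundle | BundleArrays,
    scenario: Scenario,
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Advance the cohort through ``config.n_cycles`` annual cycles under
    one parameter draw and accumulate outcomes.

    The cohort enters in the At Risk non-depressed state at its recorded
    entry ages.  Occupancy is conserved: alive + cumulative deaths +
    cumulative age-100 exits equals the entrants, checked at the end of the
    run and recorded in ``conservation_gap``.
    """
    arrays = bundle if isinstance(bundle, BundleArrays) else bundle_to_arrays(bundle)
    occ = np.zeros((2, N_AGES, N_ALIVE))
    occ[:, :, 0] = arrays.cohort.T  # everyone starts At Risk, not depressed
    n_entered = float(arrays.cohort.sum())

    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    lo, hi = scenario.eligible_age
    eligible = (ages >= lo) & (ages <= hi)

    # per-age lookup tables for valuation
    util_by_age = draw.utility.T  # (71, 32)
    cost_by_age = np.stack(
        [draw.cost[:, _BAND_OF_AGE, s].T for s in range(2)]
    )  # (2, 71, 32)

    matrices: dict[tuple[int, int, bool], tuple[np.ndarray, np.ndarray]] = {}

    def get_matrix(sex_i: int, band_i: int, rr_applied: bool):
        key = (sex_i, band_i, rr_applied)
        if key not in matrices:
            matrices[key] = _build_matrix(draw, band_i, sex_i, rr_applied)
        return matrices[key]

    ly_morb = np.zeros(5)
    ly_dep = 0.0
    new_inc = np.zeros(4)
    py_free = np.zeros(4)
    qaly = np.zeros(2)  # primary, alternative discount rate
    cost_other = 0.0
    cost_intervention = 0.0
    deaths = 0.0
    exits = 0.0

    for t in range(1, config.n_cycles + 1):
        df_cost = (1.0 + config.discount_cost) ** -(t - 0.5)
        df_q = (1.0 + config.discount_qaly) ** -(t - 0.5)
        df_q_alt = (1.0 + config.discount_qaly_alt) ** -(t - 0.5)
        rr_cycle = scenario.rr_active and t <= scenario.duration
        charge_cycle = scenario.unit_cost > 0 and t <= scenario.duration

        credit = np.zeros((2, N_AGES, N_ALIVE))
        exposure = 0.0

        for sex_i in range(2):
            occ_s = occ[sex_i]
            new_occ = np.zeros_like(occ_s)
            active = np.flatnonzero(occ_s.sum(axis=1) > 0)
            if active.size == 0:
                occ[sex_i] = new_occ
                continue
            for band_i in range(len(AGE_BANDS)):
                in_band = active[_BAND_OF_AGE[active] == band_i]
                if in_band.size == 0:
                    continue
                for rr_flag in (False, True):
                    if rr_cycle:
                        sel = in_band[eligible[in_band] == rr_flag]
                    else:
                        sel = in_band if not rr_flag else in_band[:0]
                    if sel.size == 0:
                        continue
                    M, inc_flow = get_matrix(sex_i, band_i, rr_flag)
                    start = occ_s[sel]  # (g, 32)
                    flow = start @ M    # (g, 33)
                    alive_flow = flow[:, :N_ALIVE]
                    deaths += float(flow[:, N_ALIVE].sum())
                    new_inc += (start @ inc_flow).sum(axis=0)
                    # half-cycle credit: half at the start age, half at the
                    # (clamped) end age
                    credit[sex_i, sel] += 0.5 * start
                    end_ages = np.minimum(sel + 1, N_AGES - 1)
                    np.add.at(credit[sex_i], end_ages, 0.5 * alive_flow)
                    if charge_cycle:
                        elig_sel = eligible[sel]
                        if elig_sel.any():
                            at_risk_start = start[elig_sel][:, :2].sum()
                            at_risk_end = alive_flow[elig_sel][:, :2].sum()
                            exposure += 0.5 * (at_risk_start + at_risk_end)
                    # advance ages; the top age either exits or pools
                    past_end = sel + 1 > N_AGES - 1
                    interior = ~past_end
                    if interior.any():
                        np.add.at(new_occ, sel[interior] + 1, alive_flow[interior])
                    if past_end.any():
                        if config.exit_at_max_age:
                            exits += float(alive_flow[past_end].sum())
                        else:
                            new_occ[N_AGES - 1] += alive_flow[past_end].sum(axis=0)
            occ[sex_i] = new_occ

        total_credit = credit.sum(axis=0)  # (71, 32)
        q_t = float(np.einsum("as,as->", total_credit, util_by_age))
        qaly[0] += q_t * df_q
        qaly[1] += q_t * df_q_alt
        cost_other += float(np.einsum("xas,xas->", credit, cost_by_age)) * df_cost
        ly_t = total_credit.sum(axis=0)  # (32,) per-state credited years
        for m in range(5):
            ly_morb[m] += float(ly_t[_MORB == m].sum())
        ly_dep += float(ly_t[_DEPRESSED].sum())
        py_free += np.array(
            [float(ly_t[~_HAS_COND[:, j]].sum()) for j in range(4)]
        )
        if charge_cycle:
            cost_intervention += scenario.unit_cost * exposure * df_cost

    alive_left = float(occ.sum())
    gap = alive_left + deaths + exits - n_entered
    if abs(gap) > 1e-9 * max(n_entered, 1.0):
        warnings.warn(
            f"occupancy conservation gap {gap:.3e} for {n_entered} entrants",
            RuntimeWarning,
        )

    cond_codes = [c.value for c in CONDITIONS]
    return RunResult(
        life_years_by_morbidity={m: float(ly_morb[m]) for m in range(5)},
        life_years_depressed=float(ly_dep),
        total_life_years=float(ly_morb.sum()),
        new_incidences=dict(zip(cond_codes, map(float, new_inc))),
        person_years_free=dict(zip(cond_codes, map(float, py_free))),
        qaly_3_5=float(qaly[0]),
        qaly_1_5=float(qaly[1]),
        cost_intervention=float(cost_intervention),
        cost_other=float(cost_other),
        n_entered=n_entered,
        deaths=deaths,
        exits=exits,
        conservation_gap=gap,
    )


def crude_incidence(
    result: RunResult,
    person_years_at_risk: float | dict[str, float] | None = None,
) -> dict[str, float]:
    """Crude incidence per 1,000 condition-free person-years.

    By default each condition's denominator is the person-years spent in
    states not containing that condition, as accumulated by the run; a
    scalar or per-condition override may be supplied.
    """
    rates = {}
    for c in CONDITIONS:
        code = c.value
        if person_years_at_risk is None:
            py = result.person_years_free[code]
        elif isinstance(person_years_at_risk, dict):
            py = person_years_at_risk[code]
        else:
            py = float(person_years_at_risk)
        if py <= 0:
            raise ZeroDivisionError(f"no person-years at risk for {code}")
        rates[code] = 1000.0 * result.new_incidences[code] / py
    return rates
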