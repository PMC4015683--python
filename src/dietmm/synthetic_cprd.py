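"""Synthetic primary-care input generator.

Real parameterizations of the model come from stratified analyses of a
primary-care research database (incidence, mortality, depression prevalence,
costs and utilities per state, 10-year age band and sex), which are not
redistributable.  This module generates a complete, internally consistent
:class:`~dietmm.model_inputs.InputBundle` with the qualitative structure
such an analysis produces:

* incidence of each condition rises log-linearly with age-band midpoint;
* all-cause mortality follows a Gompertz-like doubling with age and is
  multiplied up for each condition held;
* depression prevalence is elevated in disease states (base + increment per
  condition, capped);
* annual costs rise with morbidity count, depression and age, with the
  standard deviation a fixed coefficient of variation times the mean;
* utilities decline with age, morbidity and depression;
* the entering cohort follows a discretized gamma age distribution matched
  to the configured sex-specific totals and mean ages.

The per-condition incidence levels are calibrated so that a standard-care
run of the model in expected-value mode reproduces configured crude
incidence rates per 1,000 condition-free person-years
(:func:`calibrate_crude_incidence`).  The packaged defaults are already
calibrated to the rates the model is benchmarked against (diabetes 6.5,
coronary heart disease 7.6, stroke 4.1, colorectal cancer 1.0 per 1,000).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_inputs import (
    AGE_BANDS,
    MAX_AGE,
    MIN_AGE,
    SEXES,
    InputBundle,
)
from .markov_engine import STANDARD_CARE, RunConfig, crude_incidence, run_arm
from .sampling import EffectModel, draw_parameters
from .state_space import CONDITIONS, HealthState, enumerate_states, physical_sets

__all__ = [
    "SyntheticConfig",
    "CalibrationError",
    "default_config",
    "generate_cohort",
    "generate_bundle",
    "calibrate_crude_incidence",
]

_CODES = tuple(c.value for c in CONDITIONS)

#: Incidence levels (annual probability at age 30, both sexes combined)
#: calibrated so the default model world reproduces the benchmark crude
#: rates under standard care in expected-value mode.
_CALIBRATED_LEVELS = {
    "DM": 0.0006617493460876868,
    "CHD": 0.00047088363626349345,
    "STR": 0.00015831950273159588,
    "CRC": 2.0227053316867134e-05,
}


@dataclass
class SyntheticConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 1
    n_men: int = 129_396
    n_women: int = 133_308
    mean_age_men: float = 51.0
    mean_age_women: float = 54.0
    age_shape: float = 4.0  # gamma shape of the (age - 30) entry distribution

    crude_incidence_targets: dict[str, float] = field(
        default_factory=lambda: {"DM": 6.5, "CHD": 7.6, "STR": 4.1, "CRC": 1.0}
    )
    incidence_level: dict[str, float] = field(
        default_factory=lambda: dict(_CALIBRATED_LEVELS)
    )
    incidence_doubling_years: dict[str, float] = field(
        default_factory=lambda: {"DM": 12.0, "CHD": 10.0, "STR": 9.0, "CRC": 10.0}
    )
    incidence_sex_ratio: dict[str, float] = field(
        default_factory=lambda: {"DM": 1.2, "CHD": 1.8, "STR": 1.1, "CRC": 1.2}
    )

    base_mortality_30: float = 0.0008
    mortality_doubling_years: float = 8.0
    mortality_sex_ratio: float = 1.4
    condition_mortality_multipliers: dict[str, float] = field(
        default_factory=lambda: {"DM": 1.6, "CHD": 2.0, "STR": 2.5, "CRC": 3.5}
    )

    depression_base_prevalence: float = 0.08
    depression_morbidity_increment: float = 0.05
    depression_cap: float = 0.6

    cost_base: float = 300.0
    cost_per_condition: float = 1200.0
    cost_depression: float = 600.0
    cost_age_rate: float = 0.015  # proportional inflation per year over 30
    cost_cv: float = 0.8

    utility_base: float = 0.94
    utility_age_slope: float = 0.0025
    utility_decrements: dict[str, float] = field(
        default_factory=lambda: {"DM": 0.06, "CHD": 0.08, "STR": 0.12, "CRC": 0.10}
    )
    utility_depression_decrement: float = 0.15

    denominator_scale: float = 1.0
    count_noise: bool = False  # binomially sample event counts if True

    def validate(self) -> None:
        if self.n_men < 0 or self.n_women < 0 or self.n_men + self.n_women <= 0:
            raise ValueError("cohort totals must be non-negative with a positive sum")
        for mean, n in ((self.mean_age_men, self.n_men),
                        (self.mean_age_women, self.n_women)):
            if n > 0 and not (MIN_AGE < mean < MAX_AGE):
                raise ValueError(f"mean entry age {mean} outside ({MIN_AGE}, {MAX_AGE})")
        for c in _CODES:
            if self.crude_incidence_targets.get(c, 0) <= 0:
                raise ValueError(f"crude incidence target for {c} must be positive")
            if self.incidence_level.get(c, 0) <= 0:
                raise ValueError(f"incidence level for {c} must be positive")
        if not (0 < self.base_mortality_30 < 1):
            raise ValueError("base_mortality_30 must be a probability in (0, 1)")
        if not (0 <= self.depression_base_prevalence < 1):
            raise ValueError("depression_base_prevalence must lie in [0, 1)")


def default_config(seed: int = 1) -> SyntheticConfig:
    """The packaged, calibrated default configuration."""
    return SyntheticConfig(seed=seed)


class CalibrationError(RuntimeError):
    def __init__(self, achieved: dict[str, float], targets: dict[str, float]):
        self.achieved = achieved
        self.targets = targets
        detail = ", ".join(
            f"{c}: {achieved[c]:.3f} vs target {targets[c]:.3f}" for c in achieved
        )
        super().__init__(f"crude-incidence calibration did not converge ({detail})")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _age_weights(mean_age: float, shape: float) -> np.ndarray:
    """Discretized gamma weights over single years of age 30..100 whose
    discrete truncated mean equals ``mean_age``."""
    ages = np.arange(MIN_AGE, MAX_AGE + 1)

    def discrete_mean(scale: float) -> float:
        dist = stats.gamma(shape, scale=scale)
        w = dist.cdf(ages - MIN_AGE + 1) - dist.cdf(ages - MIN_AGE)
        w = w / w.sum()
        return float((ages * w).sum())

    target = mean_age
    lo, hi = 1e-3, 60.0
    scale = optimize.brentq(lambda s: discrete_mean(s) - target, lo, hi, xtol=1e-10)
    dist = stats.gamma(shape, scale=scale)
    w = dist.cdf(ages - MIN_AGE + 1) - dist.cdf(ages - MIN_AGE)
    return w / w.sum()


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` across weights deterministically, exactly."""
    raw = weights * total
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Entry counts per (single year of age, sex).

    Totals equal the configured counts exactly; the age distribution is a
    discretized gamma on [30, 100] with the configured sex-specific mean.
    """
    config.validate()
    rows = []
    ages = np.arange(MIN_AGE, MAX_AGE + 1)
    for sex, n, mean in (
        ("M", config.n_men, config.mean_age_men),
        ("F", config.n_women, config.mean_age_women),
    ):
        if n == 0:
            counts = np.zeros(len(ages), dtype=int)
        else:
            counts = _largest_remainder(_age_weights(mean, config.age_shape), n)
        for age, count in zip(ages, counts):
            rows.append({"age": int(age), "sex": sex, "count": int(count)})
    return pd.DataFrame(rows, columns=["age", "sex", "count"])


# ---------------------------------------------------------------------------
# Probability surfaces (exposed for property checks)
# ---------------------------------------------------------------------------

def incidence_probability(config: SyntheticConfig, condition: str,
                          band_mid: float, sex: str) -> float:
    ratio = config.incidence_sex_ratio[condition]
    sex_factor = math.sqrt(ratio) if sex == "M" else 1.0 / math.sqrt(ratio)
    p = (
        config.incidence_level[condition]
        * 2.0 ** ((band_mid - MIN_AGE) / config.incidence_doubling_years[condition])
        * sex_factor
    )
    return float(min(max(p, 1e-7), 0.5))


def mortality_probability(config: SyntheticConfig, state: HealthState,
                          band_mid: float, sex: str) -> float:
    sex_factor = (math.sqrt(config.mortality_sex_ratio) if sex == "M"
                  else 1.0 / math.sqrt(config.mortality_sex_ratio))
    p = (
        config.base_mortality_30
        * 2.0 ** ((band_mid - MIN_AGE) / config.mortality_doubling_years)
        * sex_factor
    )
    for c in state.physical:
        p *= config.condition_mortality_multipliers[c.value]
    return float(min(p, 0.95))


def depression_prevalence(config: SyntheticConfig, morbidity: int) -> float:
    p = config.depression_base_prevalence + config.depression_morbidity_increment * morbidity
    return float(min(p, config.depression_cap))


def cost_mean(config: SyntheticConfig, state: HealthState, band_mid: float) -> float:
    base = (
        config.cost_base
        + config.cost_per_condition * len(state.physical)
        + (config.cost_depression if state.depressed else 0.0)
    )
    return float(base * (1.0 + config.cost_age_rate * (band_mid - MIN_AGE)))


def utility_mean(config: SyntheticConfig, state: HealthState, age: int) -> float:
    u = config.utility_base - config.utility_age_slope * (age - MIN_AGE)
    for c in state.physical:
        u -= config.utility_decrements[c.value]
    if state.depressed:
        u -= config.utility_depression_decrement
    return float(min(max(u, 0.01), 1.0))


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

def _occupancy_weight(state: HealthState) -> float:
    # plausible database stratum sizes: most person-time is disease-free
    w = 0.8 * 0.08 ** len(state.physical)
    return w * (0.15 if state.depressed else 0.85)


def generate_bundle(config: SyntheticConfig) -> InputBundle:
    """A full-coverage, validated input bundle under ``config``.

    Event counts are the rounded expected counts by default (deterministic
    given the config), or binomial draws seeded by ``config.seed`` when
    ``count_noise`` is set.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if config.count_noise else None
    cohort = generate_cohort(config)

    band_totals = {}
    for (lo, hi) in AGE_BANDS:
        sel = (cohort["age"] >= lo) & (cohort["age"] <= hi)
        for sex in SEXES:
            band_totals[(lo, hi), sex] = int(
                cohort.loc[sel & (cohort["sex"] == sex), "count"].sum()
            )

    alive = [s for s in enumerate_states() if not s.is_death]

    def denominator(state: HealthState, band, sex) -> int:
        n = _occupancy_weight(state) * band_totals[band, sex] * config.denominator_scale
        return max(50, int(round(n)))

    def events(p: float, n: int) -> int:
        if rng is not None:
            return int(rng.binomial(n, p))
        return int(round(p * n))

    inc_rows, mort_rows, dep_rows, cost_rows = [], [], [], []
    for band in AGE_BANDS:
        mid = (band[0] + band[1]) / 2.0
        for sex in SEXES:
            for state in alive:
                n = denominator(state, band, sex)
                for c in CONDITIONS:
                    if c in state.physical:
                        continue
                    p = incidence_probability(config, c.value, mid, sex)
                    inc_rows.append({
                        "state": state.label, "condition": c.value,
                        "age_lower": band[0], "age_upper": band[1], "sex": sex,
                        "events": events(p, n), "denominator": n,
                    })
                mort_rows.append({
                    "state": state.label,
                    "age_lower": band[0], "age_upper": band[1], "sex": sex,
                    "events": events(mortality_probability(config, state, mid, sex), n),
                    "denominator": n,
                })
                cost_rows.append({
                    "state": state.label,
                    "age_lower": band[0], "age_upper": band[1], "sex": sex,
                    "mean": cost_mean(config, state, mid),
                    "sd": config.cost_cv * cost_mean(config, state, mid),
                })
            for phys in physical_sets():
                state = HealthState(physical=phys)
                n = denominator(state, band, sex)
                p = depression_prevalence(config, len(phys))
                dep_rows.append({
                    "state": state.label,
                    "age_lower": band[0], "age_upper": band[1], "sex": sex,
                    "events": events(p, n), "denominator": n,
                })

    util_rows = []
    for state in alive:
        for age in range(MIN_AGE, MAX_AGE + 1):
            m = utility_mean(config, state, age)
            se = 0.1 * m * (1.0 - m)
            if 0.0 < m < 1.0:
                se = max(se, 1e-4)
            util_rows.append({"state": state.label, "age": age, "mean": m, "se": se})

    bundle = InputBundle(
        incidence=pd.DataFrame(inc_rows),
        mortality=pd.DataFrame(mort_rows),
        depression=pd.DataFrame(dep_rows),
        costs=pd.DataFrame(cost_rows),
        utilities=pd.DataFrame(util_rows),
        cohort=cohort,
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def standard_care_crude_rates(config: SyntheticConfig,
                              config_run: RunConfig = RunConfig()) -> dict[str, float]:
    """Crude incidence per 1,000 condition-free person-years of a
    standard-care, expected-value run of the generated bundle."""
    bundle = generate_bundle(config)
    draw = draw_parameters(bundle, EffectModel.default(), expected=True)
    result = run_arm(draw, bundle, STANDARD_CARE, config_run)
    return crude_incidence(result)


def calibrate_crude_incidence(
    config: SyntheticConfig,
    tolerance: float = 0.05,
    max_iter: int = 12,
) -> SyntheticConfig:
    """Scale per-condition incidence levels until the standard-care crude
    rates match ``config.crude_incidence_targets`` within ``tolerance``
    (relative), by iterative proportional fitting.

    Returns a new config; the input is not modified.  Raises
    :class:`CalibrationError` with achieved-vs-target diagnostics if the
    iteration cap is reached.
    """
    config.validate()
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    cfg = dataclasses.replace(config, incidence_level=dict(config.incidence_level))
    targets = cfg.crude_incidence_targets
    achieved: dict[str, float] = {}
    for _ in range(max_iter):
        achieved = standard_care_crude_rates(cfg)
        if all(abs(achieved[c] / targets[c] - 1.0) <= tolerance for c in _CODES):
            return cfg
        cfg = dataclasses.replace(
            cfg,
            incidence_level={
                c: cfg.incidence_level[c] * targets[c] / achieved[c] for c in _CODES
            },
        )
    raise CalibrationError(achieved, dict(targets))
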