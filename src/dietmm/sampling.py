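"""Probabilistic sensitivity analysis samplers.

One :class:`ParameterDraw` is one joint realization of every uncertain model
input: annual transition probabilities drawn from beta posteriors of
event/denominator counts (beta-binomial sampling with a uniform Beta(1, 1)
prior, so zero-event strata remain sampleable), state costs drawn from
method-of-moments gamma distributions, utilities from method-of-moments beta
distributions, and intervention relative risks.

Every sampler also has a deterministic expected-value mode returning its
analytic mean: probabilities (k+1)/(n+2), costs and utilities their input
means.  Expected-value draws drive calibration and closed-form oracle tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model_inputs import BundleArrays, InputBundle, N_BANDS, bundle_to_arrays
from .state_space import CONDITIONS

__all__ = [
    "EffectModel",
    "ParameterDraw",
    "sample_probability",
    "sample_cost",
    "sample_utility",
    "sample_intervention_rr",
    "draw_parameters",
]


# ---------------------------------------------------------------------------
# Scalar samplers (the contracts); vectorized forms below reuse the same math.
# ---------------------------------------------------------------------------

def sample_probability(k: int, n: int, rng: np.random.Generator) -> float:
    """Annual probability drawn from the Beta(k+1, n-k+1) posterior of
    ``k`` events among ``n`` at risk."""
    if n < 1 or k < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    return float(rng.beta(k + 1, n - k + 1))


def sample_cost(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Annual cost drawn from a gamma distribution with the given moments.

    Shape (mean/sd)^2 and scale sd^2/mean by method of moments; degenerate
    (mean or sd zero) inputs are returned as-is.
    """
    if mean < 0 or sd < 0:
        raise ValueError("cost mean and sd must be non-negative")
    if mean == 0 or sd == 0:
        return float(mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def sample_utility(mean: float, se: float, rng: np.random.Generator) -> float:
    """Utility drawn from a beta distribution with the given moments.

    Method of moments: nu = mean(1-mean)/se^2 - 1, alpha = mean*nu,
    beta = (1-mean)*nu.  se = 0 returns the mean exactly.
    """
    if se < 0:
        raise ValueError("utility se must be non-negative")
    if se == 0:
        return float(mean)
    if not (0 < mean < 1):
        raise ValueError("utility mean must lie in (0, 1) when se > 0")
    if se * se >= mean * (1 - mean):
        raise ValueError(
            f"infeasible beta moments: se^2={se * se:.4g} >= "
            f"mean(1-mean)={mean * (1 - mean):.4g}"
        )
    nu = mean * (1 - mean) / (se * se) - 1
    return float(rng.beta(mean * nu, (1 - mean) * nu))


# ---------------------------------------------------------------------------
# Intervention effect
# ---------------------------------------------------------------------------

_COND_CODES = tuple(c.value for c in CONDITIONS)


@dataclass
class EffectModel:
    """How the dietary intervention modifies incidence in the At Risk state.

    mode "fixed_rr" applies the configured per-condition relative risks
    deterministically in every draw (the default, using the published
    simulation means).  mode "portion_sampled" draws the fruit-and-vegetable
    increment d ~ Normal(portion_mean, se) truncated at zero, with se derived
    from the 95% CI, and applies RR(c) = per_portion_rr(c) ** d.
    """

    mode: str = "fixed_rr"
    fixed_rr: dict[str, float] = field(
        default_factory=lambda: {"DM": 0.965, "CHD": 0.959, "STR": 0.975, "CRC": 0.997}
    )
    portion_mean: float = 0.5
    portion_ci: tuple[float, float] = (0.13, 0.87)
    per_portion_rr: dict[str, float | list[float]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_rr", "portion_sampled"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        lo, hi = self.portion_ci
        if not (lo <= self.portion_mean <= hi):
            raise ValueError("portion_ci must bracket portion_mean")
        if self.mode == "portion_sampled":
            if self.per_portion_rr is None:
                # squaring the fixed 0.5-portion RRs gives a coherent
                # 1-portion/day per-increment default
                self.per_portion_rr = {c: rr ** 2 for c, rr in self.fixed_rr.items()}
            missing = [c for c in _COND_CODES if c not in self.per_portion_rr]
            if missing:
                raise ValueError(f"per_portion_rr missing condition(s) {missing}")
        for c, rr in self.fixed_rr.items():
            if not (0 < rr <= 1.5):
                raise ValueError(f"fixed_rr[{c}]={rr} outside (0, 1.5]")

    @property
    def portion_se(self) -> float:
        lo, hi = self.portion_ci
        return (hi - lo) / (2 * 1.959963984540054)

    def fixed_rr_array(self) -> np.ndarray:
        """(4, 7) fixed relative risks, identical across bands and sexes."""
        rr = np.array([self.fixed_rr[c] for c in _COND_CODES])
        return np.repeat(rr[:, None], N_BANDS, axis=1)

    def per_portion_rr_array(self) -> np.ndarray:
        out = np.empty((4, N_BANDS))
        for j, c in enumerate(_COND_CODES):
            v = np.asarray(self.per_portion_rr[c], dtype=float)
            out[j] = v if v.ndim else np.full(N_BANDS, float(v))
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EffectModel":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "portion_ci" in raw:
            raw["portion_ci"] = tuple(raw["portion_ci"])
        return cls(**raw)

    @classmethod
    def default(cls) -> "EffectModel":
        """The packaged default effect configuration."""
        ref = importlib.resources.files("dietmm.data") / "effect_default.yaml"
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)


def sample_intervention_rr(
    effect: EffectModel,
    rng: np.random.Generator | None = None,
    portion: float | None = None,
) -> np.ndarray:
    """One draw of the (condition, band) relative-risk matrix.

    In "fixed_rr" mode the configured values are returned without
    randomness.  In "portion_sampled" mode the daily portion increment d is
    drawn (or forced via ``portion``) and each per-portion RR is raised to
    the power d.
    """
    if effect.mode == "fixed_rr":
        return effect.fixed_rr_array()
    if portion is None:
        if rng is None:
            raise ValueError("portion_sampled mode requires an rng or a forced portion")
        d = -1.0
        while d < 0:  # truncate the normal at zero
            d = float(rng.normal(effect.portion_mean, effect.portion_se))
    else:
        d = float(portion)
    return effect.per_portion_rr_array() ** d


# ---------------------------------------------------------------------------
# Joint draw
# ---------------------------------------------------------------------------

@dataclass
class ParameterDraw:
    """One joint realization of all model parameters.

    Arrays follow the conventions of :class:`BundleArrays`; incidence cells
    for conditions already present in the origin state are NaN.
    """

    incidence_p: np.ndarray      # (32, 4, 7, 2)
    mortality_p: np.ndarray      # (32, 7, 2)
    depression_prev: np.ndarray  # (16, 7, 2)
    cost: np.ndarray             # (32, 7, 2)
    utility: np.ndarray          # (32, 71)
    rr: np.ndarray               # (4, 7)


def _beta_counts(k: np.ndarray, n: np.ndarray, rng: np.random.Generator,
                 expected: bool) -> np.ndarray:
    mask = np.isnan(n)
    k = np.where(mask, 0.0, k)
    n = np.where(mask, 1.0, n)
    if expected:
        out = (k + 1) / (n + 2)
    else:
        out = rng.beta(k + 1, n - k + 1)
    return np.where(mask, np.nan, out)


def _gamma_moments(mean: np.ndarray, sd: np.ndarray, rng: np.random.Generator,
                   expected: bool) -> np.ndarray:
    if expected:
        return mean.copy()
    degenerate = (mean == 0) | (sd == 0)
    m = np.where(degenerate, 1.0, mean)
    s = np.where(degenerate, 1.0, sd)
    draws = rng.gamma((m / s) ** 2, s * s / m)
    return np.where(degenerate, mean, draws)


def _beta_moments(mean: np.ndarray, se: np.ndarray, rng: np.random.Generator,
                  expected: bool) -> np.ndarray:
    if expected:
        return mean.copy()
    degenerate = se == 0
    m = np.where(degenerate, 0.5, mean)
    s = np.where(degenerate, 0.1, se)
    if np.any((~degenerate) & ((mean <= 0) | (mean >= 1))):
        raise ValueError("utility means must lie in (0, 1) where se > 0")
    if np.any((~degenerate) & (se * se >= mean * (1 - mean))):
        raise ValueError("infeasible beta moments in utility table")
    nu = m * (1 - m) / (s * s) - 1
    draws = rng.beta(m * nu, (1 - m) * nu)
    return np.where(degenerate, mean, draws)


def draw_parameters(
    bundle: InputBundle | BundleArrays,
    effect: EffectModel,
    rng: np.random.Generator | None = None,
    expected: bool = False,
) -> ParameterDraw:
    """Draw one coherent :class:`ParameterDraw` covering every stratum.

    ``expected=True`` returns the analytic means of every sampler instead
    of random draws (no rng needed).
    """
    arrays = bundle if isinstance(bundle, BundleArrays) else bundle_to_arrays(bundle)
    if not expected and rng is None:
        raise ValueError("random draws require an rng; pass expected=True otherwise")
    if expected:
        rr = (effect.fixed_rr_array() if effect.mode == "fixed_rr"
              else sample_intervention_rr(effect, portion=effect.portion_mean))
    else:
        rr = sample_intervention_rr(effect, rng)
    return ParameterDraw(
        incidence_p=_beta_counts(arrays.inc_k, arrays.inc_n, rng, expected),
        mortality_p=_beta_counts(arrays.mort_k, arrays.mort_n, rng, expected),
        depression_prev=_beta_counts(arrays.dep_k, arrays.dep_n, rng, expected),
        cost=_gamma_moments(arrays.cost_mean, arrays.cost_sd, rng, expected),
        utility=_beta_moments(arrays.util_mean, arrays.util_se, rng, expected),
        rr=rr,
    )
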