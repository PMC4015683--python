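"""Stratified input tables that parameterize one model world.

The model consumes six delimited tables, mirroring the stratified estimates
a primary-care database analysis would produce:

========================  =====================================================
incidence.csv             event/denominator counts per (origin state, incident
                          condition, 10-year age band, sex)
mortality.csv             death/denominator counts per (state, age band, sex)
depression.csv            depressed/denominator counts per (physical state,
                          age band, sex)
costs.csv                 annual health-care cost mean and SD (GBP) per
                          (state, age band, sex)
utilities.csv             utility mean and standard error per (state, single
                          year of age); identical for men and women
cohort.csv                number of entrants per (single year of age, sex);
                          all entrants start healthy (At Risk, not depressed)
========================  =====================================================

All files are comma-separated UTF-8 with a mandatory header row.  Event and
denominator counts are persons experiencing the event over persons at risk
during one year, feeding beta-binomial sampling directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .state_space import (
    CONDITIONS,
    N_ALIVE,
    Condition,
    enumerate_states,
    physical_set_index,
    physical_sets,
    state_from_label,
    state_index,
    HealthState,
)

__all__ = [
    "AGE_BANDS",
    "SEXES",
    "MIN_AGE",
    "MAX_AGE",
    "band_for_age",
    "band_index",
    "InputBundle",
    "BundleValidationError",
    "read_bundle",
    "write_bundle",
    "BundleArrays",
    "bundle_to_arrays",
]

MIN_AGE = 30
MAX_AGE = 100

#: Canonical 10-year age bands; the terminal band spans 90-100.
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
    (80, 89),
    (90, 100),
)

SEXES: tuple[str, str] = ("M", "F")

N_BANDS = len(AGE_BANDS)
N_AGES = MAX_AGE - MIN_AGE + 1  # single years 30..100

FILE_NAMES = {
    "incidence": "incidence.csv",
    "mortality": "mortality.csv",
    "depression": "depression.csv",
    "costs": "costs.csv",
    "utilities": "utilities.csv",
    "cohort": "cohort.csv",
}

_COLUMNS = {
    "incidence": ["state", "condition", "age_lower", "age_upper", "sex", "events", "denominator"],
    "mortality": ["state", "age_lower", "age_upper", "sex", "events", "denominator"],
    "depression": ["state", "age_lower", "age_upper", "sex", "events", "denominator"],
    "costs": ["state", "age_lower", "age_upper", "sex", "mean", "sd"],
    "utilities": ["state", "age", "mean", "se"],
    "cohort": ["age", "sex", "count"],
}


def band_for_age(age: int) -> tuple[int, int]:
    """The unique 10-year band containing ``age``; ages 90-100 share the
    terminal band.  Raises for ages outside the model's 30-100 range."""
    if not (MIN_AGE <= age <= MAX_AGE):
        raise ValueError(f"age {age} outside model range [{MIN_AGE}, {MAX_AGE}]")
    for band in AGE_BANDS:
        if band[0] <= age <= band[1]:
            return band
    raise AssertionError("unreachable: bands partition the age range")


def band_index(age: int) -> int:
    """Index of the band containing ``age`` in [0, 6]."""
    return AGE_BANDS.index(band_for_age(age))


class BundleValidationError(ValueError):
    """Raised with the complete list of validation violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:25])
        more = "" if len(self.errors) <= 25 else f"\n  ... and {len(self.errors) - 25} more"
        super().__init__(f"{len(self.errors)} input validation error(s):\n  {preview}{more}")


@dataclass
class InputBundle:
    """The complete set of stratified tables for one model world."""

    incidence: pd.DataFrame
    mortality: pd.DataFrame
    depression: pd.DataFrame
    costs: pd.DataFrame
    utilities: pd.DataFrame
    cohort: pd.DataFrame

    def validate(self) -> None:
        """Check schemas, ranges and complete stratum coverage.

        Collects every violation before raising, so a malformed bundle is
        diagnosed in a single pass.
        """
        errors: list[str] = []
        for name in FILE_NAMES:
            df = getattr(self, name)
            missing = [c for c in _COLUMNS[name] if c not in df.columns]
            if missing:
                errors.append(f"{name}: missing column(s) {missing}")
        if errors:
            raise BundleValidationError(errors)

        alive = [s for s in enumerate_states() if not s.is_death]
        alive_labels = {s.label for s in alive}
        physical_labels = {
            HealthState(physical=p).label for p in physical_sets()
        }

        def check_label(table: str, row_id, label: str, allowed: set[str]) -> bool:
            if label not in allowed:
                errors.append(f"{table}[{row_id}]: unknown state label {label!r}")
                return False
            return True

        def check_counts(table: str, df: pd.DataFrame) -> None:
            for idx, row in df.iterrows():
                k, n = row["events"], row["denominator"]
                if n < 1:
                    errors.append(f"{table}[{idx}]: denominator {n} < 1")
                if k < 0 or k > n:
                    errors.append(f"{table}[{idx}]: events {k} outside [0, {n}]")

        def check_strata(table: str, df: pd.DataFrame, key_cols: list[str],
                         required: set[tuple]) -> None:
            seen = [tuple(t) for t in df[key_cols].itertuples(index=False)]
            counts: dict[tuple, int] = {}
            for key in seen:
                counts[key] = counts.get(key, 0) + 1
            for key, cnt in counts.items():
                if cnt > 1:
                    errors.append(f"{table}: duplicate stratum {key}")
            for key in sorted(required - set(counts), key=repr):
                errors.append(f"{table}: missing stratum {key}")
            for key in sorted(set(counts) - required, key=repr):
                errors.append(f"{table}: unexpected stratum {key}")

        bands = set(AGE_BANDS)

        # --- incidence ---
        for idx, row in self.incidence.iterrows():
            if not check_label("incidence", idx, row["state"], alive_labels):
                continue
            st = state_from_label(row["state"])
            if row["condition"] not in Condition.__members__:
                errors.append(f"incidence[{idx}]: unknown condition {row['condition']!r}")
            elif Condition[row["condition"]] in st.physical:
                errors.append(
                    f"incidence[{idx}]: condition {row['condition']} already present "
                    f"in origin state {row['state']}"
                )
        check_counts("incidence", self.incidence)
        required_inc = {
            (s.label, c.value, lo, hi, sex)
            for s in alive
            for c in CONDITIONS
            if c not in s.physical
            for (lo, hi) in AGE_BANDS
            for sex in SEXES
        }
        check_strata(
            "incidence", self.incidence,
            ["state", "condition", "age_lower", "age_upper", "sex"], required_inc,
        )

        # --- mortality ---
        for idx, row in self.mortality.iterrows():
            check_label("mortality", idx, row["state"], alive_labels)
        check_counts("mortality", self.mortality)
        required_mort = {
            (s.label, lo, hi, sex)
            for s in alive for (lo, hi) in AGE_BANDS for sex in SEXES
        }
        check_strata("mortality", self.mortality,
                     ["state", "age_lower", "age_upper", "sex"], required_mort)

        # --- depression prevalence (keyed by physical state) ---
        for idx, row in self.depression.iterrows():
            check_label("depression", idx, row["state"], physical_labels)
        check_counts("depression", self.depression)
        required_dep = {
            (lbl, lo, hi, sex)
            for lbl in physical_labels for (lo, hi) in AGE_BANDS for sex in SEXES
        }
        check_strata("depression", self.depression,
                     ["state", "age_lower", "age_upper", "sex"], required_dep)

        # --- costs ---
        for idx, row in self.costs.iterrows():
            check_label("costs", idx, row["state"], alive_labels)
            if row["mean"] < 0:
                errors.append(f"costs[{idx}]: negative mean {row['mean']}")
            if row["sd"] < 0:
                errors.append(f"costs[{idx}]: negative sd {row['sd']}")
        check_strata("costs", self.costs,
                     ["state", "age_lower", "age_upper", "sex"], required_mort)

        # --- utilities ---
        for idx, row in self.utilities.iterrows():
            check_label("utilities", idx, row["state"], alive_labels)
            if not (0 <= row["mean"] <= 1):
                errors.append(f"utilities[{idx}]: mean {row['mean']} outside [0, 1]")
            if row["se"] < 0:
                errors.append(f"utilities[{idx}]: negative se {row['se']}")
        required_util = {
            (s.label, age) for s in alive for age in range(MIN_AGE, MAX_AGE + 1)
        }
        check_strata("utilities", self.utilities, ["state", "age"], required_util)

        # --- cohort ---
        total = 0
        for idx, row in self.cohort.iterrows():
            if not (MIN_AGE <= row["age"] <= MAX_AGE):
                errors.append(f"cohort[{idx}]: entry age {row['age']} outside [30, 100]")
            if row["sex"] not in SEXES:
                errors.append(f"cohort[{idx}]: unknown sex {row['sex']!r}")
            if row["count"] < 0:
                errors.append(f"cohort[{idx}]: negative count {row['count']}")
            else:
                total += row["count"]
        if total <= 0:
            errors.append("cohort: total entrants must be positive")
        dup = self.cohort.duplicated(subset=["age", "sex"])
        for idx in self.cohort.index[dup]:
            errors.append(f"cohort[{idx}]: duplicate (age, sex) row")

        # age bands used anywhere must be the canonical partition
        for name in ("incidence", "mortality", "depression", "costs"):
            df = getattr(self, name)
            bad = {
                (lo, hi)
                for lo, hi in zip(df["age_lower"], df["age_upper"])
                if (lo, hi) not in bands
            }
            for b in sorted(bad):
                errors.append(f"{name}: non-canonical age band {b}")

        if errors:
            raise BundleValidationError(sorted(set(errors)))

    def equals(self, other: "InputBundle") -> bool:
        """Exact equality of all six tables (order-insensitive)."""
        for name in FILE_NAMES:
            a = getattr(self, name)
            b = getattr(other, name)
            keys = [c for c in _COLUMNS[name] if c not in ("events", "denominator",
                                                           "mean", "sd", "se", "count")]
            a = a.sort_values(keys).reset_index(drop=True)[_COLUMNS[name]]
            b = b.sort_values(keys).reset_index(drop=True)[_COLUMNS[name]]
            if not a.equals(b):
                return False
        return True


def read_bundle(directory: str | Path,
                filenames: Mapping[str, str] | None = None) -> InputBundle:
    """Read and validate the six CSV tables from ``directory``.

    Raises FileNotFoundError naming the first missing file, and
    :class:`BundleValidationError` listing every content violation.
    """
    directory = Path(directory)
    names = dict(FILE_NAMES)
    if filenames:
        names.update(filenames)
    tables = {}
    for key, fname in names.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path}")
        tables[key] = pd.read_csv(path, float_precision="round_trip")
    bundle = InputBundle(**tables)
    bundle.validate()
    return bundle


def write_bundle(bundle: InputBundle, directory: str | Path) -> dict[str, Path]:
    """Validate and write the bundle as six CSVs; returns the paths written.

    Floats are written at full repr precision so that a read-back reproduces
    the bundle exactly.
    """
    bundle.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for key, fname in FILE_NAMES.items():
        df = getattr(bundle, key)[_COLUMNS[key]]
        path = directory / fname
        df.to_csv(path, index=False, float_format="%.17g")
        paths[key] = path
    return paths


# ---------------------------------------------------------------------------
# Dense array view used by the samplers and the Markov engine.
# ---------------------------------------------------------------------------

@dataclass
class BundleArrays:
    """Dense, index-aligned view of an InputBundle.

    Axis conventions: alive-state index (32, canonical order), condition
    index (4), band index (7), sex index (0=M, 1=F), age offset
    (age - 30, 71 single years).  Incidence cells for conditions already
    present in the origin state hold NaN.
    """

    inc_k: np.ndarray   # (32, 4, 7, 2)
    inc_n: np.ndarray   # (32, 4, 7, 2)
    mort_k: np.ndarray  # (32, 7, 2)
    mort_n: np.ndarray  # (32, 7, 2)
    dep_k: np.ndarray   # (16, 7, 2)
    dep_n: np.ndarray   # (16, 7, 2)
    cost_mean: np.ndarray  # (32, 7, 2)
    cost_sd: np.ndarray    # (32, 7, 2)
    util_mean: np.ndarray  # (32, 71)
    util_se: np.ndarray    # (32, 71)
    cohort: np.ndarray     # (71, 2) entrant counts by (age offset, sex)


def bundle_to_arrays(bundle: InputBundle) -> BundleArrays:
    """Convert a validated bundle into dense arrays."""
    band_pos = {band: i for i, band in enumerate(AGE_BANDS)}
    sex_pos = {s: i for i, s in enumerate(SEXES)}
    cond_pos = {c.value: i for i, c in enumerate(CONDITIONS)}

    inc_k = np.full((N_ALIVE, 4, N_BANDS, 2), np.nan)
    inc_n = np.full((N_ALIVE, 4, N_BANDS, 2), np.nan)
    for row in bundle.incidence.itertuples(index=False):
        i = state_index(state_from_label(row.state))
        j = cond_pos[row.condition]
        b = band_pos[(row.age_lower, row.age_upper)]
        s = sex_pos[row.sex]
        inc_k[i, j, b, s] = row.events
        inc_n[i, j, b, s] = row.denominator

    mort_k = np.zeros((N_ALIVE, N_BANDS, 2))
    mort_n = np.ones((N_ALIVE, N_BANDS, 2))
    for row in bundle.mortality.itertuples(index=False):
        i = state_index(state_from_label(row.state))
        b = band_pos[(row.age_lower, row.age_upper)]
        s = sex_pos[row.sex]
        mort_k[i, b, s] = row.events
        mort_n[i, b, s] = row.denominator

    dep_k = np.zeros((16, N_BANDS, 2))
    dep_n = np.ones((16, N_BANDS, 2))
    for row in bundle.depression.itertuples(index=False):
        p = physical_set_index(state_from_label(row.state).physical)
        b = band_pos[(row.age_lower, row.age_upper)]
        s = sex_pos[row.sex]
        dep_k[p, b, s] = row.events
        dep_n[p, b, s] = row.denominator

    cost_mean = np.zeros((N_ALIVE, N_BANDS, 2))
    cost_sd = np.zeros((N_ALIVE, N_BANDS, 2))
    for row in bundle.costs.itertuples(index=False):
        i = state_index(state_from_label(row.state))
        b = band_pos[(row.age_lower, row.age_upper)]
        s = sex_pos[row.sex]
        cost_mean[i, b, s] = row.mean
        cost_sd[i, b, s] = row.sd

    util_mean = np.zeros((N_ALIVE, N_AGES))
    util_se = np.zeros((N_ALIVE, N_AGES))
    for row in bundle.utilities.itertuples(index=False):
        i = state_index(state_from_label(row.state))
        util_mean[i, row.age - MIN_AGE] = row.mean
        util_se[i, row.age - MIN_AGE] = row.se

    cohort = np.zeros((N_AGES, 2))
    for row in bundle.cohort.itertuples(index=False):
        cohort[row.age - MIN_AGE, sex_pos[row.sex]] += row.count

    return BundleArrays(
        inc_k=inc_k, inc_n=inc_n,
        mort_k=mort_k, mort_n=mort_n,
        dep_k=dep_k, dep_n=dep_n,
        cost_mean=cost_mean, cost_sd=cost_sd,
        util_mean=util_mean, util_se=util_se,
        cohort=cohort,
    )
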