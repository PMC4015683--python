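"""State space of the multimorbidity Markov model.

The model tracks four chronic physical conditions (diabetes mellitus,
coronary heart disease, stroke, colorectal cancer) plus reversible
depression.  Every subset of the four physical conditions, crossed with
depression status, is a distinct alive state (2^4 x 2 = 32), and a single
absorbing Death state completes the space (33 states in total).

Physical disease is progressive: a state's set of physical conditions can
only grow over time, at most one new condition per annual cycle.  Depression
may be entered or left in any cycle.  Death is reachable from every alive
state.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import FrozenSet, Iterable

__all__ = [
    "Condition",
    "HealthState",
    "DEATH",
    "N_STATES",
    "N_ALIVE",
    "enumerate_states",
    "state_index",
    "state_from_label",
    "physical_sets",
    "physical_set_index",
    "morbidity_count",
    "successors",
]


class Condition(enum.Enum):
    """The four physical conditions tracked by the model."""

    DM = "DM"    # diabetes mellitus
    CHD = "CHD"  # coronary heart disease
    STR = "STR"  # stroke
    CRC = "CRC"  # colorectal cancer

    @property
    def order(self) -> int:
        return _CONDITION_ORDER[self]


_CONDITION_ORDER = {c: i for i, c in enumerate(Condition)}

CONDITIONS: tuple[Condition, ...] = tuple(Condition)


@dataclass(frozen=True)
class HealthState:
    """One node of the model: a set of physical conditions x depression,
    or the absorbing Death state."""

    physical: FrozenSet[Condition] = frozenset()
    depressed: bool = False
    is_death: bool = False

    def __post_init__(self) -> None:
        if self.is_death and (self.physical or self.depressed):
            raise ValueError("Death carries no physical conditions or depression")

    @property
    def label(self) -> str:
        if self.is_death:
            return "DEATH"
        if not self.physical:
            base = "AT_RISK"
        else:
            base = "+".join(
                c.value for c in sorted(self.physical, key=lambda c: c.order)
            )
        return base + "|DEP" if self.depressed else base

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HealthState({self.label!r})"


DEATH = HealthState(is_death=True)

N_ALIVE = 32
N_STATES = 33


def _sorted_subsets() -> list[FrozenSet[Condition]]:
    subsets: list[FrozenSet[Condition]] = []
    for k in range(5):
        for combo in itertools.combinations(CONDITIONS, k):
            subsets.append(frozenset(combo))
    # itertools.combinations over the enum order already yields subsets in
    # (size, condition-order) canonical order.
    return subsets


@lru_cache(maxsize=1)
def physical_sets() -> tuple[FrozenSet[Condition], ...]:
    """The 16 physical-condition combinations in canonical order."""
    return tuple(_sorted_subsets())


@lru_cache(maxsize=1)
def enumerate_states() -> tuple[HealthState, ...]:
    """All 33 states in canonical order.

    Alive states are ordered by (morbidity count, condition order,
    depression flag); index 0 is the healthy, non-depressed At Risk state
    and index 32 is Death.
    """
    states: list[HealthState] = []
    for phys in physical_sets():
        for depressed in (False, True):
            states.append(HealthState(physical=phys, depressed=depressed))
    states.append(DEATH)
    return tuple(states)


@lru_cache(maxsize=1)
def _index_map() -> dict[HealthState, int]:
    return {s: i for i, s in enumerate(enumerate_states())}


@lru_cache(maxsize=1)
def _label_map() -> dict[str, HealthState]:
    return {s.label: s for s in enumerate_states()}


def state_index(state: HealthState) -> int:
    """Canonical integer index of a state in [0, 32]."""
    return _index_map()[state]


def state_from_label(label: str) -> HealthState:
    """Parse a serialized state label such as "DM+CHD|DEP" or "DEATH"."""
    try:
        return _label_map()[label]
    except KeyError:
        raise ValueError(f"unknown state label: {label!r}") from None


@lru_cache(maxsize=1)
def _physical_index_map() -> dict[FrozenSet[Condition], int]:
    return {p: i for i, p in enumerate(physical_sets())}


def physical_set_index(physical: FrozenSet[Condition]) -> int:
    """Index of a physical-condition combination in [0, 15]."""
    return _physical_index_map()[frozenset(physical)]


def morbidity_count(state: HealthState) -> int:
    """Number of physical conditions held (0-4); rejects Death."""
    if state.is_death:
        raise ValueError("morbidity count is undefined for Death")
    return len(state.physical)


def successors(state: HealthState) -> frozenset[HealthState]:
    """States reachable from ``state`` in one annual cycle.

    Physical conditions are acquired one at a time and never remit, so an
    alive state with k conditions can move only to states with k or k+1
    conditions (each crossed with both depression statuses) or to Death.
    Death is absorbing.
    """
    if state.is_death:
        return frozenset({DEATH})
    out: set[HealthState] = {DEATH}
    targets: list[FrozenSet[Condition]] = [state.physical]
    for c in CONDITIONS:
        if c not in state.physical:
            targets.append(state.physical | {c})
    for phys in targets:
        out.add(HealthState(physical=phys, depressed=False))
        out.add(HealthState(physical=phys, depressed=True))
    return frozenset(out)
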