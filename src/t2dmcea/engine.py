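"""Transition-matrix assembly and the discounted, half-cycle-corrected cohort trace.

Competing risks are composed in a fixed order: background (other-cause)
mortality is applied first, and the cause-specific disease transitions are
then distributed among the survivors.  This guarantees row-stochastic
matrices without renormalisation and encodes the structural assumptions of
the model: no diabetes mortality from the controlled state, diabetes death
reachable only from the complicated state, and no remission transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    ABSORBING_STATES,
    STATE_INDEX,
    STATE_ORDER,
    ConfigError,
    ModelSpec,
    MortalitySchedule,
    Strategy,
    UndefinedStateError,
)

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "TransitionProbabilityError",
    "build_transition_matrix",
    "build_transition_matrices",
    "run_cohort",
    "discount_weight",
    "discount_weights",
]

_CONTROLLED, _UNCONTROLLED, _COMPLICATED, _DEATH_T2DM, _DEATH_OTHER = range(5)


class TransitionProbabilityError(ConfigError):
    """Cause-specific exit probabilities from one state sum above 1."""


@dataclass(frozen=True)
class TransitionMatrix:
    """A validated row-stochastic matrix over ``STATE_ORDER``."""

    state_order: tuple[str, ...]
    entries: np.ndarray  # (n_states, n_states)

    def __post_init__(self) -> None:
        p = self.entries
        if p.shape != (len(self.state_order),) * 2:
            raise ConfigError("transition matrix shape does not match state order")
        if np.any(p < 0) or np.any(p > 1):
            raise ConfigError("transition probabilities must lie in [0, 1]")
        rowsums = p.sum(axis=1)
        if not np.allclose(rowsums, 1.0, rtol=0, atol=1e-12):
            raise ConfigError(f"rows must sum to 1 within 1e-12, got {rowsums}")
        for name in ABSORBING_STATES:
            i = self.state_order.index(name)
            if p[i, i] != 1.0:
                raise ConfigError(f"absorbing state {name} must be a unit self-loop")

    def __getitem__(self, key) -> float:
        frm, to = key
        return float(self.entries[self.state_order.index(frm), self.state_order.index(to)])


def build_transition_matrices(
    strategy: Strategy, mortality: MortalitySchedule, ages
) -> np.ndarray:
    """Stack of per-age transition matrices, shape ``(len(ages), 5, 5)``.

    Background mortality ``q_b(age)`` applies first from every transient
    state; disease transitions then split the surviving fraction
    ``1 - q_b``.  From the complicated state, the age-specific diabetes
    death probability applies to other-cause survivors.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=int))
    qb, qt = mortality.lookup(ages)

    p_cc = strategy.p_complication_controlled
    p_cu = strategy.p_complication_uncontrolled
    p_f = strategy.p_failure
    if p_cc + p_f > 1.0 + 1e-12:
        raise TransitionProbabilityError(
            f"{strategy.name}: p_complication_controlled + p_failure = "
            f"{p_cc + p_f:g} exceeds 1"
        )

    n = len(ages)
    P = np.zeros((n, 5, 5))
    s = 1.0 - qb  # other-cause survivors

    P[:, _CONTROLLED, _DEATH_OTHER] = qb
    P[:, _CONTROLLED, _COMPLICATED] = s * p_cc
    P[:, _CONTROLLED, _UNCONTROLLED] = s * p_f
    P[:, _CONTROLLED, _CONTROLLED] = s * (1.0 - p_cc - p_f)

    P[:, _UNCONTROLLED, _DEATH_OTHER] = qb
    P[:, _UNCONTROLLED, _COMPLICATED] = s * p_cu
    P[:, _UNCONTROLLED, _UNCONTROLLED] = s * (1.0 - p_cu)

    P[:, _COMPLICATED, _DEATH_OTHER] = qb
    P[:, _COMPLICATED, _DEATH_T2DM] = s * qt
    P[:, _COMPLICATED, _COMPLICATED] = s * (1.0 - qt)

    P[:, _DEATH_T2DM, _DEATH_T2DM] = 1.0
    P[:, _DEATH_OTHER, _DEATH_OTHER] = 1.0
    # guard against -0.0 and tiny negative round-off in the stay terms
    np.clip(P, 0.0, 1.0, out=P)
    return P


def build_transition_matrix(
    strategy: Strategy, mortality: MortalitySchedule, age: int
) -> TransitionMatrix:
    """One-year transition matrix for the given attained age."""
    P = build_transition_matrices(strategy, mortality, [age])[0]
    return TransitionMatrix(STATE_ORDER, P)


def discount_weight(rate: float, cycle: int) -> float:
    """``(1 + rate) ** -cycle``; cycle-0 rewards are undiscounted."""
    if not (0.0 <= rate < 1.0):
        raise ConfigError(f"discount rate must lie in [0, 1), got {rate}")
    return float((1.0 + rate) ** (-cycle))


def discount_weights(rate: float, n_cycles: int) -> np.ndarray:
    return (1.0 + rate) ** (-np.arange(n_cycles, dtype=float))


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy plus reward bookkeeping.

    ``occupancy`` has ``n_cycles + 1`` rows (start-of-cycle-0 through end of
    the last cycle).  ``membership`` is the state exposure credited per
    cycle: the trapezoidal average of consecutive occupancy rows when
    half-cycle correction is on, otherwise the start-of-cycle occupancy.
    ``entrants_complicated`` is the flow newly arriving in the complicated
    state during each cycle (used for per-event rewards).  ``cycle_cost`` /
    ``cycle_daly`` are filled by :mod:`t2dmcea.outcomes`.
    """

    state_order: tuple[str, ...]
    ages: np.ndarray  # (n_cycles,)
    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    membership: np.ndarray  # (n_cycles, n_states)
    entrants_complicated: np.ndarray  # (n_cycles,)
    cycle_cost: np.ndarray | None = None  # discounted USD per cycle
    cycle_daly: np.ndarray | None = None  # discounted DALYs per cycle

    @property
    def n_cycles(self) -> int:
        return len(self.ages)


def run_cohort(
    strategy: Strategy,
    spec: ModelSpec,
    mortality: MortalitySchedule,
    initial_state: str = "controlled",
) -> CohortTrace:
    """Propagate a unit cohort through ``spec.n_cycles`` annual cycles.

    The whole cohort starts in ``initial_state``; each cycle uses the
    transition matrix for the attained age ``start_age + cycle``.
    """
    if initial_state not in STATE_INDEX:
        raise UndefinedStateError(f"unknown initial state {initial_state!r}")
    n = spec.n_cycles
    ages = spec.start_age + np.arange(n)
    P = build_transition_matrices(strategy, mortality, ages)

    occ = np.zeros((n + 1, 5))
    occ[0, STATE_INDEX[initial_state]] = 1.0
    entrants = np.zeros(n)
    for t in range(n):
        occ[t + 1] = occ[t] @ P[t]
        # inflow into complicated = all arrivals minus those already there staying
        entrants[t] = occ[t + 1, _COMPLICATED] - occ[t, _COMPLICATED] * P[t, _COMPLICATED, _COMPLICATED]

    if spec.half_cycle_correction:
        membership = 0.5 * (occ[:-1] + occ[1:])
    else:
        membership = occ[:-1].copy()

    return CohortTrace(
        state_order=STATE_ORDER,
        ages=ages,
        occupancy=occ,
        membership=membership,
        entrants_complicated=entrants,
    )
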