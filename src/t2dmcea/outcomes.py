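"""Reduce a cohort trace to expected discounted cost and DALYs per person.

DALYs are disutility-weighted person-years over the model horizon: living
states contribute their annual disutility (years lived with disability),
dead states contribute weight 1 (horizon-truncated years of life lost),
and each complication event adds a one-off decrement.  Fewer DALYs are
better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelSpec, MortalitySchedule, Strategy
from .engine import CohortTrace, discount_weights, run_cohort

__all__ = [
    "StrategyResult",
    "accumulate_costs",
    "accumulate_dalys",
    "evaluate_strategy",
    "trace_to_frame",
]


@dataclass(frozen=True)
class StrategyResult:
    """Per-person expected discounted cost (USD) and DALYs for one arm."""

    strategy: str
    expected_cost: float
    expected_dalys: float


def _event_exposure(trace: CohortTrace, spec: ModelSpec) -> np.ndarray:
    """Cohort fraction charged the per-event complication rewards each cycle."""
    if spec.recurrent_complication_events:
        comp = trace.state_order.index("complicated")
        return trace.membership[:, comp]
    return trace.entrants_complicated


def accumulate_costs(trace: CohortTrace, strategy: Strategy, spec: ModelSpec) -> float:
    """Sum of discounted [state exposure x annual cost + event flow x event cost]."""
    disc = discount_weights(spec.discount_rate_cost, trace.n_cycles)
    cycle = (
        trace.membership @ strategy.state_costs()
        + _event_exposure(trace, spec) * strategy.event.event_cost
    ) * disc
    trace.cycle_cost = cycle
    return float(cycle.sum())


def accumulate_dalys(trace: CohortTrace, strategy: Strategy, spec: ModelSpec) -> float:
    """Sum of discounted [state exposure x disutility + event flow x decrement]."""
    disc = discount_weights(spec.discount_rate_effect, trace.n_cycles)
    cycle = (
        trace.membership @ strategy.state_disutilities()
        + _event_exposure(trace, spec) * strategy.event.event_disutility
    ) * disc
    trace.cycle_daly = cycle
    return float(cycle.sum())


def evaluate_strategy(
    strategy: Strategy,
    spec: ModelSpec,
    mortality: MortalitySchedule,
    initial_state: str = "controlled",
) -> tuple[StrategyResult, CohortTrace]:
    """Run one arm's cohort and accumulate both reward streams."""
    trace = run_cohort(strategy, spec, mortality, initial_state)
    cost = accumulate_costs(trace, strategy, spec)
    dalys = accumulate_dalys(trace, strategy, spec)
    return StrategyResult(strategy.name, cost, dalys), trace


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """One row per cycle: age, per-state occupancy (start of cycle), entrant
    flow into the complicated state, and discounted cycle rewards."""
    data = {"age": trace.ages}
    for i, name in enumerate(trace.state_order):
        data[name] = trace.occupancy[:-1, i]
    data["entrants_complicated"] = trace.entrants_complicated
    data["discounted_cost"] = trace.cycle_cost if trace.cycle_cost is not None else np.nan
    data["discounted_daly"] = trace.cycle_daly if trace.cycle_daly is not None else np.nan
    return pd.DataFrame(data)
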