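"""Ranking, dominance elimination, ICER/ACER and net monetary benefit.

Effectiveness is stored as DALYs, where fewer is better; "DALYs averted"
is always a difference against a comparator.  Strategies are ranked by
cost; a strategy is strongly dominated if some alternative costs no more
and produces no more DALYs (strictly better on at least one axis), and
extendedly dominated if its incremental ICER exceeds that of a more
effective alternative.  Survivors form the efficiency frontier, along
which ICERs are strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd

from .outcomes import StrategyResult

__all__ = [
    "CEAResult",
    "eliminate_dominated",
    "compute_icers",
    "analyze",
    "acer",
    "nmb",
    "icer_between",
    "GDP_PER_CAPITA_ETHIOPIA_2019",
    "CET_HALF_GDP",
    "WHO_CHOICE_1X_GDP",
    "WHO_CHOICE_3X_GDP",
]

#: 2019 Ethiopian GDP per capita (USD) and the derived willingness-to-pay
#: thresholds per DALY averted.
GDP_PER_CAPITA_ETHIOPIA_2019 = 953.0
CET_HALF_GDP = 0.5 * GDP_PER_CAPITA_ETHIOPIA_2019  # 476.5, the study threshold
WHO_CHOICE_1X_GDP = 1.0 * GDP_PER_CAPITA_ETHIOPIA_2019  # "very cost-effective" bound
WHO_CHOICE_3X_GDP = 3.0 * GDP_PER_CAPITA_ETHIOPIA_2019  # "cost-effective" bound


@dataclass
class CEAResult:
    """Ranked CEA table plus the efficiency frontier.

    ``table`` columns: strategy, cost, incremental_cost, dalys,
    incremental_dalys_averted, icer, acer, dominance (''|'strong'|'extended'),
    on_frontier.  Rows are ordered by increasing cost (ties broken by name).
    Frontier rows report incrementals against the previous frontier member;
    dominated rows report them against the previous row in cost order, for
    display parity with conventional CEA tables.  An undefined ICER (zero
    incremental effect) is NaN.
    """

    table: pd.DataFrame

    @property
    def frontier(self) -> list[str]:
        return list(self.table.loc[self.table["on_frontier"], "strategy"])

    def row(self, strategy: str) -> pd.Series:
        return self.table.set_index("strategy").loc[strategy]

    def frontier_icer(self, strategy: str) -> float:
        """The frontier ICER attributed to ``strategy`` (NaN for the cheapest)."""
        r = self.row(strategy)
        if not r["on_frontier"]:
            raise ValueError(f"{strategy!r} is not on the efficiency frontier")
        return float(r["icer"])


def acer(result: StrategyResult) -> float:
    """Average cost-effectiveness ratio: total cost per total DALY."""
    if result.expected_dalys <= 0:
        raise ZeroDivisionError(f"{result.strategy}: ACER undefined for DALYs <= 0")
    return result.expected_cost / result.expected_dalys


def nmb(result: StrategyResult, wtp: float, reference: StrategyResult) -> float:
    """Incremental net monetary benefit vs ``reference`` at willingness-to-pay
    ``wtp``: wtp x DALYs averted - incremental cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    averted = reference.expected_dalys - result.expected_dalys
    return wtp * averted - (result.expected_cost - reference.expected_cost)


def icer_between(cheaper: StrategyResult, costlier: StrategyResult) -> float:
    """Incremental cost per DALY averted, NaN if the incremental effect is 0."""
    d_cost = costlier.expected_cost - cheaper.expected_cost
    d_averted = cheaper.expected_dalys - costlier.expected_dalys
    if d_averted == 0:
        return math.nan
    return d_cost / d_averted


def _ranked(results: Sequence[StrategyResult]) -> list[StrategyResult]:
    return sorted(results, key=lambda r: (r.expected_cost, r.strategy))


def eliminate_dominated(results: Sequence[StrategyResult]) -> CEAResult:
    """Flag strong and extended dominance; survivors form the frontier.

    Exact cost/DALY ties are co-optimal: both are kept on the frontier,
    ordered by name.
    """
    if not results:
        raise ValueError("need at least one strategy")
    ranked = _ranked(results)
    dominance = {r.strategy: "" for r in ranked}

    # strong dominance: some alternative is no worse on both axes, better on one
    for r in ranked:
        for other in ranked:
            if other.strategy == r.strategy:
                continue
            no_worse = (
                other.expected_cost <= r.expected_cost
                and other.expected_dalys <= r.expected_dalys
            )
            better = (
                other.expected_cost < r.expected_cost
                or other.expected_dalys < r.expected_dalys
            )
            if no_worse and better:
                dominance[r.strategy] = "strong"
                break

    # extended dominance: drop frontier candidates whose incremental ICER is
    # >= that of the next, more effective candidate, until ICERs increase
    survivors = [r for r in ranked if not dominance[r.strategy]]
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        icers = [icer_between(survivors[i - 1], survivors[i]) for i in range(1, len(survivors))]
        for i in range(len(icers) - 1):
            if not math.isnan(icers[i]) and not math.isnan(icers[i + 1]) and icers[i] >= icers[i + 1]:
                dominance[survivors[i + 1].strategy] = "extended"
                survivors.pop(i + 1)
                changed = True
                break

    rows = []
    for i, r in enumerate(ranked):
        prev = ranked[i - 1] if i > 0 else None
        rows.append(
            {
                "strategy": r.strategy,
                "cost": r.expected_cost,
                "incremental_cost": (r.expected_cost - prev.expected_cost) if prev else 0.0,
                "dalys": r.expected_dalys,
                "incremental_dalys_averted": (prev.expected_dalys - r.expected_dalys) if prev else 0.0,
                "icer": math.nan,
                "acer": acer(r) if r.expected_dalys > 0 else math.nan,
                "dominance": dominance[r.strategy],
                "on_frontier": not dominance[r.strategy],
            }
        )
    return CEAResult(pd.DataFrame(rows))


def compute_icers(skeleton: CEAResult, results: Sequence[StrategyResult]) -> CEAResult:
    """Fill incremental columns: frontier rows against the previous frontier
    member, dominated rows against the previous row in cost order."""
    ranked = _ranked(results)
    by_name = {r.strategy: r for r in ranked}
    table = skeleton.table.copy()

    prev_frontier: StrategyResult | None = None
    prev_any: StrategyResult | None = None
    for idx, row in table.iterrows():
        r = by_name[row["strategy"]]
        if row["on_frontier"]:
            if prev_frontier is not None:
                table.at[idx, "incremental_cost"] = r.expected_cost - prev_frontier.expected_cost
                table.at[idx, "incremental_dalys_averted"] = (
                    prev_frontier.expected_dalys - r.expected_dalys
                )
                table.at[idx, "icer"] = icer_between(prev_frontier, r)
            else:
                table.at[idx, "incremental_cost"] = 0.0
                table.at[idx, "incremental_dalys_averted"] = 0.0
            prev_frontier = r
        elif prev_any is not None:
            table.at[idx, "incremental_cost"] = r.expected_cost - prev_any.expected_cost
            table.at[idx, "incremental_dalys_averted"] = prev_any.expected_dalys - r.expected_dalys
            table.at[idx, "icer"] = icer_between(prev_any, r)
        prev_any = r
    return CEAResult(table)


def analyze(results: Sequence[StrategyResult]) -> CEAResult:
    """Full pipeline: rank, eliminate dominated options, compute ICER/ACER."""
    return compute_icers(eliminate_dominated(results), results)
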