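"""One-way sensitivity analysis: sweeps, tornado ordering and threshold
(break-even) analysis of the frontier ICER.

Every sweep re-runs the deterministic model with a single parameter moved
across its range while all other inputs stay at their base-case values.
The reported ICER is always between a fixed pair of strategies — by
default the base-case frontier comparison — so bars and curves are
directly comparable across parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cea import icer_between
from .config import ModelInputs
from .outcomes import evaluate_strategy

__all__ = ["TornadoEntry", "one_way_sweep", "tornado", "threshold_analysis", "icer_at"]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def range_width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _default_comparison(inputs: ModelInputs) -> tuple[str, str]:
    """Base-case frontier pair (cheaper, costlier) for ICER reporting."""
    from .cea import analyze

    results = [
        evaluate_strategy(s, inputs.spec, inputs.mortality, inputs.initial_state)[0]
        for s in inputs.strategies
    ]
    frontier = analyze(results).frontier
    if len(frontier) < 2:
        raise ValueError("need at least two frontier strategies for ICER sweeps")
    return frontier[0], frontier[-1]


def icer_at(
    inputs: ModelInputs,
    values: Mapping[str, float],
    comparison: tuple[str, str] | None = None,
) -> float:
    """Deterministic frontier ICER with the given parameter overrides."""
    from .study import apply_parameters

    if comparison is None:
        comparison = _default_comparison(inputs)
    modified = apply_parameters(inputs, values)
    cheaper, costlier = (
        evaluate_strategy(modified.strategy(name), modified.spec, modified.mortality, modified.initial_state)[0]
        for name in comparison
    )
    return icer_between(cheaper, costlier)


def one_way_sweep(
    inputs: ModelInputs,
    parameter: str,
    low: float,
    high: float,
    n_points: int = 25,
    comparison: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """ICER across an evenly spaced grid of one parameter's values."""
    if low >= high:
        raise ValueError(f"{parameter}: need low < high, got ({low}, {high})")
    if comparison is None:
        comparison = _default_comparison(inputs)
    values = np.linspace(low, high, n_points)
    icers = [icer_at(inputs, {parameter: v}, comparison) for v in values]
    return pd.DataFrame({"value": values, "icer": icers})


def tornado(
    inputs: ModelInputs,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    comparison: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """ICER at each parameter's low and high bound, sorted by descending
    impact (|high - low| of the resulting ICERs)."""
    from .study import one_way_ranges

    if ranges is None:
        ranges = one_way_ranges(inputs)
    if not ranges:
        raise ValueError("tornado needs at least one parameter range")
    if comparison is None:
        comparison = _default_comparison(inputs)
    entries = []
    for name, (low, high) in ranges.items():
        entries.append(
            TornadoEntry(
                name,
                icer_at(inputs, {name: low}, comparison),
                icer_at(inputs, {name: high}, comparison),
            )
        )
    entries.sort(key=lambda e: e.range_width, reverse=True)
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "range_width": [e.range_width for e in entries],
        }
    )


def threshold_analysis(
    inputs: ModelInputs,
    parameter: str,
    low: float,
    high: float,
    wtp: float,
    n_points: int = 25,
    comparison: tuple[str, str] | None = None,
) -> list[float]:
    """Parameter values in [low, high] where the ICER crosses ``wtp``.

    A sweep locates sign changes of ICER - wtp; each bracketed crossing is
    refined by Brent root finding.  Returns an empty list if the ICER never
    crosses the threshold on the range.
    """
    if comparison is None:
        comparison = _default_comparison(inputs)
    sweep = one_way_sweep(inputs, parameter, low, high, n_points, comparison)
    f = sweep["icer"].to_numpy() - wtp
    values = sweep["value"].to_numpy()
    crossings: list[float] = []
    for i in range(len(values) - 1):
        if f[i] == 0.0:
            crossings.append(float(values[i]))
        elif f[i] * f[i + 1] < 0:
            root = brentq(
                lambda v: icer_at(inputs, {parameter: v}, comparison) - wtp,
                values[i],
                values[i + 1],
            )
            crossings.append(float(root))
    if f[-1] == 0.0:
        crossings.append(float(values[-1]))
    return crossings
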