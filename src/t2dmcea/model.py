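"""Model/Results facade over the cohort engine and analysis modules.

:class:`MarkovCEA` bundles validated model inputs; :meth:`MarkovCEA.fit`
evaluates the deterministic base case and returns a
:class:`MarkovCEAResults` carrying per-arm expected costs and DALYs, the
ranked CEA table with dominance flags and ICER/ACER columns, and the
cohort traces.  Probabilistic and one-way sensitivity analyses hang off
the model object.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from . import cea as _cea
from . import owsa as _owsa
from . import psa as _psa
from .config import ModelInputs, ParameterDistribution, load_model
from .engine import CohortTrace
from .outcomes import StrategyResult, evaluate_strategy, trace_to_frame

__all__ = ["MarkovCEA", "MarkovCEAResults"]


class MarkovCEA:
    """Markov cohort cost-effectiveness model over a set of treatment arms."""

    def __init__(self, inputs: ModelInputs):
        self.inputs = inputs

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_config(cls, path: str | Path) -> "MarkovCEA":
        """Build from a YAML model configuration file."""
        return cls(load_model(path))

    @classmethod
    def from_reference_study(cls, defaults=None, **spec_overrides) -> "MarkovCEA":
        """The packaged Ethiopian T2DM second-line therapy study."""
        from .study import build_reference_model

        return cls(build_reference_model(defaults, **spec_overrides))

    # -- evaluation ---------------------------------------------------------
    def fit(self) -> "MarkovCEAResults":
        """Evaluate the deterministic base case (cohort traces, expected
        costs/DALYs, dominance and ICERs)."""
        results: list[StrategyResult] = []
        traces: dict[str, CohortTrace] = {}
        for s in self.inputs.strategies:
            res, trace = evaluate_strategy(
                s, self.inputs.spec, self.inputs.mortality, self.inputs.initial_state
            )
            results.append(res)
            traces[s.name] = trace
        return MarkovCEAResults(self, tuple(results), traces, _cea.analyze(results))

    evaluate = fit  # alias: nothing is statistically estimated

    # -- sensitivity analyses ----------------------------------------------
    def psa(
        self,
        n_iterations: int = 1000,
        seed: int = 0,
        distributions: tuple[ParameterDistribution, ...] | None = None,
    ) -> _psa.PSAResult:
        return _psa.run_psa(self.inputs, distributions, n_iterations, seed)

    def one_way(self, parameter: str, low: float, high: float, n_points: int = 25, comparison=None):
        return _owsa.one_way_sweep(self.inputs, parameter, low, high, n_points, comparison)

    def tornado(self, ranges=None, comparison=None) -> pd.DataFrame:
        return _owsa.tornado(self.inputs, ranges, comparison)

    def threshold(self, parameter: str, low: float, high: float, wtp: float, **kwargs):
        return _owsa.threshold_analysis(self.inputs, parameter, low, high, wtp, **kwargs)


@dataclass
class MarkovCEAResults:
    """Deterministic base-case results for a :class:`MarkovCEA` model."""

    model: MarkovCEA
    strategy_results: tuple[StrategyResult, ...]
    traces: dict[str, CohortTrace]
    cea: _cea.CEAResult

    @property
    def table(self) -> pd.DataFrame:
        return self.cea.table

    def trace_frame(self, strategy: str) -> pd.DataFrame:
        return trace_to_frame(self.traces[strategy])

    def summary(self) -> str:
        """Conventional CEA table: cost, incrementals, DALYs, ICER, ACER and
        dominance per strategy, ratios rounded to the nearest dollar."""
        t = self.table.copy()
        lines = [
            "Cost-effectiveness summary (discounted, per person over horizon)",
            f"{'strategy':<26}{'cost':>10}{'incr cost':>11}{'DALYs':>9}"
            f"{'averted':>9}{'ICER':>8}{'ACER':>8}  dominance",
        ]
        for _, r in t.iterrows():
            icer = "" if pd.isna(r["icer"]) else f"{r['icer']:.0f}"
            lines.append(
                f"{r['strategy']:<26}{r['cost']:>10.1f}{r['incremental_cost']:>11.1f}"
                f"{r['dalys']:>9.3f}{r['incremental_dalys_averted']:>9.3f}"
                f"{icer:>8}{r['acer']:>8.0f}  {r['dominance'] or '-'}"
            )
        return "\n".join(lines)
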