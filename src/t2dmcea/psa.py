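"""Probabilistic sensitivity analysis: Monte Carlo parameter propagation,
acceptability curves (CEAC) and the acceptability frontier (CEAF).

Each iteration draws every uncertain parameter independently from its
moment-matched distribution, rebuilds the strategies, and re-runs the
deterministic cohort model.  Draw combinations that violate a structural
constraint (cause-specific exit probabilities from one state summing above
1) are rejected and redrawn, and the rejection count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelInputs, ParameterDistribution, sample_parameter
from .outcomes import evaluate_strategy

__all__ = ["PSAResult", "run_psa", "ceac", "ceaf", "scatter"]

_MAX_REDRAWS = 1000


@dataclass
class PSAResult:
    """Monte Carlo samples: one row per iteration with every drawn parameter
    and each strategy's cost and DALYs (columns ``cost_<name>``,
    ``dalys_<name>``)."""

    samples: pd.DataFrame
    parameters: tuple[str, ...]
    strategies: tuple[str, ...]
    n_rejected: int
    seed: int


def _feasible(inputs: ModelInputs) -> bool:
    return all(s.p_complication_controlled + s.p_failure <= 1.0 for s in inputs.strategies)


def run_psa(
    inputs: ModelInputs,
    distributions: tuple[ParameterDistribution, ...] | None = None,
    n_iterations: int = 1000,
    seed: int = 0,
) -> PSAResult:
    """Seeded Monte Carlo over the model's uncertain parameters.

    ``distributions`` defaults to the ones attached to ``inputs``; their
    names must exist in the study parameter registry.  Identical seeds give
    bit-identical sample sets.
    """
    from .study import apply_parameters  # late import: registry lives with the study

    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    dists = distributions if distributions is not None else inputs.distributions
    if not dists:
        raise ValueError("no parameter distributions supplied")
    rng = np.random.default_rng(seed)
    names = tuple(d.name for d in dists)
    strategy_names = tuple(s.name for s in inputs.strategies)

    rows = []
    n_rejected = 0
    for it in range(n_iterations):
        for attempt in range(_MAX_REDRAWS):
            draws = {d.name: float(sample_parameter(d, rng)) for d in dists}
            candidate = apply_parameters(inputs, draws)
            if _feasible(candidate):
                break
            n_rejected += 1
        else:  # pragma: no cover - would need a pathological distribution set
            raise RuntimeError(f"iteration {it}: no feasible draw in {_MAX_REDRAWS} attempts")
        row = {"iteration": it, **draws}
        for s in candidate.strategies:
            res, _ = evaluate_strategy(s, candidate.spec, candidate.mortality, candidate.initial_state)
            row[f"cost_{s.name}"] = res.expected_cost
            row[f"dalys_{s.name}"] = res.expected_dalys
        rows.append(row)

    return PSAResult(pd.DataFrame(rows), names, strategy_names, n_rejected, seed)


def _nmb_matrix(samples: pd.DataFrame, strategies: tuple[str, ...], wtp: float) -> np.ndarray:
    """Per-iteration NMB of each strategy against the cheapest-on-average
    reference; the argmax is reference-invariant."""
    ref = min(strategies, key=lambda s: samples[f"cost_{s}"].mean())
    cols = []
    for s in strategies:
        averted = samples[f"dalys_{ref}"].to_numpy() - samples[f"dalys_{s}"].to_numpy()
        d_cost = samples[f"cost_{s}"].to_numpy() - samples[f"cost_{ref}"].to_numpy()
        cols.append(wtp * averted - d_cost)
    return np.column_stack(cols)


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Probability each strategy has maximal net monetary benefit at each
    willingness-to-pay; ties go to the cheaper strategy, so the per-row
    probabilities sum to exactly 1."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    strategies = psa.strategies
    # tie-break: order candidate columns by mean cost so argmax prefers cheaper
    order = sorted(range(len(strategies)), key=lambda i: psa.samples[f"cost_{strategies[i]}"].mean())
    rows = []
    for wtp in wtp_grid:
        nmbs = _nmb_matrix(psa.samples, strategies, wtp)
        winner_ordered = np.argmax(nmbs[:, order], axis=1)
        winner = np.asarray(order)[winner_ordered]
        counts = np.bincount(winner, minlength=len(strategies)) / len(psa.samples)
        rows.append({"wtp": wtp, **{s: counts[i] for i, s in enumerate(strategies)}})
    return pd.DataFrame(rows)


def ceaf(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """At each willingness-to-pay, the strategy with the highest *expected*
    net monetary benefit (which may differ from the probability winner)."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    strategies = psa.strategies
    rows = []
    for wtp in wtp_grid:
        mean_nmb = _nmb_matrix(psa.samples, strategies, wtp).mean(axis=0)
        best = int(np.argmax(mean_nmb))
        rows.append({"wtp": wtp, "strategy": strategies[best], "expected_nmb": mean_nmb[best]})
    return pd.DataFrame(rows)


def scatter(psa: PSAResult, comparator: str, reference: str) -> pd.DataFrame:
    """Per-iteration incremental cost and DALYs averted of ``comparator``
    against ``reference`` (cost-effectiveness plane coordinates)."""
    s = psa.samples
    return pd.DataFrame(
        {
            "iteration": s["iteration"],
            "incremental_cost": s[f"cost_{comparator}"] - s[f"cost_{reference}"],
            "incremental_dalys_averted": s[f"dalys_{reference}"] - s[f"dalys_{comparator}"],
        }
    )
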