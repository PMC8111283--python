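"""Thin matplotlib helpers for the standard CEA figures.

Each function takes the plot-ready frame produced elsewhere in the
package and returns the axes, so callers control figures and saving.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_ceac", "plot_tornado", "plot_scatter"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_ceac(ceac_frame: pd.DataFrame, ax=None):
    """Acceptability curves: probability cost-effective vs willingness-to-pay."""
    ax = _axes(ax)
    for col in ceac_frame.columns:
        if col == "wtp":
            continue
        ax.plot(ceac_frame["wtp"], ceac_frame[col], label=col)
    ax.set_xlabel("willingness-to-pay (USD per DALY averted)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_tornado(tornado_frame: pd.DataFrame, base_icer: float, ax=None):
    """Horizontal tornado bars around the base-case ICER."""
    ax = _axes(ax)
    t = tornado_frame.iloc[::-1]  # widest bar on top
    for i, (_, row) in enumerate(t.iterrows()):
        lo = min(row["icer_at_low"], row["icer_at_high"])
        hi = max(row["icer_at_low"], row["icer_at_high"])
        ax.barh(i, hi - lo, left=lo, height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(t)), t["parameter"])
    ax.set_xlabel("ICER (USD per DALY averted)")
    return ax


def plot_scatter(scatter_frame: pd.DataFrame, wtp: float | None = None, ax=None):
    """Cost-effectiveness plane of per-iteration incremental outcomes."""
    ax = _axes(ax)
    ax.scatter(
        scatter_frame["incremental_dalys_averted"],
        scatter_frame["incremental_cost"],
        s=4,
        alpha=0.3,
    )
    if wtp is not None:
        xs = scatter_frame["incremental_dalys_averted"]
        lim = max(abs(xs.min()), abs(xs.max()))
        ax.plot([-lim, lim], [-wtp * lim, wtp * lim], "k--", lw=1, label=f"WTP {wtp:g}")
        ax.legend()
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental DALYs averted")
    ax.set_ylabel("incremental cost (USD)")
    return ax
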