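"""Plot helpers for the sensitivity analyses (CEAC/CEAF, price thresholds)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_ceac_ceaf", "plot_price_thresholds"]


def plot_ceac_ceaf(ceac: pd.DataFrame, ceaf: pd.Series, path: str | Path) -> None:
    """Acceptability curves per strategy, with the frontier strategy marked."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name in ceac.columns:
        ax.plot(ceac.index / 1e6, ceac[name], label=name)
    # overlay: probability of the CEAF strategy at each WTP
    frontier_prob = [ceac.loc[w, ceaf.loc[w]] for w in ceac.index]
    ax.plot(
        ceac.index / 1e6,
        frontier_prob,
        "k--",
        linewidth=1,
        label="frontier (max expected NMB)",
    )
    ax.set_xlabel("Willingness to pay (million $ per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_price_thresholds(
    thresholds: Mapping[str, float], list_prices: Mapping[str, float], path: str | Path
) -> None:
    """Bar chart of break-even annual drug prices versus list prices."""
    names = list(thresholds)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    y = range(len(names))
    ax.barh(y, [list_prices[n] for n in names], color="0.85", label="annual list price")
    ax.barh(y, [thresholds[n] for n in names], color="C0", label="break-even price")
    ax.set_yticks(list(y), names)
    ax.set_xlabel("Annual drug cost ($)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
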