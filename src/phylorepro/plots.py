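"""Summary figures: violin comparisons, forest scatter, breadth vs information."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .forest import ForestRecord

__all__ = ["violin_differences", "forest_scatter", "breadth_information_plot"]


def violin_differences(records_df: pd.DataFrame, path=None):
    """Violin plots of between-run vs run-to-truth topological differences
    over the irreproducible subset."""
    irr = records_df[~records_df.reproducible]
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(irr) >= 2:
        parts = ax.violinplot(
            [irr.d_q1q2.values, irr.d_q1t.values, irr.d_q2t.values],
            showmeans=True,
        )
        for body, color in zip(parts["bodies"], ("white", "0.6", "0.6")):
            body.set_facecolor(color)
            body.set_edgecolor("black")
    ax.set_xticks([1, 2, 3], [r"$\Delta$Q1Q2", r"$\Delta$Q1T", r"$\Delta$Q2T"])
    ax.set_ylabel("topological difference (%)")
    ax.set_title(f"irreproducible data sets (n={len(irr)})")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def forest_scatter(rec: ForestRecord, path=None):
    """Per-member inaccuracy vs log-likelihood advantage over the true tree."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if rec.members:
        x = [m.delta_ll for m in rec.members]
        y = [m.rf_percent_to_true for m in rec.members]
        ax.scatter(x, y, s=12, c="black")
        best = max(rec.members, key=lambda m: m.log_likelihood)
        ax.scatter([best.delta_ll], [best.rf_percent_to_true], s=80,
                   facecolors="none", edgecolors="red")
        if len(set(x)) > 2 and len(set(y)) > 1:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(min(x), max(x), 20)
            ax.plot(xs, a + b * xs, "--", color="0.5")
    ax.scatter([0], [0], facecolors="none", edgecolors="black", s=60)
    ax.set_xlabel(r"$\Delta$ log-likelihood vs true tree")
    ax.set_ylabel("inaccuracy (% RF to true tree)")
    ax.set_title(f"optimality forest, {rec.n_distinct} trees")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def breadth_information_plot(forest_df: pd.DataFrame, path=None):
    """Forest breadth against phylogenetic information (log-x scatter)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(forest_df.information, forest_df.breadth, s=12, c="black")
    ax.set_xscale("log")
    ax.set_xlabel("phylogenetic information (expected substitutions)")
    ax.set_ylabel("forest breadth (log-likelihood units)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
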