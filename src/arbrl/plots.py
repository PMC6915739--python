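"""Figure helpers: condition-cell bars and recovery scatter plots.

Matplotlib-based analogues of the standard behavioral panels (choice bias /
consistency per goal condition, choice optimality or P_MB per condition
cell, generative-vs-recovered parameter scatter).  All functions take tidy
frames produced by :mod:`arbrl.behavior_metrics` / :mod:`arbrl.inference`
and return the matplotlib figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def condition_cell_bars(summary: pd.DataFrame, value: str = "group_mean",
                        err: str = "group_sem", title: str = ""):
    """Bar chart of a statistic over the four (uncertainty x complexity) cells."""
    cells = summary.drop_duplicates(["uncertainty", "complexity"])
    labels = [f"{u[0].upper()}u/{c[0].upper()}c"
              for u, c in zip(cells["uncertainty"], cells["complexity"])]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(labels, cells[value], yerr=cells[err], capsize=3, color="0.6")
    ax.set_ylabel(value.replace("_", " "))
    ax.set_title(title)
    fig.tight_layout()
    return fig


def goal_condition_bars(frame: pd.DataFrame, value: str, title: str = ""):
    """Per-goal-condition group means with SEM error bars (bias/consistency)."""
    g = frame.groupby("goal_condition")[value].agg(["mean", "sem"])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(g.index, g["mean"], yerr=g["sem"], capsize=3, color="0.6")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_ylabel(value)
    ax.set_title(title)
    fig.tight_layout()
    return fig


def recovery_scatter(true_params, fits, param: str, title: str = ""):
    """Generative vs recovered values of one parameter across agents."""
    t = np.array([p[param] for p in true_params], float)
    r = np.array([f.params[param] for f in fits], float)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(t, r, s=15, color="0.3")
    lims = [min(t.min(), r.min()), max(t.max(), r.max())]
    ax.plot(lims, lims, "k--", lw=0.7)
    ax.set_xlabel(f"generative {param}")
    ax.set_ylabel(f"recovered {param}")
    ax.set_title(title)
    fig.tight_layout()
    return fig
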