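"""Minimal rendering of the stacked-CIF displays.

The package's plot functions draw the survivor curve with the per-cause
cumulative incidences stacked above it, so the unit strip between the
conditioning age and tau is partitioned into an "alive" band (area =
restricted life expectancy) and per-cause "dead" bands (areas = the
cause-specific Life Years Lost).  The plot *data* live in
:func:`lifeyears.point.stacked_series`; these helpers only render it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .point import stacked_series
from .survival import CompetingRisksCurves

__all__ = ["plot_stacked", "plot_side_by_side"]


def _draw(ax, curves: CompetingRisksCurves, tau: float, colors=None, title=None) -> None:
    data = stacked_series(curves, tau)
    ages = data["age"].to_numpy()
    lower = 0.0 * ages
    layers = [c for c in data.columns if c != "age"]
    labels = ["alive"] + [c.split("+", 1)[1] for c in layers[1:]]
    for i, (col, label) in enumerate(zip(layers, labels)):
        upper = data[col].to_numpy()
        color = None if colors is None else colors[i % len(colors)]
        ax.fill_between(ages, lower, upper, step="post", label=label, color=color, alpha=0.7)
        lower = upper
    ax.step(ages, data[layers[0]], where="post", color="black", lw=1.2)
    ax.set_xlim(curves.condition_age, tau)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Probability")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower left", fontsize=8)


def plot_stacked(curves: CompetingRisksCurves, tau: float, path=None, colors=None):
    """Survival plus stacked cause-specific cumulative incidence."""
    fig, ax = plt.subplots(figsize=(6, 4))
    _draw(ax, curves, tau, colors=colors)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_side_by_side(
    left: CompetingRisksCurves,
    right: CompetingRisksCurves,
    tau: float,
    path=None,
    titles=("diseased", "reference"),
):
    """Two stacked displays sharing axes, for cohort-vs-reference reading."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    _draw(axes[0], left, tau, title=titles[0])
    _draw(axes[1], right, tau, title=titles[1])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
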