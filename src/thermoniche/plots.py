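"""Static result figures: growth curves, feeding-rate distributions and
consumption, one layout per result block of the scenario comparison."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_COLORS = {"assumed": "#1f77b4", "observed": "#ff7f0e"}
# strip the Software tag so reruns produce byte-identical PNGs
_META = {"metadata": {"Software": None}}


def growth_figure(results, path: str | Path) -> None:
    """Weight achieved per age under each scenario (one panel per species)."""
    fig, axes = plt.subplots(1, len(results), figsize=(5 * len(results), 4))
    axes = np.atleast_1d(axes)
    for ax, r in zip(axes, results):
        c = r.comparison
        ages = [s.age + 1 for s in c.observed_trajectory.age_summaries]
        ax.plot(
            [c.observed_trajectory.age_summaries[0].age] + ages,
            [c.observed_trajectory.age_summaries[0].start_weight]
            + [s.end_weight for s in c.observed_trajectory.age_summaries],
            "o-", color=_COLORS["observed"], label="observed occupancy",
        )
        ax.plot(
            [c.projected_trajectory.age_summaries[0].age] + ages,
            [c.projected_trajectory.age_summaries[0].start_weight]
            + [s.end_weight for s in c.projected_trajectory.age_summaries],
            "s-", color=_COLORS["assumed"], label="assumed occupancy",
        )
        ax.set_xlabel("age (years)")
        ax.set_ylabel("weight (g)")
        ax.set_title(c.species)
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100, **_META)
    plt.close(fig)


def feeding_rate_figure(results, path: str | Path) -> None:
    """Distributions of per-age fitted feeding rates (p) per scenario."""
    fig, ax = plt.subplots(figsize=(6, 4))
    data, labels, colors = [], [], []
    for r in results:
        c = r.comparison
        for key, arr in (("assumed", c.p_assumed), ("observed", c.p_observed)):
            data.append(arr)
            labels.append(f"{c.species}\n{key}")
            colors.append(_COLORS[key])
    bp = ax.boxplot(data, tick_labels=labels, patch_artist=True, showmeans=True)
    for patch, color in zip(bp["boxes"], colors):
        patch.set_facecolor(color)
        patch.set_alpha(0.5)
    ax.set_ylabel("feeding rate p (fraction of Cmax)")
    fig.tight_layout()
    fig.savefig(path, dpi=100, **_META)
    plt.close(fig)


def consumption_figure(results, path: str | Path) -> None:
    """Daily age-specific consumption per scenario plus lifetime totals."""
    n = len(results)
    fig, axes = plt.subplots(1, n + 1, figsize=(5 * (n + 1), 4))
    axes = np.atleast_1d(axes)
    for ax, r in zip(axes[:n], results):
        c = r.comparison
        days = np.arange(1, 366)
        ax.plot(days, c.daily_C_observed, color=_COLORS["observed"], label="observed")
        ax.plot(days, c.daily_C_assumed, color=_COLORS["assumed"], label="assumed")
        ax.set_xlabel("simulation day")
        ax.set_ylabel("consumption (g/g/d)")
        ax.set_title(f"{c.species}: adult-year daily consumption")
        ax.legend(frameon=False)
    ax = axes[-1]
    width = 0.35
    x = np.arange(n)
    asm = [r.comparison.lifetime_consumption_assumed_kg for r in results]
    obs = [r.comparison.lifetime_consumption_observed_kg for r in results]
    ax.bar(x - width / 2, asm, width, color=_COLORS["assumed"], label="assumed")
    ax.bar(x + width / 2, obs, width, color=_COLORS["observed"], label="observed")
    ax.set_xticks(x)
    ax.set_xticklabels([r.comparison.species for r in results])
    ax.set_ylabel("lifetime consumption (kg)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100, **_META)
    plt.close(fig)
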