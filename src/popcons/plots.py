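"""Matplotlib figures for the pipeline reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .ne import NeTrajectory
from .structure import PcoaResult


def plot_pcoa(result: PcoaResult, localities: dict[str, str], path: str | Path) -> None:
    """Scatter of the first two principal coordinates, coloured by locality."""
    fig, ax = plt.subplots(figsize=(6, 5))
    coords = result.coordinates
    groups: dict[str, list[str]] = {}
    for sid in coords.index:
        groups.setdefault(localities.get(sid, "unknown"), []).append(sid)
    for loc, sids in sorted(groups.items()):
        sub = coords.loc[sids]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], label=loc, s=30, alpha=0.8)
    ax.set_xlabel(f"PCo1 ({result.percent_variance[0]:.1f}%)")
    ax.set_ylabel(f"PCo2 ({result.percent_variance[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ne_trajectories(
    trajectories: dict[str, NeTrajectory], path: str | Path, max_years: float | None = 100.0
) -> None:
    """Ne-versus-time lines per population, with bootstrap envelopes if present."""
    fig, ax = plt.subplots(figsize=(6.5, 5))
    for name, traj in trajectories.items():
        tab = traj.table.sort_values("t_years")
        if max_years is not None:
            tab = tab[tab["t_years"] <= max_years]
        if tab.empty:
            continue
        (line,) = ax.plot(tab["t_years"], tab["Ne"], marker="o", label=name)
        if traj.replicates:
            env = traj.envelope().sort_values("t_years")
            if max_years is not None:
                env = env[env["t_years"] <= max_years]
            ax.fill_between(
                env["t_years"], env["min"], env["max"], alpha=0.2, color=line.get_color()
            )
    ax.set_xlabel("years before sampling")
    ax.set_ylabel("estimated Ne")
    ax.invert_xaxis()
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(table: pd.DataFrame, path: str | Path) -> None:
    """Mean proportion of alleles covered at each budget (point per configuration)."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    per_budget = table.groupby("budget")["mean_proportion_of_alleles"].first()
    ax.plot(per_budget.index, 100 * per_budget.values, marker="o")
    ax.set_xlabel("number of populations conserved (budget)")
    ax.set_ylabel("% of alleles covered")
    ax.set_ylim(0, 100)
    ax.set_xticks(list(per_budget.index))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
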