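"""Figure helpers: clustered heatmaps and score-trajectory envelopes."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_clustermap(profile_matrix: pd.DataFrame, path, **kwargs):
    """Seaborn clustermap of compound x (group, time) temporal profiles,
    Euclidean distance with Ward linkage on both axes."""
    import seaborn as sns

    grid = sns.clustermap(profile_matrix, method="ward", metric="euclidean",
                          cmap="vlag", center=0, **kwargs)
    grid.savefig(path, dpi=150)
    plt.close(grid.fig)
    return path


def plot_score_trajectories(score_ci: pd.DataFrame, path, component: str = "PC1"):
    """Group score trajectories with shaded bootstrap envelopes."""
    sub = score_ci[score_ci["component"] == component]
    fig, ax = plt.subplots(figsize=(6, 4))
    for group, block in sub.groupby("group"):
        block = block.sort_values("time_h")
        ax.plot(block["time_h"], block["point"], marker="o", label=str(group))
        ax.fill_between(block["time_h"], block["lower"], block["upper"], alpha=0.25)
    ax.set_xlabel("fermentation time (h)")
    ax.set_ylabel(f"{component} score")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_loading_ranking(ranked: pd.DataFrame, path):
    """Horizontal bar chart of the top/bottom loadings on one component."""
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(ranked) + 1))
    ordered = ranked.sort_values("loading")
    colors = ["tab:blue" if d == "bottom" else "tab:orange"
              for d in ordered["direction"]]
    ax.barh(ordered["variable"], ordered["loading"], color=colors)
    ax.axvline(0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("loading")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
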