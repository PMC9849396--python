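"""Convenience figures for pipeline outputs. CSVs are the contract; these
are quick-look plots in the style of a gap-analysis report: network growth
panels, representation trajectories by group, and observed-vs-null
randomization dots per decade."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

GROUP_COLORS = {
    "bird": "tab:blue",
    "mammal": "tab:orange",
    "amphibian": "tab:green",
    "reptile": "tab:red",
    "plant": "tab:olive",
    "threatened": "black",
    "non_threatened": "gray",
}


def plot_network_growth(series: pd.DataFrame, path: str | Path) -> None:
    """Three panels: cumulative % protected, area added per decade, and
    mean elevation of the PAs declared each decade."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    x = np.arange(len(series))
    axes[0].plot(x, series["cumulative_pct_protected"], "o-")
    axes[0].set_ylabel("% of study area protected")
    axes[1].bar(x, series["area_added_km2"])
    axes[1].set_ylabel("area added (km²)")
    axes[2].plot(x, series["mean_elevation_m"], "o-")
    axes[2].set_ylabel("mean PA elevation (m)")
    for ax in axes:
        ax.set_xticks(x)
        ax.set_xticklabels(series["cohort"], rotation=60, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_representation_trajectories(
    summaries: pd.DataFrame, path: str | Path
) -> None:
    """Percent of species meeting targets per stratum over snapshots, with
    climate-scenario endpoints to the right."""
    cur = summaries[summaries["scenario"] == "current"]
    fut = summaries[summaries["scenario"] != "current"]
    fig, ax = plt.subplots(figsize=(7, 4))
    for stratum, sub in cur.groupby("stratum"):
        sub = sub.sort_values("snapshot_year")
        style = ":" if stratum in ("threatened", "non_threatened") else "-"
        ax.plot(
            sub["snapshot_year"],
            sub["percent_met"],
            style,
            marker="o",
            ms=3,
            color=GROUP_COLORS.get(stratum, "purple"),
            label=stratum,
        )
    if not fut.empty:
        x0 = cur["snapshot_year"].max()
        for k, (scenario, sub) in enumerate(sorted(fut.groupby("scenario"))):
            x = x0 + 10 * (k + 1)
            for _, row in sub.iterrows():
                ax.plot(
                    [x],
                    [row["percent_met"]],
                    "s",
                    ms=4,
                    color=GROUP_COLORS.get(row["stratum"], "purple"),
                )
            ax.text(x, -4, scenario, ha="center", fontsize=7)
    ax.set_xlabel("network snapshot (end year)")
    ax.set_ylabel("% of species meeting targets")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_randomization(results: pd.DataFrame, path: str | Path) -> None:
    """Observed representation (open circles; red = significant) against
    the null mean and 95th percentile per cohort and stratum."""
    strata = sorted(results["stratum"].unique())
    fig, axes = plt.subplots(
        len(strata), 1, figsize=(7, 1.6 * len(strata)), sharex=True
    )
    if len(strata) == 1:
        axes = [axes]
    for ax, stratum in zip(axes, strata):
        sub = results[results["stratum"] == stratum].reset_index(drop=True)
        x = np.arange(len(sub))
        ax.vlines(x, sub["null_mean"], sub["null_q95"], color="green", alpha=0.6)
        colors = ["red" if s else "black" for s in sub["significant"]]
        ax.scatter(
            x, sub["observed"], facecolors="none", edgecolors=colors, zorder=3
        )
        ax.set_ylabel(stratum, fontsize=7)
        ax.set_xticks(x)
        labels = [
            f"{c}\n{s}" if s != "current" else c
            for c, s in zip(sub["cohort"], sub["scenario"])
        ]
        ax.set_xticklabels(labels, fontsize=6, rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
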