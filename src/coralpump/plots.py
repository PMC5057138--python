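"""Optional matplotlib figures: sections, deposition scatter, extrema series."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import VelocityExtrema

__all__ = ["plot_section", "plot_deposition_vs_depth", "plot_extrema"]


def plot_section(section: pd.DataFrame, path: str | Path, label: str = "value",
                 cmap: str = "viridis") -> None:
    """Scatter-style vertical section (distance vs depth, coloured by value)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    sc = ax.scatter(section["distance"] / 1e3, section["depth"],
                    c=section["value"], s=8, cmap=cmap)
    floor = section.drop_duplicates("distance").sort_values("distance")
    ax.plot(floor["distance"] / 1e3, floor["seafloor"], "k-", lw=1)
    ax.invert_yaxis()
    ax.set_xlabel("distance (km)")
    ax.set_ylabel("depth (m)")
    fig.colorbar(sc, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_deposition_vs_depth(table: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"off_reef": "0.6", "coral_mound": "tab:red", "coral_ridge": "tab:orange"}
    for cls, sub in table.groupby("habitat_class"):
        ax.scatter(sub["depth"], sub["deposition"], s=10,
                   color=colors.get(cls, "k"), label=cls)
    ax.set_xlabel("water depth (m)")
    ax.set_ylabel("deposition (mmol C m$^{-2}$ d$^{-1}$)")
    ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_extrema(extrema: VelocityExtrema, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(extrema.times, extrema.max_upwelling, "r-", label="max upwelling")
    ax.plot(extrema.times, -extrema.max_downwelling, "b-", label="max downwelling")
    ax.set_xlabel("time (d)")
    ax.set_ylabel("w (m s$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
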