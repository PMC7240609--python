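"""Scan heatmaps and variance-profile figures.

The scan heatmap mirrors the field's convention: one row per date, radii on
the x axis, cell colour a blue-white-red gradient of the Pearson r with
non-significant cells blanked to white, so the scale(s) of effect stand out
as coloured bands.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def scan_heatmap(
    scan: pd.DataFrame, index: str, out: str | Path | None = None, alpha: float = 0.05
):
    """Significance-banded correlation strip for one index.

    Rows are dates, columns the buffer radii; colour encodes r in [-1, 1]
    (blue negative, red positive), white where p >= alpha or undefined.
    """
    sub = scan[scan["index"] == index]
    dates = sorted(sub["date"].unique())
    radii = sorted(sub["radius_m"].unique())
    grid = np.full((len(dates), len(radii)), np.nan)
    for i, d in enumerate(dates):
        for j, r in enumerate(radii):
            cell = sub[(sub["date"] == d) & (sub["radius_m"] == r)]
            if len(cell) == 1 and bool(cell["significant"].iloc[0]):
                grid[i, j] = cell["r"].iloc[0]
    fig, ax = plt.subplots(figsize=(10, 0.8 + 0.5 * len(dates)))
    cmap = plt.get_cmap("bwr").copy()
    cmap.set_bad("white")
    im = ax.imshow(
        np.ma.masked_invalid(grid), cmap=cmap, vmin=-1, vmax=1, aspect="auto",
        interpolation="nearest",
    )
    ax.set_yticks(range(len(dates)), dates)
    step = max(1, len(radii) // 12)
    ax.set_xticks(range(0, len(radii), step), [f"{radii[k]:.0f}" for k in range(0, len(radii), step)])
    ax.set_xlabel("buffer radius (m)")
    ax.set_title(f"{index}: abundance correlation by scale (white = p >= {alpha})")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
        return None
    return fig


def variance_profile_plot(profile: pd.DataFrame, out: str | Path | None = None):
    """Across-site variance of each index's buffer mean vs radius, per date."""
    fig, ax = plt.subplots(figsize=(8, 5))
    for (index, date), grp in profile.groupby(["index", "date"]):
        grp = grp.sort_values("radius_m")
        ax.plot(grp["radius_m"], grp["variance"], label=f"{index} {date}", alpha=0.8)
    ax.set_xlabel("buffer radius (m)")
    ax.set_ylabel("across-site variance of buffer mean")
    ax.set_yscale("log")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=120)
        plt.close(fig)
        return None
    return fig
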