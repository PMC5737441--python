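"""Simple static figures: smoothed-F_ST window scans and PC scores."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_windows(windows: pd.DataFrame, path: str | Path, alpha: float = 0.05) -> None:
    """One panel per linkage group: smoothed F_ST against cM position,
    significant windows (boot_p <= alpha) highlighted."""
    groups = list(windows.groupby("linkage_group", sort=False))
    if not groups:
        return
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(8, 2.2 * len(groups)), squeeze=False, sharex=False
    )
    for ax, (lg, grp) in zip(axes.ravel(), groups):
        filled = grp[grp.n_loci > 0]
        ax.plot(filled.center_cM, filled.smoothed_fst, color="0.3", lw=1)
        if "boot_p" in grp.columns:
            sig = filled[filled.boot_p <= alpha]
            ax.scatter(sig.center_cM, sig.smoothed_fst, color="crimson", s=12, zorder=3)
        ax.set_ylabel("smoothed $F_{ST}$")
        ax.set_title(str(lg), fontsize=9)
    axes.ravel()[-1].set_xlabel("position (cM)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pc_scores(
    pc_scores: pd.DataFrame,
    path: str | Path,
    labels: dict[str, str] | None = None,
) -> None:
    """PC1 x PC2 scatter (PC1 alone if only one component), colored by
    population label when provided."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = pc_scores["PC1"]
    y = pc_scores["PC2"] if "PC2" in pc_scores.columns else pd.Series(0.0, index=pc_scores.index)
    if labels:
        groups = pd.Series([labels.get(i, "?") for i in pc_scores["individual"]])
        for name, idx in groups.groupby(groups).groups.items():
            ax.scatter(x.iloc[idx], y.iloc[idx], s=10, label=str(name), alpha=0.8)
        ax.legend(fontsize=6, markerscale=1.5, frameon=False)
    else:
        ax.scatter(x, y, s=10, color="0.3")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2" if "PC2" in pc_scores.columns else "")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = ["plot_windows", "plot_pc_scores"]
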