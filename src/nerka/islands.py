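"""Kernel-smoothed sliding-window F_ST along a linkage map, a two-stage
bootstrap null, island calling and outlier-overlap annotation.

Windows of 5 cM advance in 1 cM steps along each linkage group; loci in
a window are weighted by a Gaussian kernel centered on the window with
``sigma = (window/2) / 3``, so weight has effectively decayed (about
0.011) at the window edge.  The null resamples member counts from the
genome-wide pool of defined per-locus theta values, re-applying the
window's actual weights; windows whose observed statistic falls above
the 90th percentile of all observed window statistics are re-evaluated
with a larger number of replicates.  Maximal runs of consecutive
significant windows become islands, labelled ``<LG>_<ordinal>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import LinkageMap


def smooth_fst(
    locus_theta: pd.DataFrame,
    lmap: LinkageMap,
    window_cM: float = 5.0,
    step_cM: float = 1.0,
) -> pd.DataFrame:
    """Gaussian-kernel-smoothed per-window theta.

    ``locus_theta`` needs columns ``locus_id`` and ``theta``; only mapped
    loci with a defined (finite) theta participate.  Windows are centered
    every ``step_cM`` from the first to the last mapped position on each
    linkage group; empty windows are recorded with ``n_loci = 0`` and no
    statistic.  Returns columns linkage_group, center_cM, n_loci,
    smoothed_fst, member_loci.
    """
    if window_cM <= 0 or step_cM <= 0:
        raise ValueError("window and step must be positive")
    sigma = (window_cM / 2.0) / 3.0
    half = window_cM / 2.0
    theta_of = dict(zip(locus_theta["locus_id"], locus_theta["theta"]))
    rows = []
    for lg in lmap.linkage_groups():
        mapped = [
            (lid, cm)
            for lid, cm in lmap.loci_on(lg)
            if lid in theta_of and np.isfinite(theta_of[lid])
        ]
        if not mapped:
            continue
        lids = np.array([lid for lid, _ in mapped])
        pos = np.array([cm for _, cm in mapped])
        th = np.array([theta_of[lid] for lid in lids])
        lo, hi = pos.min(), pos.max()
        n_steps = int(np.floor((hi - lo) / step_cM + 1e-9))
        centers = lo + step_cM * np.arange(n_steps + 1)
        for center in centers:
            d = pos - center
            inside = np.abs(d) <= half + 1e-12
            if inside.any():
                w = np.exp(-(d[inside] ** 2) / (2.0 * sigma**2))
                val = float((w * th[inside]).sum() / w.sum())
                rows.append(
                    {
                        "linkage_group": lg,
                        "center_cM": float(center),
                        "n_loci": int(inside.sum()),
                        "smoothed_fst": val,
                        "member_loci": ",".join(lids[inside]),
                    }
                )
            else:
                rows.append(
                    {
                        "linkage_group": lg,
                        "center_cM": float(center),
                        "n_loci": 0,
                        "smoothed_fst": np.nan,
                        "member_loci": "",
                    }
                )
    return pd.DataFrame(
        rows, columns=["linkage_group", "center_cM", "n_loci", "smoothed_fst", "member_loci"]
    )


def _window_weights(
    windows: pd.DataFrame, lmap: LinkageMap, window_cM: float
) -> list[np.ndarray]:
    """Recover each window's Gaussian weights from its member positions."""
    sigma = (window_cM / 2.0) / 3.0
    out = []
    for _, row in windows.iterrows():
        if row["n_loci"] == 0:
            out.append(np.empty(0))
            continue
        members = row["member_loci"].split(",")
        d = np.array([lmap.position[l][1] for l in members]) - row["center_cM"]
        out.append(np.exp(-(d**2) / (2.0 * sigma**2)))
    return out


def bootstrap_window_p(
    windows: pd.DataFrame,
    theta_pool: np.ndarray,
    lmap: LinkageMap,
    window_cM: float = 5.0,
    B1: int = 1000,
    escalate_quantile: float = 0.90,
    B2: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach a bootstrap p-value to every non-empty window.

    For each window, ``n_loci`` values are resampled with replacement from
    the genome-wide pool of defined theta values and combined with the
    window's actual kernel weights, ``B1`` times; windows whose observed
    statistic exceeds the ``escalate_quantile`` of all observed window
    statistics are re-evaluated with ``B2`` fresh replicates.  The
    add-one estimator ``(1 + #{resampled >= observed}) / (B + 1)`` avoids
    zero p-values.
    """
    theta_pool = np.asarray(theta_pool, dtype=float)
    theta_pool = theta_pool[np.isfinite(theta_pool)]
    if theta_pool.size == 0:
        raise ValueError("empty theta pool")
    windows = windows.copy().reset_index(drop=True)
    obs = windows["smoothed_fst"].to_numpy()
    nonempty = windows["n_loci"].to_numpy() > 0
    cutoff = (
        np.quantile(obs[nonempty], escalate_quantile) if nonempty.any() else np.inf
    )
    weights = _window_weights(windows, lmap, window_cM)
    rng = np.random.default_rng(seed)
    boot_p = np.full(len(windows), np.nan)
    boot_B = np.zeros(len(windows), dtype=int)
    for i in range(len(windows)):
        if not nonempty[i]:
            continue
        w = weights[i]
        B = B2 if obs[i] >= cutoff else B1
        draws = rng.choice(theta_pool, size=(B, w.size), replace=True)
        stat = draws @ w / w.sum()
        # tolerance so exact ties (e.g. a constant pool) count as exceedances
        tol = 1e-12 * max(1.0, abs(obs[i]))
        boot_p[i] = (1.0 + (stat >= obs[i] - tol).sum()) / (B + 1.0)
        boot_B[i] = B
    windows["boot_p"] = boot_p
    windows["boot_B"] = boot_B
    return windows


@dataclass
class IslandCall:
    """A maximal run of consecutive significant smoothed-F_ST windows."""

    island_id: str
    linkage_group: str
    start_cM: float
    end_cM: float
    n_windows: int
    min_boot_p: float
    member_loci: list[str]
    provisional: bool = False  # single-window call below min_windows
    outliers_inside: list[str] = field(default_factory=list)


def call_islands(
    windows: pd.DataFrame,
    alpha: float = 0.05,
    min_windows: int = 4,
    window_cM: float = 5.0,
) -> list[IslandCall]:
    """Merge maximal runs of consecutive significant windows (boot_p <=
    alpha) on a linkage group into islands.

    Island extent = outermost significant window centers +/- window/2.
    Runs shorter than ``min_windows`` are still reported but labelled
    provisional; the default of 4 demands support from more than one
    locus, since a single high locus can carry at most ~3 consecutive
    windows above threshold given the kernel's 2.5 cM truncation.
    Islands are named ``<LG>_<ordinal>`` in position order.
    """
    if "boot_p" not in windows.columns:
        raise ValueError("windows need bootstrap p-values; run bootstrap_window_p first")
    calls: list[IslandCall] = []
    half = window_cM / 2.0
    for lg, grp in windows.groupby("linkage_group", sort=False):
        grp = grp.sort_values("center_cM").reset_index(drop=True)
        sig = (grp["n_loci"] > 0) & (grp["boot_p"] <= alpha)
        runs: list[tuple[int, int]] = []
        start = None
        for i, s in enumerate(sig):
            if s and start is None:
                start = i
            elif not s and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(grp) - 1))
        ordinal = 0
        for lo, hi in runs:
            ordinal += 1
            seg = grp.iloc[lo : hi + 1]
            members: list[str] = []
            for m in seg["member_loci"]:
                for lid in str(m).split(","):
                    if lid and lid not in members:
                        members.append(lid)
            calls.append(
                IslandCall(
                    island_id=f"{lg}_{ordinal}",
                    linkage_group=str(lg),
                    start_cM=float(seg["center_cM"].iloc[0] - half),
                    end_cM=float(seg["center_cM"].iloc[-1] + half),
                    n_windows=len(seg),
                    min_boot_p=float(seg["boot_p"].min()),
                    member_loci=members,
                    provisional=len(seg) < min_windows,
                )
            )
    return calls


def annotate_island_outliers(
    islands: list[IslandCall],
    outlier_records: pd.DataFrame,
    lmap: LinkageMap,
) -> tuple[list[IslandCall], dict]:
    """Attach mapped flagged outliers falling inside each island's closed
    interval, and summarize: fraction of mapped flagged outliers inside
    any island, and the maximum number of outliers in one island."""
    flagged = outlier_records[outlier_records["flagged"].astype(bool)]
    flagged_loci = sorted(set(flagged["locus_id"]))
    mapped_flagged = [l for l in flagged_loci if l in lmap]
    inside_any: set[str] = set()
    for isl in islands:
        isl.outliers_inside = []
        for lid in mapped_flagged:
            lg, cm = lmap.position[lid]
            if lg == isl.linkage_group and isl.start_cM <= cm <= isl.end_cM:
                isl.outliers_inside.append(lid)
                inside_any.add(lid)
    summary = {
        "n_flagged_outliers": len(flagged_loci),
        "n_mapped_flagged_outliers": len(mapped_flagged),
        "n_outliers_in_islands": len(inside_any),
        "fraction_mapped_outliers_in_islands": (
            len(inside_any) / len(mapped_flagged) if mapped_flagged else float("nan")
        ),
        "max_outliers_per_island": max(
            (len(isl.outliers_inside) for isl in islands), default=0
        ),
    }
    return islands, summary


def islands_to_frame(islands: list[IslandCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "island_id": isl.island_id,
                "linkage_group": isl.linkage_group,
                "start_cM": isl.start_cM,
                "end_cM": isl.end_cM,
                "n_windows": isl.n_windows,
                "min_boot_p": isl.min_boot_p,
                "provisional": isl.provisional,
                "member_loci": ",".join(isl.member_loci),
                "outliers_inside": ",".join(isl.outliers_inside),
            }
            for isl in islands
        ],
        columns=[
            "island_id", "linkage_group", "start_cM", "end_cM", "n_windows",
            "min_boot_p", "provisional", "member_loci", "outliers_inside",
        ],
    )


__all__ = [
    "smooth_fst",
    "bootstrap_window_p",
    "call_islands",
    "annotate_island_outliers",
    "islands_to_frame",
    "IslandCall",
]
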