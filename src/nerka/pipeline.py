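"""End-to-end orchestration: simulate/load -> QC -> statistics ->
outlier scans -> islands -> report.

Two dataset tracks are maintained after QC, mirroring standard RADseq
practice: the *outlier track* keeps multiple SNPs per RAD tag (so no
informative site is lost in the scans), while the *neutral track* thins
to one SNP per tag and removes every locus flagged by any outlier test
(union over methods and comparisons) before diversity, F_ST and Ne
estimation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from . import qc
from .islands import (
    annotate_island_outliers,
    bootstrap_window_p,
    call_islands,
    islands_to_frame,
    smooth_fst,
)
from .outliers import comparison_theta, pca_scan, perm_fst_outliers, shared_outlier_ledger
from .plots import plot_pc_scores, plot_windows
from .simulate import SimParams, simulate_panel, study_design_params
from .stats import locus_pop_summary, ne_ld, pairwise_fst_matrix, wc_theta
from .types import ComparisonSpec, GenotypeMatrix, LinkageMap, SampleTable


def percent_summary(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-even to ``decimals``
    decimal places — the arithmetic used throughout the run report."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_EVEN))


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``sim_params`` (synthetic input) or ``genepop_path``
    (file input, with ``samples_path`` and optionally ``map_path``) must
    be set.
    """

    out_dir: str = "nerka_run"
    seed: int = 0
    # inputs
    sim_params: SimParams | None = None
    genepop_path: str | None = None
    samples_path: str | None = None
    map_path: str | None = None
    comparisons_path: str | None = None
    comparisons: list[ComparisonSpec] = field(default_factory=list)
    # filters
    min_locus_call: float = 0.8
    min_maf: float = 0.05
    hwe_fdr: float = 0.05
    hwe_min_pops: int = 3
    min_ind_call: float = 0.5
    # outliers
    n_perm: int = 999
    q_threshold: float = 0.2
    pca_k: int | str = "auto"
    # islands
    window_cM: float = 5.0
    step_cM: float = 1.0
    boot_b1: int = 1000
    boot_b2: int = 10000
    escalate_quantile: float = 0.90
    island_alpha: float = 0.05
    island_min_windows: int = 4

    def __post_init__(self) -> None:
        if (self.sim_params is None) == (self.genepop_path is None):
            raise ValueError("exactly one of sim_params or genepop_path must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim_params" in raw and raw["sim_params"] is not None:
            sp = raw.pop("sim_params")
            if isinstance(sp, dict):
                base = sp.pop("study_design", True)
                if base:
                    raw["sim_params"] = study_design_params(**sp)
                else:
                    raw["sim_params"] = SimParams(**sp)
        return cls(**raw)


def default_comparisons(samples: SampleTable) -> list[ComparisonSpec]:
    """Ecotype-pair contrasts derived from population attributes: one
    shore-vs-stream contrast per lake holding both, one kokanee-vs-
    anadromous contrast per catchment holding both, and the pooled
    all-shore vs all-stream contrast."""
    comps: list[ComparisonSpec] = []
    by_lake: dict[str, dict[str, set[str]]] = {}
    by_catch: dict[str, dict[str, set[str]]] = {}
    for pop, a in samples.pop_attrs.items():
        if pop not in samples.populations:
            continue
        if a.lake and a.reproductive_ecotype in ("shore", "stream"):
            by_lake.setdefault(a.lake, {}).setdefault(a.reproductive_ecotype, set()).add(pop)
        if a.catchment and a.migratory_ecotype in ("kokanee", "anadromous"):
            by_catch.setdefault(a.catchment, {}).setdefault(a.migratory_ecotype, set()).add(pop)
    for lake, sides in sorted(by_lake.items()):
        if "shore" in sides and "stream" in sides:
            comps.append(
                ComparisonSpec(f"{lake}_shore_vs_stream", frozenset(sides["shore"]),
                               frozenset(sides["stream"]))
            )
    for catch, sides in sorted(by_catch.items()):
        if "kokanee" in sides and "anadromous" in sides:
            comps.append(
                ComparisonSpec(f"{catch}_kokanee_vs_anadromous", frozenset(sides["kokanee"]),
                               frozenset(sides["anadromous"]))
            )
    all_shore = {p for p, a in samples.pop_attrs.items()
                 if p in samples.populations and a.reproductive_ecotype == "shore"}
    all_stream = {p for p, a in samples.pop_attrs.items()
                  if p in samples.populations and a.reproductive_ecotype == "stream"}
    if all_shore and all_stream:
        comps.append(
            ComparisonSpec("all_shore_vs_all_stream", frozenset(all_shore),
                           frozenset(all_stream))
        )
    return comps


@dataclass
class RunReport:
    stage_counts: list[dict]
    tag_snp_distribution: dict
    mapped_locus_percent: float | None
    population_table: pd.DataFrame
    outlier_counts: dict[str, int]
    sharing_histogram: dict[int, int]
    island_table: pd.DataFrame
    island_overlap_summary: dict
    notices: list[str]

    def reconcile(self) -> None:
        """Recompute every percentage from its integer counts and assert
        agreement — the report never carries a percentage its counts do
        not reproduce."""
        d = self.tag_snp_distribution
        total = d["n_tags"]
        if total:
            for k in (1, 2, 3):
                assert d[f"pct_tags_{k}_snp"] == percent_summary(
                    d[f"n_tags_{k}_snp"], total, 1
                )


def _tag_snp_distribution(gm: GenotypeMatrix) -> dict:
    sizes: dict[str, int] = {}
    for lid in gm.locus_ids:
        sizes[gm.tag_of_locus[lid]] = sizes.get(gm.tag_of_locus[lid], 0) + 1
    n_tags = len(sizes)
    counts = {k: sum(1 for v in sizes.values() if v == k) for k in (1, 2, 3)}
    out = {"n_snps": gm.n_loci, "n_tags": n_tags}
    for k in (1, 2, 3):
        out[f"n_tags_{k}_snp"] = counts[k]
        out[f"pct_tags_{k}_snp"] = (
            percent_summary(counts[k], n_tags, 1) if n_tags else float("nan")
        )
    return out


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all stage outputs under
    ``config.out_dir``.  Deterministic given the master seed: stage seeds
    are derived by fixed offsets."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    notices: list[str] = []
    t0 = time.time()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.time() - t0:8.2f}s] {msg}")

    seed = int(config.seed)
    stage_seed = {"simulate": seed, "perm": seed + 10_000, "boot": seed + 20_000}

    # ---- inputs ----------------------------------------------------------
    stage = "input"
    try:
        if config.sim_params is not None:
            params = config.sim_params
            gm, samples, lmap, truth = simulate_panel(params)
            nio.write_genepop(gm, samples, out / "input.genepop")
            nio.write_sample_attributes(samples, out / "input_samples.tsv")
            nio.write_linkage_map(lmap, out / "input_map.tsv")
            nio.write_records(truth, out / "truth.tsv")
            log(f"simulated panel: {gm.n_individuals} individuals x {gm.n_loci} loci")
        else:
            gm, skeleton = nio.read_genepop(config.genepop_path)
            samples = (
                nio.read_sample_attributes(config.samples_path)
                if config.samples_path
                else skeleton
            )
            lmap = (
                nio.read_linkage_map(config.map_path) if config.map_path else LinkageMap()
            )
            log(f"loaded panel: {gm.n_individuals} individuals x {gm.n_loci} loci")
        samples.validate_against(gm)

        comparisons = list(config.comparisons)
        if config.comparisons_path:
            comparisons.extend(nio.read_comparisons(config.comparisons_path))
        if not comparisons:
            comparisons = default_comparisons(samples)
        log(f"comparisons: {[c.label for c in comparisons]}")

        # ---- QC ----------------------------------------------------------
        stage = "qc"
        gm_f, freport = qc.apply_standard_filters(
            gm,
            samples,
            min_locus_call=config.min_locus_call,
            min_maf=config.min_maf,
            hwe_fdr=config.hwe_fdr,
            hwe_min_pops=config.hwe_min_pops,
            min_ind_call=config.min_ind_call,
            one_snp_per_tag=False,
        )
        samples_f = samples.restrict(gm_f.individual_ids)
        nio.write_records(pd.DataFrame(freport.stage_counts), out / "filter_report.tsv")
        nio.write_genepop(gm_f, samples_f, out / "filtered.genepop")
        for line in freport.stage_counts:
            log(
                f"filter {line['stage']}: {line['loci_before']} -> {line['loci_after']} loci, "
                f"{line['individuals_before']} -> {line['individuals_after']} individuals"
            )

        # ---- outlier scans (multi-SNP-per-tag track) ---------------------
        stage = "outliers"
        all_records = []
        outlier_counts: dict[str, int] = {}
        for k, cmp in enumerate(comparisons):
            rec = perm_fst_outliers(
                gm_f,
                samples_f,
                cmp,
                n_perm=config.n_perm,
                seed=stage_seed["perm"] + k,
                q_threshold=config.q_threshold,
            )
            all_records.append(rec)
            outlier_counts[f"{cmp.label}:perm_fst"] = int(rec["flagged"].sum())
        pca_records, pc_scores, pca_info = pca_scan(
            gm_f, K=config.pca_k, q_threshold=config.q_threshold
        )
        all_records.append(pca_records)
        outlier_counts["pca_global:pca_mahalanobis"] = int(pca_records["flagged"].sum())
        records = pd.concat(all_records, ignore_index=True)
        nio.write_records(records, out / "outlier_records.tsv")
        nio.write_records(pc_scores, out / "pc_scores.tsv")
        plot_pc_scores(pc_scores, out / "pc_scores.png", samples_f.pop_of_individual)
        ledger, hist = shared_outlier_ledger(records, samples_f, comparisons)
        nio.write_records(ledger, out / "shared_outlier_ledger.tsv")
        log(
            f"outliers: {int(records['flagged'].sum())} flags across "
            f"{len(comparisons)} comparisons + PCA (K={pca_info['K']})"
        )

        # ---- neutral track: one SNP per tag, outliers removed ------------
        stage = "neutral_stats"
        flagged_loci = set(records.loc[records["flagged"].astype(bool), "locus_id"])
        neutral_keep = [l for l in gm_f.locus_ids if l not in flagged_loci]
        gm_neutral = gm_f.subset_loci(neutral_keep)
        gm_neutral, _ = qc.first_snp_per_tag(gm_neutral)
        log(f"neutral track: {gm_neutral.n_loci} loci (one SNP per tag, outliers removed)")

        pop_rows = []
        for pop in samples_f.populations:
            summ = locus_pop_summary(gm_neutral, samples_f, pop)
            row = {
                "population": pop,
                "n_individuals": len(samples_f.individuals_of(pop)),
                "H_o": float(summ["H_o"].mean(skipna=True)),
                "H_e": float(summ["H_e"].mean(skipna=True)),
            }
            try:
                est = ne_ld(gm_neutral, samples_f, pop, maf_min=config.min_maf)
                row.update(
                    ne_point=est.ne_point, ne_ci_low=est.ci_low, ne_ci_high=est.ci_high
                )
            except ValueError as exc:
                row.update(ne_point=np.nan, ne_ci_low=np.nan, ne_ci_high=np.nan)
                notices.append(f"ne_ld skipped for {pop}: {exc}")
            pop_rows.append(row)
        pop_table = pd.DataFrame(pop_rows)
        nio.write_records(pop_table, out / "population_table.tsv")
        fst_matrix = pairwise_fst_matrix(gm_neutral, samples_f)
        fst_matrix.to_csv(out / "pairwise_fst.tsv", sep="\t", float_format="%.17g")
        _, global_theta = wc_theta(gm_neutral, samples_f)
        log(f"neutral multilocus theta (all populations): {global_theta:.4f}")

        # ---- islands ------------------------------------------------------
        stage = "islands"
        island_frames = []
        overlap_summary: dict = {}
        if len(lmap) == 0:
            notices.append("island stage skipped: no linkage map (0 loci mapped)")
            log("islands: skipped, no linkage map")
            island_table = islands_to_frame([])
        else:
            per_cmp_islands = []
            for k, cmp in enumerate(comparisons):
                ltheta = comparison_theta(gm_f, samples_f, cmp)
                windows = smooth_fst(
                    ltheta, lmap, window_cM=config.window_cM, step_cM=config.step_cM
                )
                if not len(windows):
                    notices.append(f"island scan for {cmp.label}: 0 loci mapped")
                    continue
                pool = ltheta["theta"].to_numpy()
                windows = bootstrap_window_p(
                    windows,
                    pool,
                    lmap,
                    window_cM=config.window_cM,
                    B1=config.boot_b1,
                    escalate_quantile=config.escalate_quantile,
                    B2=config.boot_b2,
                    seed=stage_seed["boot"] + k,
                )
                nio.write_records(windows, out / f"windows_{cmp.label}.tsv")
                plot_windows(windows, out / f"windows_{cmp.label}.png",
                             alpha=config.island_alpha)
                calls = call_islands(
                    windows,
                    alpha=config.island_alpha,
                    min_windows=config.island_min_windows,
                    window_cM=config.window_cM,
                )
                cmp_rec = records[records["comparison"] == cmp.label]
                calls, summary = annotate_island_outliers(calls, cmp_rec, lmap)
                frame = islands_to_frame(calls)
                frame.insert(0, "comparison", cmp.label)
                island_frames.append(frame)
                per_cmp_islands.append((cmp.label, summary))
                log(
                    f"islands {cmp.label}: {len(calls)} called "
                    f"({sum(not c.provisional for c in calls)} multi-window)"
                )
            island_table = (
                pd.concat(island_frames, ignore_index=True)
                if island_frames
                else islands_to_frame([])
            )
            overlap_summary = {label: s for label, s in per_cmp_islands}
            nio.write_records(island_table, out / "islands.tsv")

        # ---- report -------------------------------------------------------
        stage = "report"
        tag_dist = _tag_snp_distribution(gm_f)
        mapped_pct = (
            percent_summary(
                sum(1 for l in gm_f.locus_ids if l in lmap), gm_f.n_loci, 1
            )
            if len(lmap)
            else None
        )
        report = RunReport(
            stage_counts=freport.stage_counts,
            tag_snp_distribution=tag_dist,
            mapped_locus_percent=mapped_pct,
            population_table=pop_table,
            outlier_counts=outlier_counts,
            sharing_histogram=hist,
            island_table=island_table,
            island_overlap_summary=overlap_summary,
            notices=notices,
        )
        report.reconcile()
        _write_report_text(report, out / "report.txt", seed=seed)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        return report
    except Exception as exc:
        (out / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_report_text(report: RunReport, path: Path, seed: int) -> None:
    lines = [f"nerka run report (seed={seed})", ""]
    lines.append("== filtering ==")
    for s in report.stage_counts:
        lines.append(
            f"{s['stage']}: loci {s['loci_before']} -> {s['loci_after']}, "
            f"individuals {s['individuals_before']} -> {s['individuals_after']}"
        )
    d = report.tag_snp_distribution
    lines.append("")
    lines.append("== tag/SNP distribution (outlier track) ==")
    lines.append(f"{d['n_snps']} SNPs across {d['n_tags']} RAD tags")
    for k in (1, 2, 3):
        lines.append(
            f"tags with {k} SNP(s): {d[f'n_tags_{k}_snp']} ({d[f'pct_tags_{k}_snp']}%)"
        )
    if report.mapped_locus_percent is not None:
        lines.append(f"mapped loci: {report.mapped_locus_percent}%")
    lines.append("")
    lines.append("== per-population diversity and Ne ==")
    lines.append(report.population_table.to_string(index=False))
    lines.append("")
    lines.append("== outlier flags per comparison ==")
    for k, v in report.outlier_counts.items():
        lines.append(f"{k}: {v}")
    lines.append(f"sharing histogram (k comparisons -> loci): {report.sharing_histogram}")
    lines.append("")
    lines.append("== islands ==")
    if len(report.island_table):
        lines.append(report.island_table.to_string(index=False))
    else:
        lines.append("none called")
    for note in report.notices:
        lines.append(f"NOTE: {note}")
    path.write_text("\n".join(lines) + "\n")


__all__ = [
    "RunConfig",
    "RunReport",
    "run_all",
    "percent_summary",
    "default_comparisons",
]
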