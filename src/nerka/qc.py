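"""Locus and individual retention filters for RADseq SNP panels.

The retention rules mirror a standard RADseq QC recipe: loci genotyped
in >=80% of individuals, pooled minor allele frequency >=0.05, removal
of loci out of Hardy–Weinberg equilibrium (exact conditional test,
Benjamini–Hochberg FDR within each population, removed only when
significant in at least ``min_pops`` populations — a rule aimed at
paralogous sequence variants rather than single-population departures),
removal of individuals with <50% of loci called, and optional thinning
to the first SNP per RAD tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .types import GenotypeMatrix, SampleTable


@dataclass
class FilterReport:
    """Per-stage accounting of what each filter removed."""

    loci_removed_call_rate: list[str] = field(default_factory=list)
    loci_removed_maf: list[str] = field(default_factory=list)
    loci_removed_hwe: list[str] = field(default_factory=list)
    individuals_removed: list[str] = field(default_factory=list)
    loci_removed_tag_thinning: list[str] = field(default_factory=list)
    stage_counts: list[dict] = field(default_factory=list)

    def record(self, stage: str, before: tuple[int, int], after: tuple[int, int]) -> None:
        self.stage_counts.append(
            {
                "stage": stage,
                "individuals_before": before[0],
                "loci_before": before[1],
                "individuals_after": after[0],
                "loci_after": after[1],
            }
        )


def filter_locus_call_rate(
    gm: GenotypeMatrix, min_fraction: float = 0.8
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep loci genotyped in >= ``min_fraction`` of individuals (inclusive)."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    frac = gm.called().mean(axis=0)
    keep_mask = frac >= min_fraction
    removed = [lid for lid, k in zip(gm.locus_ids, keep_mask) if not k]
    keep = [lid for lid, k in zip(gm.locus_ids, keep_mask) if k]
    return gm.subset_loci(keep), removed


def filter_individual_call_rate(
    gm: GenotypeMatrix, min_fraction: float = 0.5
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove individuals with a called-locus fraction strictly below
    ``min_fraction`` (an individual at exactly 50% is kept)."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    frac = gm.called().mean(axis=1)
    keep_mask = frac >= min_fraction
    removed = [iid for iid, k in zip(gm.individual_ids, keep_mask) if not k]
    keep = [iid for iid, k in zip(gm.individual_ids, keep_mask) if k]
    return gm.subset_individuals(keep), removed


def pooled_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per locus over all called genotypes pooled
    across populations.  Loci with zero calls raise."""
    called = gm.called()
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        bad = [lid for lid, n in zip(gm.locus_ids, n_called) if n == 0]
        raise ValueError(f"loci with zero called genotypes: {bad[:5]}")
    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    p = alt / (2.0 * n_called)
    return np.minimum(p, 1.0 - p)


def filter_maf(
    gm: GenotypeMatrix, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep loci with pooled MAF >= ``min_maf`` (inclusive boundary);
    monomorphic loci are always removed when ``min_maf`` > 0."""
    if not (0 <= min_maf < 0.5):
        raise ValueError("min_maf must lie in [0, 0.5)")
    maf = pooled_maf(gm)
    keep_mask = maf >= min_maf
    removed = [lid for lid, k in zip(gm.locus_ids, keep_mask) if not k]
    keep = [lid for lid, k in zip(gm.locus_ids, keep_mask) if k]
    return gm.subset_loci(keep), removed


@lru_cache(maxsize=100_000)
def _hwe_enumeration(n: int, n_minor: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """All heterozygote counts compatible with (n diploids, n_minor minor
    allele copies) and their exact conditional probabilities."""
    n_major = 2 * n - n_minor
    hets = tuple(range(n_minor % 2, min(n_minor, n_major) + 1, 2))
    logs = []
    for h in hets:
        n_aa = (n_minor - h) // 2
        n_AA = n - h - n_aa
        logs.append(
            gammaln(n + 1)
            - gammaln(n_AA + 1)
            - gammaln(h + 1)
            - gammaln(n_aa + 1)
            + h * np.log(2.0)
        )
    logs = np.array(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    return hets, tuple(probs)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value.

    Conditions on the diploid count and the minor-allele count, and sums
    the probabilities of all heterozygote configurations no more probable
    than the observed one (two-sided, probability ordering).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes to test")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets, probs = _hwe_enumeration(n, n_minor)
    p_obs = probs[hets.index(n_Aa)]
    probs = np.asarray(probs)
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), mapped
    back to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _genotype_counts(gm: GenotypeMatrix, mask: np.ndarray) -> np.ndarray:
    """(n_loci, 3) counts of AA/Aa/aa genotypes among individuals in mask."""
    sub = gm.dosage[mask]
    return np.stack([(sub == d).sum(axis=0) for d in (0, 1, 2)], axis=1)


def hwe_filter(
    gm: GenotypeMatrix,
    samples: SampleTable,
    fdr: float = 0.05,
    min_pops: int = 3,
    pooled: bool = False,
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove loci BH-significant for HWE departure in >= ``min_pops``
    populations.

    With ``pooled=False`` (default) the BH correction runs within each
    population across that population's per-locus p-values; with
    ``pooled=True`` one global vector across all population x locus tests
    is corrected instead.  A population with zero calls at a locus
    contributes p = 1 (no evidence).
    """
    pops = samples.populations
    n_pops = len(pops)
    pvals = np.ones((n_pops, gm.n_loci))
    for k, pop in enumerate(pops):
        mask = samples.members_mask(gm, [pop])
        if not mask.any():
            continue
        counts = _genotype_counts(gm, mask)
        for j in range(gm.n_loci):
            n_AA, n_Aa, n_aa = (int(c) for c in counts[j])
            if n_AA + n_Aa + n_aa == 0:
                continue
            pvals[k, j] = hwe_exact_p(n_AA, n_Aa, n_aa)
    if pooled:
        qvals = bh_adjust(pvals.ravel()).reshape(pvals.shape)
    else:
        qvals = np.vstack([bh_adjust(pvals[k]) for k in range(n_pops)])
    n_sig = (qvals <= fdr).sum(axis=0)
    keep_mask = n_sig < min_pops
    removed = [lid for lid, k in zip(gm.locus_ids, keep_mask) if not k]
    keep = [lid for lid, k in zip(gm.locus_ids, keep_mask) if k]
    return gm.subset_loci(keep), removed


def first_snp_per_tag(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Keep, per RAD tag, the locus with the smallest within-tag SNP
    offset (ties broken by locus id); all other loci are removed."""
    best: dict[str, str] = {}
    for lid in gm.locus_ids:
        tag = gm.tag_of_locus[lid]
        off = gm.snp_index_in_tag[lid]
        cur = best.get(tag)
        if cur is None or (off, lid) < (gm.snp_index_in_tag[cur], cur):
            best[tag] = lid
    keepers = set(best.values())
    keep = [lid for lid in gm.locus_ids if lid in keepers]
    removed = [lid for lid in gm.locus_ids if lid not in keepers]
    return gm.subset_loci(keep), removed


def apply_standard_filters(
    gm: GenotypeMatrix,
    samples: SampleTable,
    min_locus_call: float = 0.8,
    min_maf: float = 0.05,
    hwe_fdr: float = 0.05,
    hwe_min_pops: int = 3,
    min_ind_call: float = 0.5,
    one_snp_per_tag: bool = False,
    hwe_pooled: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """The fixed filter cascade: locus call rate -> MAF -> HWE ->
    individual call rate -> (optional) one SNP per tag."""
    report = FilterReport()

    def shape(g: GenotypeMatrix) -> tuple[int, int]:
        return (g.n_individuals, g.n_loci)

    before = shape(gm)
    gm, report.loci_removed_call_rate = filter_locus_call_rate(gm, min_locus_call)
    report.record("locus_call_rate", before, shape(gm))

    before = shape(gm)
    gm, report.loci_removed_maf = filter_maf(gm, min_maf)
    report.record("maf", before, shape(gm))

    before = shape(gm)
    gm, report.loci_removed_hwe = hwe_filter(
        gm, samples, fdr=hwe_fdr, min_pops=hwe_min_pops, pooled=hwe_pooled
    )
    report.record("hwe", before, shape(gm))

    before = shape(gm)
    gm, report.individuals_removed = filter_individual_call_rate(gm, min_ind_call)
    report.record("individual_call_rate", before, shape(gm))

    if one_snp_per_tag:
        before = shape(gm)
        gm, report.loci_removed_tag_thinning = first_snp_per_tag(gm)
        report.record("first_snp_per_tag", before, shape(gm))

    return gm, report


__all__ = [
    "FilterReport",
    "filter_locus_call_rate",
    "filter_individual_call_rate",
    "filter_maf",
    "pooled_maf",
    "hwe_exact_p",
    "bh_adjust",
    "hwe_filter",
    "first_snp_per_tag",
    "apply_standard_filters",
]
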