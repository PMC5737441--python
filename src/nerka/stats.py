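"""Diversity, differentiation, linkage disequilibrium and effective
population size.

Differentiation uses the Weir & Cockerham (1984) variance-components
estimator theta: per-locus components a (among populations), b (among
individuals within populations) and c (within individuals), with the
multilocus estimate the ratio of summed components.  LD uses the
Burrows composite disequilibrium on unphased dosages, with the
Hardy–Weinberg-departure-corrected denominator (equivalently the squared
sample correlation of dosage vectors).  Effective population size uses
the one-sample LD method: mean r-squared across unlinked locus pairs,
corrected for sample size by 1/S, mapped through Ne = 1/(3 (r2 - 1/S)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, SampleTable


# ---------------------------------------------------------------------------
# per-population locus summaries
# ---------------------------------------------------------------------------

def _pop_locus_aggregates(
    gm: GenotypeMatrix, samples: SampleTable, pops: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (population, locus): called diploid count n, alternate-allele
    frequency p (NaN where n = 0), observed heterozygote fraction h."""
    called = gm.called()
    alt = np.where(called, gm.dosage, 0)
    het = (gm.dosage == 1)
    P = len(pops)
    n = np.zeros((P, gm.n_loci))
    p = np.full((P, gm.n_loci), np.nan)
    h = np.zeros((P, gm.n_loci))
    for k, pop in enumerate(pops):
        mask = samples.members_mask(gm, [pop])
        n[k] = called[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = alt[mask].sum(axis=0) / (2.0 * n[k])
            h[k] = np.where(n[k] > 0, het[mask].sum(axis=0) / n[k], 0.0)
    return n, p, h


def locus_pop_summary(
    gm: GenotypeMatrix, samples: SampleTable, pop: str, unbiased: bool = True
) -> pd.DataFrame:
    """Per-locus allele frequency, call count, observed and expected
    heterozygosity within one population.

    ``unbiased=True`` applies Nei's small-sample correction
    ``H_e = 2 p (1-p) * 2n / (2n - 1)``; loci with zero calls are marked
    unavailable (NaN columns, ``available = False``).
    """
    if pop not in samples.populations:
        raise ValueError(f"unknown population {pop!r}")
    n, p, h = _pop_locus_aggregates(gm, samples, [pop])
    n, p, h = n[0], p[0], h[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 2.0 * p * (1.0 - p)
        if unbiased:
            he = np.where(n > 0, he * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0), np.nan)
    avail = n > 0
    return pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "p_hat": np.where(avail, p, np.nan),
            "n_called": n.astype(int),
            "H_o": np.where(avail, h, np.nan),
            "H_e": np.where(avail, he, np.nan),
            "available": avail,
        }
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def wc_components_from_aggregates(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components a, b, c from per-population
    aggregates.

    ``n, p, h`` have populations on axis 0 (any trailing shape); entries
    with ``n = 0`` are excluded.  Returns arrays of the trailing shape;
    components are NaN where fewer than two populations have calls or the
    mean sample size is <= 1.
    """
    n = np.asarray(n, dtype=float)
    p = np.where(n > 0, np.asarray(p, dtype=float), 0.0)
    h = np.where(n > 0, np.asarray(h, dtype=float), 0.0)
    present = n > 0
    r = present.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / n_tot
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / n_tot
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    invalid = (r < 2) | (nbar <= 1)
    for arr in (a, b, c):
        arr[invalid] = np.nan
    return a, b, c


def theta_from_components(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Per-locus theta = a / (a+b+c); NaN where the denominator is zero
    (locus monomorphic across the compared sample)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        return np.where(denom != 0, a / denom, np.nan)


def wc_theta(
    gm: GenotypeMatrix, samples: SampleTable, pops: list[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Locus-specific Weir–Cockerham components and theta over ``pops``
    (default: all populations), plus the multilocus ratio-of-sums theta.

    Negative estimates are preserved; loci with undefined components or a
    zero denominator are excluded from the multilocus sum.
    """
    if pops is None:
        pops = samples.populations
    pops = list(pops)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    n, p, h = _pop_locus_aggregates(gm, samples, pops)
    a, b, c = wc_components_from_aggregates(n, p, h)
    theta = theta_from_components(a, b, c)
    df = pd.DataFrame(
        {"locus_id": gm.locus_ids, "a": a, "b": b, "c": c, "theta": theta}
    )
    with np.errstate(invalid="ignore"):
        denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if not ok.any():
        multilocus = float("nan")
    else:
        multilocus = float(a[ok].sum() / denom[ok].sum())
    return df, multilocus


def two_group_theta(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> np.ndarray:
    """Vectorized per-locus theta for a two-group comparison (used by the
    permutation outlier scan); inputs broadcast over any shape."""
    n = np.stack([n1, n2])
    p = np.stack([p1, p2])
    h = np.stack([h1, h2])
    return theta_from_components(*wc_components_from_aggregates(n, p, h))


def pairwise_fst_matrix(gm: GenotypeMatrix, samples: SampleTable) -> pd.DataFrame:
    """Symmetric population x population multilocus theta matrix (zero
    diagonal, negative estimates preserved, within-pair monomorphic loci
    excluded)."""
    pops = samples.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for pop in pops:
        if not samples.members_mask(gm, [pop]).any():
            raise ValueError(f"population {pop!r} has no individuals in the matrix")
    n, p, h = _pop_locus_aggregates(gm, samples, pops)
    P = len(pops)
    out = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            a, b, c = wc_components_from_aggregates(
                n[[i, j]], p[[i, j]], h[[i, j]]
            )
            with np.errstate(invalid="ignore"):
                denom = a + b + c
            ok = np.isfinite(denom) & (denom != 0)
            val = float(a[ok].sum() / denom[ok].sum()) if ok.any() else np.nan
            out[i, j] = out[j, i] = val
    return pd.DataFrame(out, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# linkage disequilibrium and Ne
# ---------------------------------------------------------------------------

def _pairwise_r2_arrays(
    dosage: np.ndarray, min_pair_n: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Composite-LD r-squared between all locus pairs from a dosage block
    (individuals x loci, MISSING = -1), computed on pairwise-complete
    individuals.

    Returns (r2, valid, n_pair): (L, L) arrays; ``valid`` is False on the
    diagonal, for pairs with < ``min_pair_n`` complete individuals and
    pairs where either locus is monomorphic on the complete subset.
    """
    mask = (dosage >= 0).astype(float)
    X = np.where(dosage >= 0, dosage, 0).astype(float)
    X2 = X * X
    n = mask.T @ mask
    Sx = X.T @ mask  # Sx[i, j] = sum of dosages at locus i over pair-complete inds
    Sxy = X.T @ X
    Sxx = X2.T @ mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Sx / n
        my = Sx.T / n
        cov = Sxy / n - mx * my
        vx = Sxx / n - mx * mx
        vy = Sxx.T / n - my * my
        r2 = cov * cov / (vx * vy)
    valid = (n >= min_pair_n) & (vx > 1e-12) & (vy > 1e-12)
    np.fill_diagonal(valid, False)
    return r2, valid, n


def burrows_r2(
    gm: GenotypeMatrix,
    samples: SampleTable,
    pop: str,
    maf_min: float = 0.05,
    min_pair_n: int = 5,
) -> pd.DataFrame:
    """Pairwise composite-LD r-squared table within one population.

    Pairs where either locus is monomorphic or below ``maf_min`` in the
    population, or with fewer than ``min_pair_n`` pairwise-complete
    individuals, are flagged with a skip reason instead of a value.
    """
    mask = samples.members_mask(gm, [pop])
    if not mask.any():
        raise ValueError(f"population {pop!r} has no individuals")
    D = gm.dosage[mask].astype(np.int64)
    called = D >= 0
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(called, D, 0).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p_hat, 1.0 - p_hat)
    eligible = (n_called > 0) & (maf >= maf_min) & (maf > 0)
    r2, valid, n_pair = _pairwise_r2_arrays(D, min_pair_n=min_pair_n)
    rows = []
    L = gm.n_loci
    for i in range(L):
        for j in range(i + 1, L):
            if not (eligible[i] and eligible[j]):
                reason = "maf_below_min_or_fixed"
            elif n_pair[i, j] < min_pair_n:
                reason = "too_few_complete_pairs"
            elif not valid[i, j]:
                reason = "monomorphic_on_complete_subset"
            else:
                reason = ""
            rows.append(
                {
                    "locus_a": gm.locus_ids[i],
                    "locus_b": gm.locus_ids[j],
                    "n": int(n_pair[i, j]),
                    "r2": float(r2[i, j]) if not reason else np.nan,
                    "skipped": reason,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class NeEstimate:
    """LD-method effective population size for one population."""

    r2_mean: float
    r2_drift: float
    ne_point: float  # may be +inf
    ci_low: float
    ci_high: float  # may be +inf
    n_pairs: int
    n_loci: int
    sample_size: float


def _ne_from_r2(r2_mean: float, S: float) -> float:
    drift = r2_mean - 1.0 / S
    return 1.0 / (3.0 * drift) if drift > 0 else float("inf")


def ne_ld(
    gm: GenotypeMatrix,
    samples: SampleTable,
    pop: str,
    maf_min: float = 0.05,
    min_pair_n: int = 5,
) -> NeEstimate:
    """LD-method Ne: unweighted mean composite r-squared over all retained
    locus pairs, corrected by 1/S and mapped through Ne = 1/(3 r2_drift);
    a non-positive drift signal yields an infinite point estimate.
    Same-tag locus pairs are excluded (physical linkage), and the CI comes
    from a delete-one-locus jackknife on the mean r-squared mapped through
    the same formula.
    """
    mask = samples.members_mask(gm, [pop])
    if mask.sum() < 10:
        raise ValueError(f"population {pop!r} has fewer than 10 individuals")
    D = gm.dosage[mask].astype(np.int64)
    called = D >= 0
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(called, D, 0).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p_hat, 1.0 - p_hat)
    eligible = (n_called > 0) & (maf >= maf_min) & (maf > 0)
    if eligible.sum() < 2:
        raise ValueError("fewer than two polymorphic loci after the MAF screen")
    idx = np.flatnonzero(eligible)
    D = D[:, idx]
    tags = np.array([gm.tag_of_locus[gm.locus_ids[j]] for j in idx])
    r2, valid, n_pair = _pairwise_r2_arrays(D, min_pair_n=min_pair_n)
    same_tag = tags[:, None] == tags[None, :]
    valid &= ~same_tag
    iu = np.triu_indices(len(idx), k=1)
    use = valid[iu]
    if not use.any():
        raise ValueError("no eligible locus pairs")
    r2_vals = r2[iu][use]
    n_vals = n_pair[iu][use]
    r2_mean = float(r2_vals.mean())
    S = float(n_vals.mean())
    ne_point = _ne_from_r2(r2_mean, S)

    # delete-one-locus jackknife on the mean r2
    vr2 = np.where(valid, np.nan_to_num(r2, nan=0.0), 0.0)
    row_sum = vr2.sum(axis=1)  # counts each unordered pair once per member
    row_cnt = valid.sum(axis=1)
    total = r2_vals.sum()
    n_pairs = int(use.sum())
    part = row_cnt > 0
    loo_mean = (total - row_sum[part]) / np.maximum(n_pairs - row_cnt[part], 1)
    m = loo_mean.size
    if m > 1:
        se = float(np.sqrt((m - 1) / m * ((loo_mean - loo_mean.mean()) ** 2).sum()))
    else:
        se = 0.0
    ci_low = _ne_from_r2(r2_mean + 1.96 * se, S)
    ci_high = _ne_from_r2(r2_mean - 1.96 * se, S)
    if ci_low > ci_high:
        ci_low, ci_high = ci_high, ci_low
    ci_low = min(ci_low, ne_point)
    ci_high = max(ci_high, ne_point)
    return NeEstimate(
        r2_mean=r2_mean,
        r2_drift=r2_mean - 1.0 / S,
        ne_point=ne_point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_pairs=n_pairs,
        n_loci=int(len(idx)),
        sample_size=S,
    )


__all__ = [
    "locus_pop_summary",
    "wc_components_from_aggregates",
    "theta_from_components",
    "wc_theta",
    "two_group_theta",
    "pairwise_fst_matrix",
    "burrows_r2",
    "ne_ld",
    "NeEstimate",
]
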