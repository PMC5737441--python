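"""Outlier-locus detection: candidates for divergent selection.

Two complementary scans are provided.  ``perm_fst_outliers`` tests each
locus's Weir–Cockerham theta between two a-priori population groups
against a null built by permuting individual group labels (individuals
are permuted jointly across loci, preserving LD), one-tailed for high
differentiation.  ``pca_scan`` performs genotype PCA and flags loci whose
association z-scores with the retained principal components have an
outlying Mahalanobis distance, with genomic-inflation rescaling of the
chi-square reference.  Both report Benjamini–Hochberg q-values and flag
loci at q <= 0.2 (a 20% false discovery rate), and a shared ledger
tallies loci flagged in multiple comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .qc import bh_adjust
from .stats import two_group_theta, wc_components_from_aggregates, theta_from_components
from .types import ComparisonSpec, GenotypeMatrix, SampleTable

Q_THRESHOLD_DEFAULT = 0.2


def _side_aggregates(S: np.ndarray, M: np.ndarray, A: np.ndarray, H: np.ndarray):
    """Per-locus aggregates (n, p, h) for group membership rows ``S``
    (..., n_ind) against call mask M, alt-dosage A and heterozygote H."""
    n = S @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (S @ A) / (2.0 * n)
        h = np.where(n > 0, (S @ H) / n, 0.0)
    return n, p, h


def comparison_theta(
    gm: GenotypeMatrix, samples: SampleTable, cmp: ComparisonSpec
) -> pd.DataFrame:
    """Observed per-locus theta between the pooled sides of a comparison."""
    mask_a = samples.members_mask(gm, cmp.side_a).astype(float)
    mask_b = samples.members_mask(gm, cmp.side_b).astype(float)
    M = gm.called().astype(float)
    A = np.where(gm.dosage >= 0, gm.dosage, 0).astype(float)
    H = (gm.dosage == 1).astype(float)
    na, pa, ha = _side_aggregates(mask_a, M, A, H)
    nb, pb, hb = _side_aggregates(mask_b, M, A, H)
    theta = two_group_theta(na, pa, ha, nb, pb, hb)
    return pd.DataFrame({"locus_id": gm.locus_ids, "theta": theta})


def perm_fst_outliers(
    gm: GenotypeMatrix,
    samples: SampleTable,
    cmp: ComparisonSpec,
    n_perm: int = 9999,
    seed: int = 0,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    chunk: int = 500,
) -> pd.DataFrame:
    """Permutation F_ST outlier test for one two-sided comparison.

    The observed statistic is the per-locus Weir–Cockerham theta between
    the pooled side A and side B individuals.  The null permutes the side
    labels of the individuals (jointly across all loci); the one-tailed
    p-value is ``(1 + #{perm theta >= observed}) / (n_perm + 1)``,
    BH-adjusted across loci.  Loci monomorphic across the comparison are
    reported unflagged with NaN statistics.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    in_a = samples.members_mask(gm, cmp.side_a)
    in_b = samples.members_mask(gm, cmp.side_b)
    if in_a.sum() < 5 or in_b.sum() < 5:
        raise ValueError(
            f"comparison {cmp.label!r}: each side needs >= 5 individuals "
            f"(got {int(in_a.sum())} vs {int(in_b.sum())})"
        )
    both = in_a | in_b
    idx = np.flatnonzero(both)
    D = gm.dosage[idx]
    side_a_local = in_a[idx]
    n_ind = len(idx)
    n_a = int(side_a_local.sum())

    M = (D >= 0).astype(float)
    A = np.where(D >= 0, D, 0).astype(float)
    H = (D == 1).astype(float)
    tot = _side_aggregates(np.ones(n_ind), M, A, H)

    sa = side_a_local.astype(float)
    na, pa, ha = _side_aggregates(sa, M, A, H)
    nb = tot[0] - na
    with np.errstate(invalid="ignore", divide="ignore"):
        pb = np.where(nb > 0, (tot[0] * 2 * tot[1] - na * 2 * pa) / (2 * nb), np.nan)
        hb = np.where(nb > 0, (tot[0] * tot[2] - na * ha) / nb, 0.0)
    obs = two_group_theta(na, pa, ha, nb, pb, hb)
    testable = np.isfinite(obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(gm.n_loci)
    done = 0
    sumA = M.sum(axis=0), A.sum(axis=0), H.sum(axis=0)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        S = np.zeros((b, n_ind))
        for r in range(b):
            S[r, rng.choice(n_ind, size=n_a, replace=False)] = 1.0
        SA = S @ A
        SH = S @ H
        pna = S @ M
        pnb = sumA[0][None, :] - pna
        with np.errstate(invalid="ignore", divide="ignore"):
            ppa = SA / (2.0 * pna)
            pha = np.where(pna > 0, SH / pna, 0.0)
            ppb = np.where(pnb > 0, (sumA[1][None, :] - SA) / (2.0 * pnb), np.nan)
            phb = np.where(pnb > 0, (sumA[2][None, :] - SH) / pnb, 0.0)
        pth = two_group_theta(pna, ppa, pha, pnb, ppb, phb)
        exceed += np.nansum(pth >= obs[None, :], axis=0)
        done += b

    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(testable, p, 1.0)
    q = bh_adjust(p)
    flagged = testable & (q <= q_threshold)
    return pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "comparison": cmp.label,
            "method": "perm_fst",
            "statistic": obs,
            "p": np.where(testable, p, np.nan),
            "q": np.where(testable, q, np.nan),
            "flagged": flagged,
        }
    )


def choose_k_scree(explained_variance: np.ndarray, k_max: int = 10) -> int:
    """Deterministic scree elbow: the largest K (1-indexed) with
    ``ev[K] / ev[K+1] >= 1.1``, at least 1, capped at ``k_max``."""
    ev = np.asarray(explained_variance, dtype=float)
    if ev.size < 2:
        raise ValueError("need at least two eigenvalues")
    if (np.diff(ev) > 1e-12).any() or (ev < 0).any():
        raise ValueError("explained variance must be nonincreasing and nonnegative")
    k = 1
    for i in range(ev.size - 1):
        if ev[i + 1] > 0 and ev[i] / ev[i + 1] >= 1.1:
            k = i + 1
        elif ev[i + 1] == 0:
            k = i + 1
            break
    return max(1, min(k, k_max))


def pca_scan(
    gm: GenotypeMatrix,
    K: int | str = "auto",
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    k_max: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """PCA-based outlier scan.

    Dosages are per-locus mean-imputed, centered and scaled by
    ``sqrt(p_hat (1 - p_hat))``.  Each locus is regressed on the K
    retained PC score vectors; the vector of standardized regression
    z-scores gets a Mahalanobis distance under its empirical covariance,
    rescaled by the genomic inflation factor (median statistic over the
    chi-square(K) median) before chi-square(K) p-values.  Monomorphic
    loci are reported unflagged with NaN statistics.

    Returns (records, pc_scores, info) where info carries K, the
    inflation factor lambda and the explained-variance spectrum.
    """
    n, L = gm.n_individuals, gm.n_loci
    if n < 2:
        raise ValueError("need at least two individuals")
    D = gm.dosage.astype(float)
    called = D >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(called, D, np.nan)
        col_mean = np.nanmean(col_mean, axis=0)
    G = np.where(called, D, col_mean[None, :])
    p_hat = col_mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    scale = np.sqrt(np.where(poly, p_hat * (1 - p_hat), 1.0))
    G = (G - col_mean[None, :]) / scale
    G[:, ~poly] = 0.0

    n_comp = min(n - 1, L, max(k_max + 1, 2))
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    scores = pca.fit_transform(G)
    ev = pca.explained_variance_
    if K == "auto":
        K_used = choose_k_scree(ev, k_max=k_max)
    else:
        K_used = int(K)
        if K_used >= min(n, L):
            raise ValueError("K must be smaller than min(individuals, loci)")
        if K_used < 1:
            raise ValueError("K must be >= 1")
    U = scores[:, :K_used]  # orthogonal columns
    u_norm2 = (U**2).sum(axis=0)

    proj = U.T @ G  # (K, L): g . u_k
    beta = proj / u_norm2[:, None]
    fitted_ss = (proj**2 / u_norm2[:, None]).sum(axis=0)
    tot_ss = (G**2).sum(axis=0)
    dof = max(n - K_used - 1, 1)
    with np.errstate(invalid="ignore"):
        s2 = np.maximum(tot_ss - fitted_ss, 0.0) / dof
    s = np.sqrt(np.maximum(s2, 1e-300))
    z = (beta * np.sqrt(u_norm2)[:, None] / s[None, :]).T  # (L, K)

    zp = z[poly]
    center = zp.mean(axis=0)
    cov = np.cov(zp, rowvar=False)
    cov = np.atleast_2d(cov)
    cov_inv = np.linalg.pinv(cov)
    dev = zp - center
    d2 = np.einsum("ij,jk,ik->i", dev, cov_inv, dev)
    lam = float(np.median(d2) / sps.chi2.median(K_used))
    lam = max(lam, 1e-12)
    p_poly = sps.chi2.sf(d2 / lam, K_used)
    q_poly = bh_adjust(p_poly)

    stat = np.full(L, np.nan)
    p = np.full(L, np.nan)
    q = np.full(L, np.nan)
    stat[poly] = d2
    p[poly] = p_poly
    q[poly] = q_poly
    flagged = poly & (np.nan_to_num(q, nan=1.0) <= q_threshold)
    top_pc = np.zeros(L, dtype=int)
    top_pc[poly] = np.abs(zp).argmax(axis=1) + 1

    records = pd.DataFrame(
        {
            "locus_id": gm.locus_ids,
            "comparison": "pca_global",
            "method": "pca_mahalanobis",
            "statistic": stat,
            "p": p,
            "q": q,
            "flagged": flagged,
            "top_pc": top_pc,
        }
    )
    pc_scores = pd.DataFrame(
        scores[:, :K_used],
        columns=[f"PC{k + 1}" for k in range(K_used)],
    )
    pc_scores.insert(0, "individual", gm.individual_ids)
    info = {
        "K": K_used,
        "lambda": lam,
        "explained_variance": ev,
        "explained_variance_ratio": pca.explained_variance_ratio_,
    }
    return records, pc_scores, info


def shared_outlier_ledger(
    records: pd.DataFrame,
    samples: SampleTable,
    comparisons: list[ComparisonSpec] | None = None,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Tally, per locus, the comparisons in which it was flagged by either
    method, plus a histogram of loci flagged in exactly k comparisons and
    the catchments spanned by those comparisons."""
    cmp_pops: dict[str, set[str]] = {}
    for c in comparisons or []:
        cmp_pops[c.label] = set(c.side_a) | set(c.side_b)
    flagged = records[records["flagged"].astype(bool)]
    entries = []
    for locus, grp in flagged.groupby("locus_id"):
        comps = sorted(set(grp["comparison"]))
        catchments: set[str] = set()
        for label in comps:
            for pop in cmp_pops.get(label, set()):
                a = samples.pop_attrs.get(pop)
                if a and a.catchment:
                    catchments.add(a.catchment)
        entries.append(
            {
                "locus_id": locus,
                "comparisons": ",".join(comps),
                "n_comparisons": len(comps),
                "catchments_spanned": ",".join(sorted(catchments)),
                "n_catchments": len(catchments),
            }
        )
    ledger = pd.DataFrame(
        entries, columns=["locus_id", "comparisons", "n_comparisons",
                          "catchments_spanned", "n_catchments"]
    )
    if len(ledger):
        ledger = ledger.sort_values(
            ["n_comparisons", "locus_id"], ascending=[False, True]
        ).reset_index(drop=True)
    hist: dict[int, int] = {}
    for k in ledger["n_comparisons"] if len(ledger) else []:
        hist[int(k)] = hist.get(int(k), 0) + 1
    return ledger, hist


__all__ = [
    "comparison_theta",
    "perm_fst_outliers",
    "pca_scan",
    "choose_k_scree",
    "shared_outlier_ledger",
    "Q_THRESHOLD_DEFAULT",
]
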