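"""Independent brute-force oracles used to verify the package's
statistics.  Everything here is written directly from first principles
(plain loops, exact rational arithmetic) and shares no code with the
implementation under test."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def wc_theta_bruteforce(pop_dosages: list[list[int]]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components a, b, c for one locus,
    computed with scalar loops from per-population dosage lists (missing
    genotypes encoded as -1 and dropped)."""
    ns, ps, hs = [], [], []
    for dosages in pop_dosages:
        called = [d for d in dosages if d >= 0]
        if not called:
            continue
        n_i = len(called)
        p_i = sum(called) / (2.0 * n_i)
        h_i = sum(1 for d in called if d == 1) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    r = len(ns)
    if r < 2:
        return math.nan, math.nan, math.nan
    nbar = sum(ns) / r
    if nbar <= 1:
        return math.nan, math.nan, math.nan
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def hwe_exact_p_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by exhaustive enumeration of all genotype tables with
    the same diploid count and minor-allele count, using exact rational
    arithmetic for the conditional probabilities."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    configs = []
    for het in range(n + 1):
        rem = n_minor - het
        if rem < 0 or rem % 2:
            continue
        n_minor_hom = rem // 2
        n_major_hom = n - het - n_minor_hom
        if n_major_hom < 0:
            continue
        weight = Fraction(
            math.factorial(n),
            math.factorial(n_major_hom) * math.factorial(het) * math.factorial(n_minor_hom),
        ) * Fraction(2) ** het
        configs.append((het, weight))
    total = sum(w for _, w in configs)
    probs = {het: w / total for het, w in configs}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg q-values by the literal step-up definition
    q_(i) = min_{j >= i} m p_(j) / j, mapped back to input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvals[i] / rank)
        q_sorted[rank - 1] = running_min
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def gaussian_weighted_mean(
    positions: list[float], values: list[float], center: float, window: float
) -> float:
    """Direct computation of the kernel-smoothed window statistic with
    sigma = (window/2)/3, including only loci within window/2 of center."""
    sigma = (window / 2.0) / 3.0
    num = den = 0.0
    for x, v in zip(positions, values):
        d = x - center
        if abs(d) <= window / 2.0:
            w = math.exp(-(d * d) / (2 * sigma * sigma))
            num += w * v
            den += w
    return num / den


def burrows_r2_naive(x: list[int], y: list[int]) -> float:
    """Composite-LD r-squared between two dosage vectors by direct loops
    over pairwise-complete individuals (HW-departure-corrected
    denominator)."""
    pairs = [(a, b) for a, b in zip(x, y) if a >= 0 and b >= 0]
    n = len(pairs)
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum(a * b for a, b in pairs) / n - mx * my
    vx = sum(a * a for a in xs) / n - mx * mx
    vy = sum(b * b for b in ys) / n - my * my
    return (cov * cov) / (vx * vy)


def random_instance(rng: np.random.Generator, max_pops: int = 4, max_n: int = 20):
    """A random small multi-population single-locus dosage instance."""
    n_pops = int(rng.integers(2, max_pops + 1))
    pops = []
    for _ in range(n_pops):
        n = int(rng.integers(2, max_n + 1))
        p = rng.uniform(0.05, 0.95)
        dosages = rng.binomial(2, p, size=n).astype(int)
        miss = rng.random(n) < 0.1
        dosages[miss] = -1
        pops.append(list(dosages))
    return pops
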