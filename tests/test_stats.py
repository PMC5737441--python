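"""Diversity summaries, Weir–Cockerham theta, composite LD and the
LD-method Ne estimator."""

import numpy as np
import pandas as pd
import pytest

from nerka import stats
from nerka.simulate import simulate_wright_fisher
from nerka.types import GenotypeMatrix, SampleTable

from .oracles import burrows_r2_naive, random_instance, wc_theta_bruteforce


def _single_pop(dosage):
    dosage = np.asarray(dosage, dtype=np.int8).reshape(-1, 1)
    gm = GenotypeMatrix(
        [f"i_{k}" for k in range(len(dosage))], ["L0_1"], dosage
    )
    return gm, SampleTable({i: "p" for i in gm.individual_ids})


def _two_pop(dos_a, dos_b, extra_loci=None):
    """One-locus two-population matrix from dosage lists."""
    cols = [list(dos_a) + list(dos_b)]
    if extra_loci:
        cols.extend(extra_loci)
    dosage = np.array(cols, dtype=np.int8).T
    ids = [f"a_{k}" for k in range(len(dos_a))] + [f"b_{k}" for k in range(len(dos_b))]
    gm = GenotypeMatrix(ids, [f"L{j}_1" for j in range(dosage.shape[1])], dosage)
    pops = {i: ("a" if i.startswith("a_") else "b") for i in ids}
    return gm, SampleTable(pops)


class TestLocusPopSummary:
    def test_all_heterozygotes(self):
        gm, samples = _single_pop([1] * 10)
        row = stats.locus_pop_summary(gm, samples, "p").iloc[0]
        assert row.H_o == 1.0
        assert row.p_hat == 0.5
        assert row.H_e == pytest.approx(0.5 * 20 / 19)

    def test_monomorphic_zero_heterozygosity(self):
        gm, samples = _single_pop([0] * 8)
        row = stats.locus_pop_summary(gm, samples, "p").iloc[0]
        assert row.H_o == 0.0 and row.H_e == 0.0

    def test_unbiased_at_least_plugin(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            gm, samples = _single_pop(rng.binomial(2, rng.uniform(0.1, 0.9), n))
            unb = stats.locus_pop_summary(gm, samples, "p", unbiased=True).iloc[0].H_e
            plug = stats.locus_pop_summary(gm, samples, "p", unbiased=False).iloc[0].H_e
            assert unb >= plug - 1e-15

    def test_zero_calls_marked_unavailable(self):
        gm, samples = _single_pop([-1, -1, -1])
        row = stats.locus_pop_summary(gm, samples, "p").iloc[0]
        assert not row.available and np.isnan(row.H_e)


class TestWcTheta:
    def test_fixed_difference_is_one(self):
        gm, samples = _two_pop([0, 0, 0], [2, 2, 2])
        df, multi = stats.wc_theta(gm, samples)
        assert df.theta.iloc[0] == pytest.approx(1.0)
        assert multi == pytest.approx(1.0)

    def test_monomorphic_locus_undefined(self):
        gm, samples = _two_pop([0, 0], [0, 0])
        df, multi = stats.wc_theta(gm, samples)
        assert np.isnan(df.theta.iloc[0]) and np.isnan(multi)

    def test_hand_worked_counts_match_oracle(self):
        # pop1: 8 AA / 4 Aa / 0 aa ; pop2: 2 AA / 6 Aa / 4 aa
        pop1 = [0] * 8 + [1] * 4
        pop2 = [0] * 2 + [1] * 6 + [2] * 4
        gm, samples = _two_pop(pop1, pop2)
        df, _ = stats.wc_theta(gm, samples)
        a, b, c = wc_theta_bruteforce([pop1, pop2])
        assert df.a.iloc[0] == pytest.approx(a, abs=1e-12)
        assert df.b.iloc[0] == pytest.approx(b, abs=1e-12)
        assert df.c.iloc[0] == pytest.approx(c, abs=1e-12)
        assert df.theta.iloc[0] == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_matches_oracle_on_random_instances(self):
        """Property check across random 2-4 population instances."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            pops = random_instance(rng)
            dosage = np.array(sum(pops, []), dtype=np.int8).reshape(-1, 1)
            ids, assign = [], {}
            k = 0
            for pi, dos in enumerate(pops):
                for _ in dos:
                    ids.append(f"p{pi}_i{k}")
                    assign[f"p{pi}_i{k}"] = f"p{pi}"
                    k += 1
            gm = GenotypeMatrix(ids, ["L0_1"], dosage)
            samples = SampleTable(assign)
            df, _ = stats.wc_theta(gm, samples)
            a, b, c = wc_theta_bruteforce(pops)
            if np.isnan(a):
                assert np.isnan(df.a.iloc[0])
                continue
            assert df.a.iloc[0] == pytest.approx(a, abs=1e-12)
            assert df.b.iloc[0] == pytest.approx(b, abs=1e-12)
            assert df.c.iloc[0] == pytest.approx(c, abs=1e-12)

    def test_multilocus_within_locus_range_when_denoms_positive(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, rng.uniform(0.3, 0.7, 20)[None, :], size=(40, 20))
        ids = [f"a_{k}" for k in range(20)] + [f"b_{k}" for k in range(20)]
        gm = GenotypeMatrix(ids, [f"L{j}_1" for j in range(20)], dosage.astype(np.int8))
        samples = SampleTable(
            {i: ("a" if i.startswith("a_") else "b") for i in ids}
        )
        df, multi = stats.wc_theta(gm, samples)
        denom = df.a + df.b + df.c
        if (denom > 0).all():
            assert df.theta.min() - 1e-12 <= multi <= df.theta.max() + 1e-12


class TestPairwiseFst:
    def test_symmetry_and_zero_diagonal(self, small_panel):
        gm, samples, _, _ = small_panel
        m = stats.pairwise_fst_matrix(gm, samples)
        assert np.allclose(m.values, m.values.T, equal_nan=True)
        assert np.allclose(np.diag(m.values), 0.0)

    def test_duplicated_population_small_negative(self):
        """Self-comparison: theta is slightly negative with expectation
        about -1/(2(n-1)), so at n = 150 it sits within 0.005 of zero."""
        rng = np.random.default_rng(5)
        n, L = 150, 1000
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, L)[None, :], size=(n, L))
        dosage = np.vstack([dosage, dosage])  # same individuals twice
        ids = [f"a_{k}" for k in range(n)] + [f"b_{k}" for k in range(n)]
        gm = GenotypeMatrix(ids, [f"L{j}_1" for j in range(L)], dosage.astype(np.int8))
        samples = SampleTable({i: i[0] for i in ids})
        m = stats.pairwise_fst_matrix(gm, samples)
        assert m.loc["a", "b"] <= 0
        assert abs(m.loc["a", "b"]) < 0.005


class TestBurrowsR2:
    def test_duplicated_locus_perfect_correlation(self):
        rng = np.random.default_rng(2)
        col = rng.binomial(2, 0.4, 40).astype(np.int8)
        gm = GenotypeMatrix(
            [f"i_{k}" for k in range(40)], ["A_1", "B_1"],
            np.stack([col, col], axis=1),
        )
        samples = SampleTable({i: "p" for i in gm.individual_ids})
        table = stats.burrows_r2(gm, samples, "p")
        assert table.r2.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.binomial(2, 0.5, 60).astype(np.int8)
        y = rng.binomial(2, 0.4, 60).astype(np.int8)
        gm1 = GenotypeMatrix(
            [f"i_{k}" for k in range(60)], ["A_1", "B_1"], np.stack([x, y], axis=1)
        )
        gm2 = GenotypeMatrix(
            [f"i_{k}" for k in range(60)], ["A_1", "B_1"],
            np.stack([2 - x, y], axis=1),
        )
        samples = SampleTable({i: "p" for i in gm1.individual_ids})
        r1 = stats.burrows_r2(gm1, samples, "p").r2.iloc[0]
        r2 = stats.burrows_r2(gm2, samples, "p").r2.iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_matches_naive_oracle_with_missing(self):
        rng = np.random.default_rng(6)
        x = rng.binomial(2, 0.5, 80)
        y = rng.binomial(2, 0.4, 80)
        x[rng.random(80) < 0.15] = -1
        y[rng.random(80) < 0.15] = -1
        gm = GenotypeMatrix(
            [f"i_{k}" for k in range(80)], ["A_1", "B_1"],
            np.stack([x, y], axis=1).astype(np.int8),
        )
        samples = SampleTable({i: "p" for i in gm.individual_ids})
        got = stats.burrows_r2(gm, samples, "p").r2.iloc[0]
        assert got == pytest.approx(
            burrows_r2_naive(list(x), list(y)), abs=1e-12
        )

    def test_unlinked_mean_near_sampling_expectation(self):
        """Independent loci: mean r2 is near 1/(n-1), the sampling floor."""
        rng = np.random.default_rng(8)
        n, L = 100, 120
        D = rng.binomial(2, rng.uniform(0.2, 0.8, L)[None, :], size=(n, L))
        gm = GenotypeMatrix(
            [f"i_{k}" for k in range(n)], [f"L{j}_1" for j in range(L)],
            D.astype(np.int8),
        )
        samples = SampleTable({i: "p" for i in gm.individual_ids})
        table = stats.burrows_r2(gm, samples, "p")
        vals = table.r2.dropna().to_numpy()
        se = vals.std() / np.sqrt(L / 2)  # ~L/2 effectively independent pairs
        assert abs(vals.mean() - 1 / (n - 1)) < 3 * se

    def test_fixed_locus_pairs_flagged(self):
        gm = GenotypeMatrix(
            [f"i_{k}" for k in range(20)], ["A_1", "B_1"],
            np.stack([np.zeros(20), np.tile([0, 1], 10)], axis=1).astype(np.int8),
        )
        samples = SampleTable({i: "p" for i in gm.individual_ids})
        table = stats.burrows_r2(gm, samples, "p")
        assert table.skipped.iloc[0] == "maf_below_min_or_fixed"


def _wf_sample(Ne, S, L, gens, seed):
    gm = simulate_wright_fisher(Ne, S, L, gens, seed)
    return gm, SampleTable({i: "wf" for i in gm.individual_ids})


class TestNeLd:
    def test_relabeling_invariance(self):
        gm, samples = _wf_sample(50, 40, 200, 3, seed=1)
        est = stats.ne_ld(gm, samples, "wf")
        rng = np.random.default_rng(0)
        perm_i = rng.permutation(gm.n_individuals)
        perm_j = rng.permutation(gm.n_loci)
        gm2 = GenotypeMatrix(
            [gm.individual_ids[i] for i in perm_i],
            [gm.locus_ids[j] for j in perm_j],
            gm.dosage[np.ix_(perm_i, perm_j)],
        )
        est2 = stats.ne_ld(gm2, samples, "wf")
        assert est2.r2_mean == pytest.approx(est.r2_mean, rel=1e-12)
        assert est2.ne_point == pytest.approx(est.ne_point, rel=1e-12)

    def test_ci_brackets_point(self):
        gm, samples = _wf_sample(50, 50, 400, 4, seed=2)
        est = stats.ne_ld(gm, samples, "wf")
        assert est.ci_low <= est.ne_point <= est.ci_high

    def test_ci_narrows_with_more_loci(self):
        """Doubling the locus count tightens the jackknife CI."""
        narrower = 0
        for seed in range(10):
            e1 = stats.ne_ld(*_wf_sample(50, 50, 400, 4, seed), "wf")
            e2 = stats.ne_ld(*_wf_sample(50, 50, 800, 4, seed + 1000), "wf")
            narrower += (e2.ci_high - e2.ci_low) < (e1.ci_high - e1.ci_low)
        assert narrower >= 8

    def test_huge_ne_signal_below_noise(self):
        """At Ne = 10,000 the drift LD is below sampling noise: the
        estimate is very large or infinite."""
        gm, samples = _wf_sample(10000, 50, 800, 4, seed=3)
        est = stats.ne_ld(gm, samples, "wf")
        assert est.ne_point > 500 or np.isinf(est.ne_point)
        assert np.isinf(est.ci_high) or est.ci_high > est.ne_point

    def test_same_tag_pairs_excluded(self):
        rng = np.random.default_rng(9)
        col = rng.binomial(2, 0.5, 30).astype(np.int8)
        col2 = rng.binomial(2, 0.5, 30).astype(np.int8)
        # two loci on one tag plus one single-SNP tag
        gm = GenotypeMatrix(
            [f"i_{k}" for k in range(30)], ["T1_1", "T1_2", "T2_1"],
            np.stack([col, col, col2], axis=1),
        )
        samples = SampleTable({i: "p" for i in gm.individual_ids})
        est = stats.ne_ld(gm, samples, "p", maf_min=0.0)
        assert est.n_pairs == 2  # (T1_1,T2_1) and (T1_2,T2_1); not (T1_1,T1_2)

    def test_small_sample_rejected(self):
        gm, _ = _wf_sample(50, 9, 50, 1, seed=5)
        samples = SampleTable({i: "wf" for i in gm.individual_ids})
        with pytest.raises(ValueError, match="fewer than 10"):
            stats.ne_ld(gm, samples, "wf")
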