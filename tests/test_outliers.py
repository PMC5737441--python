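"""Permutation F_ST scan, PCA scan, scree rule and the shared-outlier
ledger."""

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from nerka import outliers
from nerka.simulate import (
    DivergentGroup,
    PopulationSpec,
    SimParams,
    simulate_panel,
    study_design_params,
)
from nerka.types import ComparisonSpec, GenotypeMatrix, SampleTable

from .conftest import two_pop_params

P = PopulationSpec


class TestPermFst:
    def test_deterministic_given_seed(self, small_panel, shore_stream_cmp):
        gm, samples, _, _ = small_panel
        r1 = outliers.perm_fst_outliers(gm, samples, shore_stream_cmp, n_perm=199, seed=5)
        r2 = outliers.perm_fst_outliers(gm, samples, shore_stream_cmp, n_perm=199, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_small_side_refused(self, small_panel):
        gm, samples, _, _ = small_panel
        tiny = ComparisonSpec("tiny", frozenset({"x_shore"}), frozenset({"nope"}))
        with pytest.raises(ValueError, match=">= 5 individuals"):
            outliers.perm_fst_outliers(gm, samples, tiny, n_perm=199)

    def test_q_at_least_p_and_flag_consistency(self, small_panel, shore_stream_cmp):
        gm, samples, _, _ = small_panel
        rec = outliers.perm_fst_outliers(gm, samples, shore_stream_cmp, n_perm=199, seed=1)
        ok = rec.dropna(subset=["p"])
        assert (ok.q >= ok.p - 1e-12).all()
        assert ((ok.q <= 0.2) == ok.flagged.loc[ok.index]).all()

    def test_planted_strong_locus_flagged_by_both_methods(self):
        """A single delta = 0.45 locus with 48/side is caught by both scans."""
        hits = 0
        cmp = ComparisonSpec("t", frozenset({"x_shore"}), frozenset({"x_stream"}))
        for seed in range(10):
            params = SimParams(
                populations=[
                    P("x_shore", "lk", "c1", "kokanee", "shore", 0.02, 48),
                    P("x_stream", "lk", "c1", "kokanee", "stream", 0.02, 48),
                ],
                f_catch={"c1": 0.05}, f_lake={"lk": 0.03},
                L_neutral=500,
                divergent=[DivergentGroup("shore_vs_stream", 0.45, n_loci=1)],
                missing_rate=0.03, seed=200 + seed,
            )
            gm, samples, _, truth = simulate_panel(params)
            target = truth.loc[truth.is_divergent, "locus_id"].iloc[0]
            rp = outliers.perm_fst_outliers(gm, samples, cmp, n_perm=499, seed=seed)
            rc, _, _ = outliers.pca_scan(gm, K=1)
            got_p = bool(rp.set_index("locus_id").loc[target, "flagged"])
            got_c = bool(rc.set_index("locus_id").loc[target, "flagged"])
            hits += got_p and got_c
        assert hits >= 9


class TestChooseKScree:
    def test_obvious_elbow(self):
        assert outliers.choose_k_scree([10, 9, 1, 0.98, 0.97]) == 2

    def test_flat_spectrum(self):
        assert outliers.choose_k_scree([1, 1, 1, 1]) == 1

    def test_geometric_decay_hits_max_bound(self):
        ev = [2.0 ** -i for i in range(8)]
        assert outliers.choose_k_scree(ev, k_max=4) == 4

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            outliers.choose_k_scree([1.0])


class TestPcaScan:
    def test_separated_clusters_on_pc1(self):
        params = two_pop_params(
            seed=21, L_neutral=600,
            divergent=[DivergentGroup("shore_vs_stream", 0.45, n_loci=40)],
        )
        gm, samples, _, _ = simulate_panel(params)
        _, scores, _ = outliers.pca_scan(gm, K=1)
        labels = [samples.pop_of_individual[i] for i in scores.individual]
        sil = silhouette_score(scores[["PC1"]].to_numpy(), labels)
        assert sil > 0.9

    def test_null_lambda_near_one_and_few_flags(self):
        params = SimParams(
            populations=[P("x_a", "lk", "c", "kokanee", "shore", 1e-6, 60)],
            f_catch={"c": 1e-6}, f_lake={"lk": 1e-6},
            L_neutral=2000, missing_rate=0.03, seed=5,
        )
        gm, *_ = simulate_panel(params)
        rec, _, info = outliers.pca_scan(gm, K=1)
        assert 0.8 <= info["lambda"] <= 1.25
        assert rec.flagged.sum() <= 0.01 * rec.p.notna().sum()

    def test_k1_statistic_is_squared_standardized_association(self):
        """With K = 1 the Mahalanobis distance degenerates to the squared
        centered/scaled association z-score (cross-checked against an
        independent per-locus regression on the PC1 scores)."""
        params = two_pop_params(seed=23, L_neutral=150, missing_rate=0.0)
        gm, *_ = simulate_panel(params)
        rec, scores, _ = outliers.pca_scan(gm, K=1)
        # independent recomputation: regress each scaled locus on PC1
        D = gm.dosage.astype(float)
        p_hat = D.mean(axis=0) / 2
        poly = (p_hat > 0) & (p_hat < 1)
        G = (D - 2 * p_hat) / np.sqrt(np.where(poly, p_hat * (1 - p_hat), 1.0))
        u = scores.PC1.to_numpy()
        z = np.full(gm.n_loci, np.nan)
        for j in np.flatnonzero(poly):
            beta = (G[:, j] @ u) / (u @ u)
            resid = G[:, j] - beta * u
            s = np.sqrt((resid @ resid) / (len(u) - 2))
            z[j] = beta * np.sqrt(u @ u) / s
        zp = z[poly]
        expected = ((zp - zp.mean()) ** 2) / np.var(zp, ddof=1)
        got = rec.statistic.to_numpy()[poly]
        assert np.allclose(got, expected, rtol=1e-8)

    def test_invariant_to_individual_and_locus_order(self):
        params = two_pop_params(seed=29, L_neutral=200)
        gm, *_ = simulate_panel(params)
        rec, _, _ = outliers.pca_scan(gm, K=2)
        rng = np.random.default_rng(0)
        perm_i = rng.permutation(gm.n_individuals)
        perm_j = rng.permutation(gm.n_loci)
        gm2 = GenotypeMatrix(
            [gm.individual_ids[i] for i in perm_i],
            [gm.locus_ids[j] for j in perm_j],
            gm.dosage[np.ix_(perm_i, perm_j)],
        )
        rec2, _, _ = outliers.pca_scan(gm2, K=2)
        a = rec.set_index("locus_id").statistic
        b = rec2.set_index("locus_id").statistic.reindex(a.index)
        assert np.allclose(a.to_numpy(), b.to_numpy(), rtol=1e-8, equal_nan=True)

    def test_agreement_between_methods_is_partial(self):
        """On a structured multi-lake panel the pairwise permutation scan
        and the global PCA scan overlap but neither subsumes the other."""
        params = study_design_params(seed=3, loci_per_axis=20, delta=0.35)
        params.L_neutral = 1500
        gm, samples, _, _ = simulate_panel(params)
        cmp = ComparisonSpec(
            "wood", frozenset({"wood_ko_shore"}), frozenset({"wood_ko_stream"})
        )
        rp = outliers.perm_fst_outliers(gm, samples, cmp, n_perm=499, seed=1)
        rc, _, _ = outliers.pca_scan(gm, K="auto")
        fp = set(rp.loc[rp.flagged, "locus_id"])
        fc = set(rc.loc[rc.flagged, "locus_id"])
        assert fp & fc
        assert fp - fc and fc - fp


class TestSharedLedger:
    @staticmethod
    def _records(flagged_map):
        rows = []
        for (locus, cmp), fl in flagged_map.items():
            rows.append(
                {"locus_id": locus, "comparison": cmp, "method": "perm_fst",
                 "statistic": 0.5, "p": 0.001, "q": 0.01, "flagged": fl}
            )
        return pd.DataFrame(rows)

    def test_counts_comparisons(self):
        rec = self._records(
            {("L1", "A"): True, ("L1", "B"): True, ("L1", "C"): True,
             ("L2", "A"): True, ("L2", "B"): False}
        )
        samples = SampleTable({"i_1": "p1"})
        ledger, hist = outliers.shared_outlier_ledger(rec, samples)
        row = ledger.set_index("locus_id").loc["L1"]
        assert row.n_comparisons == 3
        assert hist == {3: 1, 1: 1}

    def test_no_flags_empty_ledger(self):
        rec = self._records({("L1", "A"): False})
        ledger, hist = outliers.shared_outlier_ledger(rec, SampleTable({"i": "p"}))
        assert len(ledger) == 0 and hist == {}

    def test_shared_loci_dominate_high_sharing_bins(self):
        """Loci planted as divergent in all lakes appear in more
        comparisons than lake-private planted loci."""
        wins = 0
        for seed in range(10):
            params = study_design_params(seed=300 + seed, loci_per_axis=0)
            params.L_neutral = 600
            params.divergent = [
                DivergentGroup("shore_vs_stream", 0.4, n_loci=8),  # all lakes
                DivergentGroup(
                    "shore_vs_stream", 0.4, n_loci=8,
                    shared_across=frozenset({"wood"}),
                ),
            ]
            gm, samples, _, truth = simulate_panel(params)
            comps = [
                ComparisonSpec(f"{lake}_ss", frozenset({f"{pre}_ko_shore"}),
                               frozenset({f"{pre}_ko_stream"}))
                for lake, pre in [
                    ("okanagan", "okanagan"), ("wood", "wood"),
                    ("kootenay_west", "kootenaywest"), ("tchesinkut", "tchesinkut"),
                ]
            ]
            recs = pd.concat(
                [outliers.perm_fst_outliers(gm, samples, c, n_perm=299, seed=seed + k)
                 for k, c in enumerate(comps)],
                ignore_index=True,
            )
            ledger, _ = outliers.shared_outlier_ledger(recs, samples, comps)
            div = truth[truth.is_divergent].copy()
            shared = set(div.locus_id[: 8])
            private = set(div.locus_id[8:])
            counts = dict(zip(ledger.locus_id, ledger.n_comparisons))
            mean_shared = np.mean([counts.get(l, 0) for l in shared])
            mean_private = np.mean([counts.get(l, 0) for l in private])
            wins += mean_shared > mean_private
        assert wins >= 8
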