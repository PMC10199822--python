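import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hexatac.acr_refinement import ACR, AccessibilitySignal
from hexatac.differential_accessibility import (
    CLUSTERS,
    UNASSIGNED,
    assign_clusters,
    assign_specificity,
    associate_acr_genes,
    call_degs,
    cluster_patterns,
    moderated_ttest,
    normalize_acr_scores,
    overlap_enrichment,
    pairwise_diff,
    presence_vector,
    promoter_accessibility_matrix,
    size_factors,
)
from hexatac.genomic_core import GeneModel, GenomicInterval

TISSUES = ["leaf", "DAP5", "DAP9", "DAP15", "DAP20"]


def bh_oracle(pvals):
    """Step-up Benjamini-Hochberg, written independently of statsmodels."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


class TestAssignSpecificity:
    @pytest.mark.parametrize(
        "presence,expected",
        [
            ((True, False, False, False, False), "Leafs"),
            ((False, True, False, False, False), "DAP5s"),
            ((False, False, True, False, False), "DAP9s"),
            ((False, True, True, False, False), "DAP5and9s"),
            ((False, False, False, True, False), "DAP15s"),
            ((False, False, False, False, True), "DAP20s"),
            ((False, False, False, True, True), "DAP15and20s"),
            ((False, True, True, True, True), "AllGs"),
            ((False, True, False, True, False), UNASSIGNED),
            ((False, False, False, False, False), UNASSIGNED),
            ((True, True, True, True, True), UNASSIGNED),
        ],
    )
    def test_exact_pattern_map(self, presence, expected):
        assert assign_specificity(presence) == expected

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            assign_specificity([True, False])

    def test_total_and_deterministic_over_all_patterns(self):
        from itertools import product

        seen = {}
        for bits in product([False, True], repeat=5):
            seen[bits] = assign_specificity(bits)
            assert assign_specificity(bits) == seen[bits]
        assert sum(v != UNASSIGNED for v in seen.values()) == 8
        assert set(v for v in seen.values() if v != UNASSIGNED) == set(CLUSTERS)

    def test_cluster_patterns_requires_five_tissues(self):
        with pytest.raises(ValueError):
            cluster_patterns(["a", "b"])


class TestNormalizeScores:
    def make_signal(self, positions, sample="s", tissue="t", rep=1):
        return AccessibilitySignal(sample, tissue, rep, {"c": np.array(positions)})

    def test_single_acr_holds_everything(self):
        acrs = [GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 600)]
        sig = self.make_signal([10, 20, 30])
        scores = normalize_acr_scores(acrs, [sig])
        assert scores.iloc[0, 0] == pytest.approx(1e6)
        assert scores.iloc[1, 0] == 0

    def test_depth_invariance(self):
        acrs = [GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 600)]
        a = self.make_signal([10, 20, 510])
        b = self.make_signal([10, 10, 20, 20, 510, 510])  # doubled depth
        sa = normalize_acr_scores(acrs, [a])
        sb = normalize_acr_scores(acrs, [b])
        assert np.allclose(sa.to_numpy(), sb.to_numpy())

    def test_hand_computed(self, rng):
        acrs = [GenomicInterval("c", i * 100, i * 100 + 50) for i in range(10)]
        pos = rng.integers(0, 1000, size=300)
        sig = self.make_signal(np.sort(pos))
        scores = normalize_acr_scores(acrs, [sig])
        counts = np.array(
            [np.sum((pos >= a.start) & (pos < a.end)) for a in acrs], dtype=float
        )
        assert np.allclose(scores.iloc[:, 0].to_numpy(), counts * 1e6 / counts.sum())

    def test_zero_in_peak_sample_is_error(self):
        acrs = [GenomicInterval("c", 0, 10)]
        with pytest.raises(ValueError):
            normalize_acr_scores(acrs, [self.make_signal([500])])


class TestPairwiseDiff:
    def test_identical_groups_no_call(self):
        x = np.tile([[10.0, 12.0]], (20, 1))
        res = pairwise_diff(x, x)
        assert np.allclose(res["log2fc"], 0)
        assert (res["call"] == 0).all()

    def test_bh_step_up_example(self):
        # adjusted p for (0.01, 0.02, 0.03, 0.04) at m=4 is 0.04 across the board
        assert np.allclose(bh_oracle([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        from statsmodels.stats.multitest import multipletests

        assert np.allclose(
            multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1], 0.04
        )

    def test_bh_oracle_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        assert np.allclose(bh_oracle(p), multipletests(p, method="fdr_bh")[1])

    def test_mismatched_features(self):
        with pytest.raises(ValueError):
            pairwise_diff(np.ones((3, 2)), np.ones((4, 2)))

    def test_single_replicate_falls_back_to_fold_only(self):
        a = np.array([[100.0], [1.0]])
        b = np.array([[1.0], [100.0]])
        with pytest.warns(UserWarning):
            res = pairwise_diff(a, b)
        assert res["call"].tolist() == [1, -1]
        assert res["p"].isna().all()

    def test_sign_orientation(self, rng):
        a = np.full((10, 2), 400.0) + rng.normal(0, 5, (10, 2))
        b = np.full((10, 2), 10.0) + rng.normal(0, 1, (10, 2))
        res = pairwise_diff(a, b)
        assert (res["call"] == 1).all()


class TestModeratedTtest:
    def test_matches_plain_ttest_when_unmoderated(self, rng):
        a = rng.normal(5, 1, size=(50, 4))
        b = rng.normal(5, 1, size=(50, 4))
        t, p = moderated_ttest(a, b, moderation="none")
        t_ref, p_ref = stats.ttest_ind(a, b, axis=1)
        assert np.allclose(t, t_ref)
        assert np.allclose(p, p_ref)

    def test_moderation_gains_power_at_two_replicates(self, rng):
        a = rng.normal(8, 0.5, size=(200, 2))
        b = rng.normal(4, 0.5, size=(200, 2))
        _, p_plain = moderated_ttest(a, b, moderation="none")
        _, p_mod = moderated_ttest(a, b, moderation="pool")
        assert np.median(p_mod) < np.median(p_plain)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            moderated_ttest(np.ones((3, 1)), np.ones((3, 2)))


class TestPresenceAndClusters:
    def make_pair_results(self, rep_matrix):
        """rep_matrix: feature -> per-tissue mean scores; replicates jittered."""
        from hexatac.differential_accessibility import all_pairwise

        jitter = np.random.default_rng(0)
        cols = {}
        for ti, t in enumerate(TISSUES):
            for r in (1, 2):
                cols[f"{t}_r{r}"] = [
                    rep_matrix[f][ti] * float(jitter.uniform(0.9, 1.1))
                    for f in rep_matrix
                ]
        frame = pd.DataFrame(cols, index=list(rep_matrix))
        sample_tissues = {f"{t}_r{r}": t for t in TISSUES for r in (1, 2)}
        return all_pairwise(frame, sample_tissues, pseudo=1.0), sample_tissues

    def test_planted_patterns_recovered(self):
        features = {
            "leaf_only": [500, 1, 1, 1, 1],
            "d5and9": [1, 500, 500, 1, 1],
            "flat": [100, 100, 100, 100, 100],
        }
        pair_results, _ = self.make_pair_results(features)
        clusters = assign_clusters(pair_results, TISSUES)
        assert clusters.loc["leaf_only", "cluster"] == "Leafs"
        assert clusters.loc["d5and9", "cluster"] == "DAP5and9s"
        assert "flat" not in clusters.index  # no call at all -> not differential

    def test_presence_all_false_when_inconsistent(self):
        features = {"checker": [500, 1, 500, 1, 500]}
        pair_results, _ = self.make_pair_results(features)
        pres = presence_vector(pair_results, TISSUES, "checker")
        cluster = assign_specificity(pres)
        assert cluster == UNASSIGNED or pres == [True, False, True, False, True]


class TestCallDegs:
    def test_external_table_passthrough(self):
        counts = pd.DataFrame(
            np.ones((3, 4), dtype=int),
            index=["g1", "g2", "g3"],
            columns=["a_r1", "a_r2", "b_r1", "b_r2"],
        )
        st = {"a_r1": "a", "a_r2": "a", "b_r1": "b", "b_r2": "b"}
        ext = {
            ("a", "b"): pd.DataFrame(
                {"log2fc": [2.0, 0.0, -2.0], "p": [1e-5, 0.9, 1e-5],
                 "padj": [1e-4, 0.95, 1e-4], "call": [1, 0, -1]},
                index=["g1", "g2", "g3"],
            )
        }
        pairs, _ = call_degs(counts, st, external_calls=ext)
        assert pairs is ext
        pd.testing.assert_frame_equal(pairs[("a", "b")], ext[("a", "b")])

    def test_non_integer_counts_warn(self):
        counts = pd.DataFrame(
            {"a_r1": [1.5, 2.0], "a_r2": [1.0, 2.0], "b_r1": [1.0, 2.0], "b_r2": [1.0, 2.0]},
            index=["g1", "g2"],
        )
        st = {"a_r1": "a", "a_r2": "a", "b_r1": "b", "b_r2": "b"}
        with pytest.warns(UserWarning):
            call_degs(counts, st)

    def test_size_factors_median_of_ratios(self, rng):
        base = rng.integers(10, 1000, size=50).astype(float)
        counts = pd.DataFrame(
            {"s1": base, "s2": base * 2, "s3": base * 0.5}, index=[f"g{i}" for i in range(50)]
        )
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)
        assert sf["s3"] / sf["s1"] == pytest.approx(0.5)

    def test_all_zero_gene_skipped(self):
        counts = pd.DataFrame(
            {"a_r1": [100, 0], "a_r2": [110, 0], "b_r1": [10, 0], "b_r2": [12, 0]},
            index=["g1", "gzero"],
        )
        st = {"a_r1": "a", "a_r2": "a", "b_r1": "b", "b_r2": "b"}
        pairs, _ = call_degs(counts, st)
        assert "gzero" not in pairs[("a", "b")].index


class TestAssociateAcrGenes:
    GENES = [GeneModel("gA", GenomicInterval("c", 10_000, 12_000, "+"))]

    def test_boundary_one_bp(self):
        # gene window is [8000, 14000); ACR ending at 8000 misses, at 8001 hits
        miss = ACR(interval=GenomicInterval("c", 7900, 8000))
        hit = ACR(interval=GenomicInterval("c", 7901, 8001))
        assert associate_acr_genes([miss], self.GENES).get("all", []) == []
        assert associate_acr_genes([hit], self.GENES) == {"all": ["gA"]}

    def test_acr_spanning_two_windows(self):
        genes = self.GENES + [GeneModel("gB", GenomicInterval("c", 15_000, 16_000, "+"))]
        acr = ACR(interval=GenomicInterval("c", 13_500, 13_600))
        assert associate_acr_genes([acr], genes) == {"all": ["gA", "gB"]}

    def test_matches_brute_force(self, rng):
        genes = [
            GeneModel(f"g{i:02d}", GenomicInterval("c", int(s), int(s) + 500, "+"))
            for i, s in enumerate(sorted(rng.integers(0, 100_000, size=30)))
        ]
        acrs = [
            ACR(interval=GenomicInterval("c", int(s), int(s) + 200))
            for s in rng.integers(0, 100_000, size=100)
        ]
        got = associate_acr_genes(acrs, genes, window=2000)
        expected = set()
        for a in acrs:
            for g in genes:
                if g.interval.start - 2000 < a.interval.end and a.interval.start < g.interval.end + 2000:
                    expected.add(g.gene_id)
        assert set(got.get("all", [])) == expected


class TestOverlapEnrichment:
    def test_saturation(self):
        # A = B = universe: every shuffle reproduces the full overlap, so by
        # the (1 + #{null >= obs}) / (1 + n) definition p is exactly 1
        universe = [f"u{i}" for i in range(30)]
        res = overlap_enrichment(universe, universe, universe, n_shuffles=100, seed=1)
        assert res.observed == 30
        assert np.all(res.null == 30)
        assert res.p == pytest.approx(1.0)

    def test_minimal_p_when_observed_unreachable(self):
        # observed beats every shuffle -> the smallest attainable p, 1/(1+n)
        universe = [f"u{i}" for i in range(40)]
        res = overlap_enrichment(universe[:10], universe[:10], universe,
                                 n_shuffles=100, seed=4)
        assert res.observed == 10
        assert res.p == pytest.approx(1 / 101)

    def test_disjoint_sets_p_near_one(self):
        universe = [f"u{i}" for i in range(100)]
        res = overlap_enrichment(universe[:40], universe[60:], universe, n_shuffles=200, seed=2)
        assert res.observed == 0
        assert res.p > 0.95

    def test_deterministic_under_seed(self):
        universe = [f"u{i}" for i in range(50)]
        a, b = universe[:10], universe[5:20]
        r1 = overlap_enrichment(a, b, universe, n_shuffles=50, seed=9)
        r2 = overlap_enrichment(a, b, universe, n_shuffles=50, seed=9)
        assert np.array_equal(r1.null, r2.null)

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            overlap_enrichment(["x"], ["a"], ["a", "b"], n_shuffles=5, seed=0)

    def test_fold_infinite_flag(self):
        universe = [f"u{i}" for i in range(10)]
        res = overlap_enrichment(universe[:1], [], universe, n_shuffles=20, seed=0)
        assert res.fold_infinite and np.isinf(res.fold)


class TestPromoterAccessibilityMatrix:
    def test_row_order_and_zero_promoter(self):
        genes = [
            GeneModel("g1", GenomicInterval("c", 10_000, 12_000, "+")),
            GeneModel("g2", GenomicInterval("c", 50_000, 52_000, "+")),
        ]
        sig = AccessibilitySignal("s", "t", 1, {"c": np.array([9_000, 9_100, 9_200])})
        mat = promoter_accessibility_matrix(genes, [sig], {"c": 100_000})
        assert list(mat.index) == ["g1", "g2"]
        assert mat.loc["g1", "s"] == pytest.approx(1e6)
        assert mat.loc["g2", "s"] == 0

    def test_planted_promoter_genes_score_open_over_closed(self, sim7):
        mat = promoter_accessibility_matrix(
            sim7.genes, sim7.signals, sim7.genome.chrom_lengths
        )
        from hexatac.differential_accessibility import cluster_patterns, tissue_means

        by_tissue = tissue_means(mat, sim7.sample_tissues)
        patterns = cluster_patterns(list(sim7.config.tissues))
        truth = sim7.truth.genes
        hosts = truth[truth.promoter_acr.notna()]
        acr_cluster = sim7.truth.acrs.set_index("acr_id")["cluster"]
        wins = total = 0
        for r in hosts.itertuples():
            open_t = patterns[acr_cluster[r.promoter_acr]]
            closed_t = [t for t in sim7.config.tissues if t not in open_t]
            open_mean = by_tissue.loc[r.gene_id, list(open_t)].mean()
            closed_mean = by_tissue.loc[r.gene_id, closed_t].mean()
            total += 1
            wins += open_mean > closed_mean
        assert wins / total >= 0.95


class TestClusterTrendConcordance:
    def test_promoter_accessibility_and_expression_rank_tissues_alike(self, sim7):
        """Mean per-cluster promoter accessibility and mean expression rank
        the open tissues above the closed ones for planted promoter genes."""
        from hexatac.differential_accessibility import cluster_patterns, tissue_means

        mat = promoter_accessibility_matrix(
            sim7.genes, sim7.signals, sim7.genome.chrom_lengths
        )
        acc = tissue_means(mat, sim7.sample_tissues)
        expr = sim7.expression.tissue_mean_tpm()
        patterns = cluster_patterns(list(sim7.config.tissues))
        truth = sim7.truth.genes
        acr_cluster = sim7.truth.acrs.set_index("acr_id")["cluster"]
        hosts = truth[truth.promoter_acr.notna()].copy()
        hosts["cluster"] = [acr_cluster[a] for a in hosts.promoter_acr]
        concordant = 0
        for label, sub in hosts.groupby("cluster"):
            open_t = list(patterns[label])
            closed_t = [t for t in sim7.config.tissues if t not in open_t]
            acc_gap = acc.loc[sub.gene_id, open_t].mean().mean() - acc.loc[
                sub.gene_id, closed_t
            ].mean().mean()
            expr_gap = expr.loc[sub.gene_id, open_t].mean().mean() - expr.loc[
                sub.gene_id, closed_t
            ].mean().mean()
            if acc_gap > 0 and expr_gap > 0:
                concordant += 1
        assert concordant >= 7  # of the 8 clusters
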