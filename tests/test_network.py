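"""Ensemble co-occurrence network: measures, candidate selection, ReBoot
null, bootstrap stability, Brown's method and the full pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import braycurtis

from rhizonet.network import (
    MEASURES,
    NetworkConfig,
    bootstrap_stability,
    build_network,
    cluster_abundance_profile,
    empirical_log_p_covariance,
    merge_kingdom_tables,
    merge_pvalues_brown,
    reboot_pvalue,
    score_all_pairs,
    score_matrix,
    select_initial_edges,
)
from rhizonet.synthetic import SyntheticConfig, generate_dataset
from rhizonet.tables_io import CountTable


def _random_table(rng, n_otus=10, n_samples=10, low=1, high=100) -> CountTable:
    return CountTable(
        pd.DataFrame(
            rng.integers(low, high, (n_otus, n_samples)),
            index=[f"o{i:02d}" for i in range(n_otus)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
    )


class TestMergeKingdomTables:
    def _pair(self, f_counts, b_counts):
        samples = [f"s{i}" for i in range(len(f_counts[0]))]
        f = CountTable(pd.DataFrame(f_counts, index=[f"f{i}" for i in range(len(f_counts))], columns=samples))
        b = CountTable(pd.DataFrame(b_counts, index=[f"b{i}" for i in range(len(b_counts))], columns=samples))
        return f, b

    def test_min_reads_boundary_strict_less_than(self):
        f, b = self._pair([[499], [500]], [[1000]])
        merged, kingdom = merge_kingdom_tables(f, b)
        assert "f0" not in merged.otu_ids and "f1" in merged.otu_ids

    def test_disjoint_ids_row_concatenated(self):
        f, b = self._pair([[600], [700]], [[800]])
        merged, kingdom = merge_kingdom_tables(f, b)
        assert merged.shape[0] == 3
        assert set(kingdom.unique()) == {"fungal", "bacterial"}

    def test_colliding_ids_get_kingdom_prefixes(self):
        samples = ["s0"]
        f = CountTable(pd.DataFrame([[600]], index=["otu1"], columns=samples))
        b = CountTable(pd.DataFrame([[700]], index=["otu1"], columns=samples))
        merged, kingdom = merge_kingdom_tables(f, b)
        assert set(merged.otu_ids) == {"F_otu1", "B_otu1"}
        assert kingdom["F_otu1"] == "fungal" and kingdom["B_otu1"] == "bacterial"

    def test_sample_mismatch_reported(self):
        f = CountTable(pd.DataFrame([[600]], index=["f0"], columns=["s0"]))
        b = CountTable(pd.DataFrame([[700]], index=["b0"], columns=["s1"]))
        with pytest.raises(ValueError, match="s0|s1"):
            merge_kingdom_tables(f, b)


class TestScores:
    def test_identical_profiles_limits(self):
        table = CountTable(
            pd.DataFrame(
                {"s1": [10, 10, 5], "s2": [20, 20, 1], "s3": [5, 5, 9], "s4": [8, 8, 2]},
                index=["a", "b", "c"],
            )
        )
        rel = table.relative_abundance().to_numpy()
        assert score_matrix(rel, "bray_curtis")[0, 1] == pytest.approx(1.0)
        assert score_matrix(rel, "kullback_leibler")[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert score_matrix(rel, "pearson")[0, 1] == pytest.approx(1.0)
        assert score_matrix(rel, "spearman")[0, 1] == pytest.approx(1.0)

    def test_disjoint_profiles_limits(self):
        table = CountTable(
            pd.DataFrame(
                {"s1": [1, 0, 3], "s2": [0, 1, 3], "s3": [1, 0, 3], "s4": [0, 1, 3]},
                index=["a", "b", "c"],
            )
        )
        rel = table.relative_abundance().to_numpy()
        assert score_matrix(rel, "bray_curtis")[0, 1] == pytest.approx(0.0)
        assert score_matrix(rel, "pearson")[0, 1] == pytest.approx(-1.0)

    def test_all_measures_match_textbook_oracles(self):
        rng = np.random.default_rng(0)
        table = _random_table(rng)
        rel = table.relative_abundance()
        r = rel.to_numpy()
        mats = {m: score_matrix(r, m) for m in MEASURES}
        eps = 1e-6
        for i in range(10):
            for j in range(i + 1, 10):
                x, y = r[i], r[j]
                assert mats["pearson"][i, j] == pytest.approx(
                    stats.pearsonr(x, y)[0], abs=1e-12
                )
                assert mats["spearman"][i, j] == pytest.approx(
                    stats.spearmanr(x, y)[0], abs=1e-12
                )
                assert mats["bray_curtis"][i, j] == pytest.approx(
                    1 - braycurtis(x, y), abs=1e-12
                )
                p = (x + eps) / (x + eps).sum()
                q = (y + eps) / (y + eps).sum()
                jeffreys = np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p))
                assert mats["kullback_leibler"][i, j] == pytest.approx(
                    -jeffreys, abs=1e-12
                )

    def test_constant_profile_skipped_for_correlations(self):
        table = CountTable(
            pd.DataFrame(
                {"s1": [5, 1], "s2": [5, 2], "s3": [5, 3], "s4": [5, 4]},
                index=["const", "vary"],
            )
        )
        # constant relative abundance requires constant column totals
        pairs = score_all_pairs(
            CountTable(table.df), "pearson"
        )
        # the pair may appear only if defined; a truly constant rel row is NaN
        rel = table.relative_abundance().to_numpy()
        mat = score_matrix(np.vstack([np.full(4, 0.5), rel[1]]), "pearson")
        assert np.isnan(mat[0, 1])

    def test_score_all_pairs_requires_four_samples(self):
        table = CountTable(pd.DataFrame({"s1": [1, 2], "s2": [3, 4], "s3": [5, 6]},
                                        index=["a", "b"]))
        with pytest.raises(ValueError):
            score_all_pairs(table, "pearson")


class TestInitialEdgeSelection:
    def _mats(self, scores_flat, n):
        mat = np.full((n, n), np.nan)
        iu, ju = np.triu_indices(n, k=1)
        mat[iu, ju] = scores_flat
        mat[ju, iu] = scores_flat
        return mat

    def test_small_instance_top_and_bottom(self):
        # 5 OTUs -> 10 pairs with distinct scores; n_initial_edges=4
        n = 5
        scores = np.array([0.9, 0.8, 0.7, 0.1, 0.0, -0.1, -0.5, -0.6, 0.2, 0.3])
        mats = {"pearson": self._mats(scores, n)}
        ids = [f"o{i}" for i in range(n)]
        cfg = NetworkConfig(measures=("pearson",), n_initial_edges=4, min_support=1)
        chosen = select_initial_edges(mats, ids, cfg)
        iu, ju = np.triu_indices(n, k=1)
        flat = {(int(a), int(b)): s for a, b, s in zip(iu, ju, scores)}
        chosen_scores = sorted(flat[p] for p in chosen)
        assert chosen_scores == [-0.6, -0.5, 0.8, 0.9]

    def test_everything_kept_when_budget_exceeds_pairs(self):
        rng = np.random.default_rng(1)
        n = 5
        mats = {"pearson": self._mats(rng.normal(size=10), n)}
        cfg = NetworkConfig(measures=("pearson",), n_initial_edges=2000, min_support=1)
        chosen = select_initial_edges(mats, [f"o{i}" for i in range(n)], cfg)
        assert len(chosen) == 10

    def test_tie_at_cutoff_prefers_lexicographically_smaller_pair(self):
        n = 4  # pairs: (0,1),(0,2),(0,3),(1,2),(1,3),(2,3)
        scores = np.array([0.5, 0.5, 0.1, 0.1, 0.1, 0.1])
        mats = {"pearson": self._mats(scores, n)}
        cfg = NetworkConfig(measures=("pearson",), n_initial_edges=2, min_support=1)
        chosen = select_initial_edges(mats, [f"o{i}" for i in range(n)], cfg)
        # top-1 tie between (0,1) and (0,2) -> (0,1); bottom-1 tie among
        # the 0.1s -> (0,3)
        assert (0, 1) in chosen and (0, 3) in chosen


class TestReboot:
    def test_null_pair_p_uniform(self):
        # independent profiles: p-values from the Gaussian null fit must
        # be roughly uniform (KS test not rejected at alpha=0.01)
        rng = np.random.default_rng(3)
        pvals = []
        for trial in range(120):
            table = _random_table(rng, n_otus=6, n_samples=12)
            p, _ = reboot_pvalue(table, ("o00", "o01"), "pearson",
                                 n_permutations=100, seed=int(rng.integers(2**31)))
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_correlation_detected(self):
        rng = np.random.default_rng(4)
        hits = 0
        trials = 30
        for trial in range(trials):
            g = rng.normal(size=30)
            base = np.exp(rng.normal(0, 0.8, (12, 30)))
            x = np.exp(1.0 * (np.sqrt(0.95) * g + np.sqrt(0.05) * rng.normal(size=30)))
            y = np.exp(1.0 * (np.sqrt(0.95) * g + np.sqrt(0.05) * rng.normal(size=30)))
            counts = np.vstack([base, 5 * x, 5 * y])
            counts = np.round(counts * 1000).astype(int)
            ids = [f"o{i:02d}" for i in range(14)]
            table = CountTable(pd.DataFrame(counts, index=ids,
                                            columns=[f"s{j}" for j in range(30)]))
            p, direction = reboot_pvalue(table, ("o12", "o13"), "spearman",
                                         n_permutations=100, seed=trial)
            if p < 0.01 and direction == "copresence":
                hits += 1
        assert hits / trials >= 0.95

    def test_zero_variance_null_gives_p_one(self, caplog):
        table = CountTable(
            pd.DataFrame({"s1": [5, 5], "s2": [5, 5], "s3": [5, 5], "s4": [5, 5]},
                         index=["a", "b"])
        )
        with caplog.at_level("WARNING"):
            p, _ = reboot_pvalue(table, ("a", "b"), "bray_curtis", seed=0)
        assert p == 1.0

    def test_observed_at_null_mean_gives_p_one(self):
        # symmetric construction: the observed score sits at the center
        # of the permutation null, so the two-sided Gaussian p is ~1
        rng = np.random.default_rng(5)
        table = _random_table(rng, n_otus=4, n_samples=10)
        p, _ = reboot_pvalue(table, ("o00", "o01"), "pearson",
                             n_permutations=400, seed=1)
        assert p > 0.2  # null pair: far from significance


class TestBootstrapStability:
    def test_consistent_association_is_stable(self):
        rng = np.random.default_rng(6)
        x = rng.integers(10, 100, 20)
        table = CountTable(
            pd.DataFrame(
                np.vstack([x, x * 2, rng.integers(10, 100, 20)]),
                index=["a", "b", "c"], columns=[f"s{i}" for i in range(20)],
            )
        )
        stable, (lo, hi) = bootstrap_stability(table, ("a", "b"), "pearson", seed=0)
        assert stable

    def test_outlier_widens_bootstrap_interval(self):
        # an edge carried by one extreme sample has a bootstrap
        # distribution that collapses whenever the outlier is resampled
        # out, so its percentile interval is far wider than that of a
        # consistent association of the same strength
        rng = np.random.default_rng(7)
        widths_outlier, widths_smooth = [], []
        for trial in range(10):
            x = np.ones(12, dtype=int) * 10 + rng.integers(0, 3, 12)
            y = np.ones(12, dtype=int) * 10 + rng.integers(0, 3, 12)
            x[0], y[0] = 500, 500
            table = CountTable(
                pd.DataFrame(np.vstack([x, y, rng.integers(5, 50, 12)]),
                             index=["a", "b", "c"],
                             columns=[f"s{i}" for i in range(12)])
            )
            _, (lo, hi) = bootstrap_stability(table, ("a", "b"), "pearson", seed=trial)
            widths_outlier.append(hi - lo)
            g = rng.integers(10, 100, 12)
            smooth = CountTable(
                pd.DataFrame(np.vstack([g, g * 2 + rng.integers(0, 4, 12),
                                        rng.integers(5, 50, 12)]),
                             index=["a", "b", "c"],
                             columns=[f"s{i}" for i in range(12)])
            )
            _, (lo, hi) = bootstrap_stability(smooth, ("a", "b"), "pearson", seed=trial)
            widths_smooth.append(hi - lo)
        assert np.median(widths_outlier) > 3 * np.median(widths_smooth)

    def test_unstable_fraction_near_nominal_under_null(self):
        # for a smooth statistic the observed score is the plug-in
        # estimate, so it falls outside its own central 95% bootstrap
        # interval for roughly 5% of edges
        rng = np.random.default_rng(70)
        unstable = total = 0
        for trial in range(60):
            table = _random_table(rng, n_otus=4, n_samples=14)
            stable, _ = bootstrap_stability(
                table, ("o00", "o01"), "pearson", n_bootstraps=200,
                seed=int(rng.integers(2**31)),
            )
            unstable += not stable
            total += 1
        assert unstable / total <= 0.25

    def test_full_percentile_range_always_stable(self):
        rng = np.random.default_rng(8)
        table = _random_table(rng, n_otus=3, n_samples=10)
        stable, _ = bootstrap_stability(
            table, ("o00", "o01"), "spearman", percentiles=(0, 100), seed=0
        )
        assert stable


class TestBrown:
    def test_independent_half_half_matches_fisher_value(self):
        # X = -2(ln .5 + ln .5) = 2.7726; chi2(4).sf = 0.5966
        merged = merge_pvalues_brown([0.5, 0.5], covariance=np.zeros((2, 2)))
        assert merged == pytest.approx(0.5966, abs=5e-5)
        assert merged == pytest.approx(
            float(stats.chi2.sf(-2 * np.log(0.25), 4)), abs=1e-12
        )

    def test_zero_covariance_reduces_to_fisher(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            k = rng.integers(2, 5)
            p = rng.uniform(1e-6, 1, k)
            fisher = float(stats.combine_pvalues(p, method="fisher")[1])
            assert merge_pvalues_brown(p, np.zeros((k, k))) == pytest.approx(
                fisher, abs=1e-10
            )

    def test_perfectly_dependent_duplicate_recovers_single_p(self):
        # cov(-2 ln p, -2 ln p) = 4 for uniform p; moment matching then
        # gives c=2, df=2 and the merged p equals the single p exactly
        cov = np.full((2, 2), 4.0)
        for p in (0.01, 0.2, 0.5, 0.9):
            assert merge_pvalues_brown([p, p], cov) == pytest.approx(p, abs=1e-12)

    def test_single_p_returned_unchanged(self):
        assert merge_pvalues_brown([0.123]) == 0.123
        assert merge_pvalues_brown([np.nan, 0.4]) == 0.4

    def test_empirical_covariance_of_duplicated_columns(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, size=2000)
        cov = empirical_log_p_covariance(np.column_stack([p, p]))
        # var of -2 ln U(0,1) is 4; duplicated columns -> cov == var
        assert cov[0, 1] == pytest.approx(4.0, abs=0.4)


class TestBuildNetwork:
    @pytest.fixture(scope="class")
    def planted_net(self):
        cfg = SyntheticConfig(
            sites=tuple(f"S{i}" for i in range(5)), habitats=("rhizosphere", "bulk"),
            n_fungal_otus=40, n_bacterial_otus=40, planted_enriched=0,
            site_effect_sd=0.0,
            planted_consortia=((10, 0.9, "copresence", "mixed"),), seed=13,
        )
        fungal, bacterial, md, truth = generate_dataset(cfg)
        merged, kingdom = merge_kingdom_tables(fungal, bacterial)
        net = build_network(merged, kingdom, NetworkConfig(seed=20))
        return net, truth, merged, md

    def test_planted_consortium_recovered(self, planted_net):
        net, truth, _, _ = planted_net
        planted = {(a, b) for a, b, d in truth.edges()}
        retained = net.retained_edges
        got = {tuple(sorted(p)) for p in zip(retained.otu_a, retained.otu_b)}
        recovered = planted & got
        assert len(recovered) / len(planted) >= 0.6
        directions = retained.set_index(
            retained.apply(lambda r: tuple(sorted((r.otu_a, r.otu_b))), axis=1)
        )["direction"]
        assert all(directions[e] == "copresence" for e in recovered)
        assert (retained["support"] >= 3).all()

    def test_retention_monotone_in_support_and_alpha(self, planted_net):
        net, _, _, _ = planted_net
        e = net.edges
        keep = lambda alpha, support: set(
            e.index[(e.q < alpha) & (e.support >= support) & (e.direction != "tie") & (e.direction != "")]
        )
        assert keep(0.05, 4) <= keep(0.05, 3)
        assert keep(0.01, 3) <= keep(0.05, 3)

    def test_bit_reproducible_under_seed(self):
        cfg = SyntheticConfig(
            sites=("A", "B"), n_fungal_otus=15, n_bacterial_otus=15,
            planted_enriched=0, planted_consortia=((6, 0.9, "copresence", "mixed"),),
            seed=3,
        )
        fungal, bacterial, _, _ = generate_dataset(cfg)
        merged, kingdom = merge_kingdom_tables(fungal, bacterial, min_otu_reads=100)
        n1 = build_network(merged, kingdom, NetworkConfig(seed=5, n_initial_edges=100))
        n2 = build_network(merged, kingdom, NetworkConfig(seed=5, n_initial_edges=100))
        pd.testing.assert_frame_equal(n1.edges, n2.edges)

    def test_two_disjoint_consortia_give_two_clusters(self):
        cfg = SyntheticConfig(
            sites=tuple(f"S{i}" for i in range(5)), habitats=("rhizosphere", "bulk"),
            n_fungal_otus=30, n_bacterial_otus=30, planted_enriched=0,
            site_effect_sd=0.0, noise_sd=0.7,
            planted_consortia=(
                (8, 0.9, "copresence", "fungal"),
                (8, 0.9, "copresence", "bacterial"),
            ),
            seed=17,
        )
        fungal, bacterial, md, truth = generate_dataset(cfg)
        merged, kingdom = merge_kingdom_tables(fungal, bacterial)
        net = build_network(merged, kingdom, NetworkConfig(seed=21))
        members_a = set(truth.consortia[0]["members"])
        members_b = set(truth.consortia[1]["members"])
        planted_clusters = [
            c for c in net.clusters if c & (members_a | members_b)
        ]
        # each consortium is recovered as its own connected component:
        # exactly two planted clusters, neither mixing the consortia
        assert len(planted_clusters) == 2
        for cluster in planted_clusters:
            assert not (cluster & members_a and cluster & members_b)

    def test_exclusion_consortium_labeled_exclusion(self):
        cfg = SyntheticConfig(
            sites=tuple(f"S{i}" for i in range(5)), habitats=("rhizosphere", "bulk"),
            n_fungal_otus=30, n_bacterial_otus=30, planted_enriched=0,
            site_effect_sd=0.0, consortium_sd=1.5,
            planted_consortia=((8, 0.9, "exclusion", "mixed"),), seed=19,
        )
        fungal, bacterial, _, truth = generate_dataset(cfg)
        merged, kingdom = merge_kingdom_tables(fungal, bacterial)
        net = build_network(merged, kingdom, NetworkConfig(seed=23))
        truth_dirs = {(a, b): d for a, b, d in truth.edges()}
        retained = net.retained_edges
        checked = agreed = 0
        for _, row in retained.iterrows():
            key = tuple(sorted((row.otu_a, row.otu_b)))
            if key in truth_dirs:
                checked += 1
                agreed += row.direction == truth_dirs[key]
        assert checked >= 5
        assert agreed / checked >= 0.8

    def test_empty_network_is_valid(self):
        rng = np.random.default_rng(30)
        table = _random_table(rng, n_otus=8, n_samples=8, low=50, high=60)
        net = build_network(table, None, NetworkConfig(min_otu_reads=0, seed=1,
                                                       n_initial_edges=10))
        assert net.graph.number_of_nodes() == 8
        assert isinstance(net.clusters, list)


class TestClusterAbundance:
    def test_cluster_of_all_otus_has_unit_abundance(self, site_metadata):
        import networkx as nx

        from rhizonet.network import MicrobialNetwork

        table = CountTable(
            pd.DataFrame(
                np.random.default_rng(0).integers(1, 50, (4, 6)),
                index=list("abcd"), columns=site_metadata.index,
            )
        )
        net = MicrobialNetwork(nx.Graph(), pd.DataFrame(), [set("abcd")], 0, None)
        profile, cmp = cluster_abundance_profile(net, table, site_metadata)
        assert np.allclose(profile.loc["cluster_1"], 1.0)

    def test_enriched_cluster_separated_by_letters(self):
        cfg = SyntheticConfig(seed=29)
        fungal, bacterial, md, truth = generate_dataset(cfg)
        merged, kingdom = merge_kingdom_tables(fungal, bacterial, min_otu_reads=0)
        import networkx as nx

        from rhizonet.network import MicrobialNetwork

        net = MicrobialNetwork(
            nx.Graph(), pd.DataFrame(), [set(truth.enriched)], 0, None
        )
        profile, cmp = cluster_abundance_profile(net, merged, md)
        c = cmp["cluster_1"]
        assert c is not None and c.p_value < 0.05
        rhizo_groups = [g for g in c.letters if g.endswith("rhizosphere")]
        bulk_groups = [g for g in c.letters if g.endswith("bulk")]
        # enriched OTUs are planted in the rhizosphere at every site
        assert all(
            c.means[r] > c.means[b]
            for r in rhizo_groups for b in bulk_groups
            if r.split(":")[0] == b.split(":")[0]
        )
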