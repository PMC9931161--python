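import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gdlink.discovery import (
    DiscoveryError,
    HoldoutSpec,
    _kmeans_1d_dp,
    build_holdout,
    cluster_success,
    compare_clusters,
    mean_link_probability,
    overlap,
    overlap_grid,
    rank_candidates,
    ratio_curve,
)
from gdlink.edge_sampling import make_labeled_set
from gdlink.embedding import EmbeddingConfig, embed_graph
from gdlink.gdps import GdpsContext
from gdlink.hetgraph import HetGraph
from gdlink.link_classifier import build_features, train
from tests.conftest import random_coexpression
from tests.test_tables_io import make_record


class TestBuildHoldout:
    @pytest.fixture
    def setting(self):
        # hand-traced cascade: mean DSI over genes {A:.9,B:.3,C:.8,D:.5,E:.9}
        # = 0.68; mean DPI over {A:.1,B:.8,C:.2,D:.5,E:.9} = 0.5
        recs = [
            make_record("A", "d1", dsi=0.9, dpi=0.1, year_initial=2020),
            make_record("B", "d1", dsi=0.3, dpi=0.8, year_initial=2020),
            make_record("C", "d1", dsi=0.8, dpi=0.2, year_initial=2020),
            make_record("A", "d2", dsi=0.9, dpi=0.1, year_initial=2020),
            make_record("D", "d2", dsi=0.5, dpi=0.5, year_initial=2010),
            make_record("E", "d3", dsi=0.9, dpi=0.9, year_initial=2020),
            make_record("C", "d3", dsi=0.8, dpi=0.2, year_initial=2020),
            make_record("C", "d4", dsi=0.8, dpi=0.2, year_initial=2020),
            make_record("A", "d5", dsi=0.9, dpi=0.1, year_initial=2020),
            make_record("B", "d5", dsi=0.3, dpi=0.8, year_initial=2020),
        ]
        g_prime = HetGraph(
            disease_nodes={"d1", "d2", "d3", "d4", "d5"},
            gene_nodes={"A", "B", "C", "D", "E", "X"},
            gd_edges={("C", "d1")},  # (C, d1) still known in G'
        )
        return recs, g_prime

    def test_hand_traced_cascade(self, setting):
        recs, g_prime = setting
        out = build_holdout(recs, g_prime, HoldoutSpec(year=2020))
        # d2: only one 2020 gene -> dropped; d4: single gene -> dropped;
        # d1: A survives (B fails DSI/DPI, C is an edge of G');
        # d3: C survives (E fails DPI); d5: A survives (B fails)
        assert out == {"d1": {"A"}, "d3": {"C"}, "d5": {"A"}}

    def test_pair_in_g_prime_excluded(self, setting):
        recs, g_prime = setting
        out = build_holdout(recs, g_prime, HoldoutSpec(year=2020))
        assert "C" not in out.get("d1", set())

    def test_dsi_dpi_rules_can_be_disabled(self, setting):
        recs, g_prime = setting
        out = build_holdout(
            recs,
            g_prime,
            HoldoutSpec(year=2020, dsi_rule=False, dpi_rule=False),
        )
        assert out["d1"] == {"A", "B"}
        assert out["d3"] == {"C", "E"}

    def test_min_new_genes_validated(self):
        with pytest.raises(DiscoveryError):
            HoldoutSpec(year=2020, min_new_genes=1)

    def test_empty_holdout_warns_and_returns_empty(self, setting, caplog):
        recs, g_prime = setting
        with caplog.at_level("WARNING"):
            out = build_holdout(recs, g_prime, HoldoutSpec(year=1999))
        assert out == {}


class TestOverlap:
    RANKED = [(f"g{i}", 1.0 - i / 20) for i in range(20)]

    def test_all_captured_is_one(self):
        rep = overlap(self.RANKED, {"g0", "g1", "g2"}, 20)
        assert rep.overlap == 1.0

    def test_disjoint_is_zero(self):
        rep = overlap(self.RANKED, {"zz1", "zz2"}, 50)
        assert rep.overlap == 0.0

    def test_three_of_four(self):
        i_d = {"g0", "g1", "g2", "zz"}
        assert overlap(self.RANKED, i_d, 20).overlap == 0.75

    def test_ceil_cutoff(self):
        # 11% of 20 candidates -> ceil(2.2) = 3 genes in P_f
        rep = overlap(self.RANKED, {"g2"}, 11)
        assert rep.p_f == {"g0", "g1", "g2"}
        assert rep.overlap == 1.0

    def test_empty_i_d_rejected(self):
        with pytest.raises(DiscoveryError):
            overlap(self.RANKED, set(), 10)

    def test_f_out_of_range_rejected(self):
        with pytest.raises(DiscoveryError):
            overlap(self.RANKED, {"g0"}, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_monotone_in_f(self, data):
        n = data.draw(st.integers(5, 40))
        ranked = [(f"g{i}", 1.0 - i / n) for i in range(n)]
        i_d = set(
            data.draw(
                st.lists(
                    st.sampled_from([g for g, _ in ranked] + ["far1", "far2"]),
                    min_size=1,
                    max_size=6,
                    unique=True,
                )
            )
        )
        grid = overlap_grid(ranked, i_d)
        values = [grid[f].overlap for f in sorted(grid)]
        assert values == sorted(values)


class TestRatioCurve:
    def _grid(self, ranked, i_d, disease):
        return overlap_grid(ranked, i_d, disease)

    def test_all_overlap_one_at_small_f(self):
        ranked = [(f"g{i}", 1.0 - i / 10) for i in range(10)]
        reports = {f"d{j}": self._grid(ranked, {"g0"}, f"d{j}") for j in range(10)}
        curve, best_f = ratio_curve(reports)
        assert curve[10] == 10 / 10
        assert best_f == 10

    def test_zero_everywhere_without_full_overlap(self):
        ranked = [(f"g{i}", 1.0 - i / 10) for i in range(10)]
        reports = {"d0": self._grid(ranked, {"absent"}, "d0")}
        curve, _ = ratio_curve(reports)
        assert all(v == 0.0 for v in curve.values())

    def test_denominator_is_percentage_number(self):
        ranked = [(f"g{i}", 1.0 - i / 10) for i in range(10)]
        reports = {"d0": self._grid(ranked, {"g9"}, "d0")}
        curve, _ = ratio_curve(reports)
        assert curve[100] == 1 / 100

    def test_empty_reports_rejected(self):
        with pytest.raises(DiscoveryError):
            ratio_curve({})


class TestRankCandidates:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(31)
        genes = [f"G{i:03d}" for i in range(40)]
        diseases = [f"D{i}" for i in range(5)]
        edges = set()
        for d in diseases:
            for i in rng.choice(40, size=8, replace=False):
                edges.add((genes[i], d))
        g = HetGraph(
            disease_nodes=set(diseases), gene_nodes=set(genes), gd_edges=edges
        )
        matrix = random_coexpression(40, seed=32)
        ctx = GdpsContext(graph=g, matrix=matrix)
        labeled, g_prime = make_labeled_set(g, 0.2, 0.7, ctx, seed=33)
        ctx = GdpsContext(graph=g_prime, matrix=matrix)
        tbl = embed_graph(g_prime, EmbeddingConfig(dimensions=16, epochs=2, seed=34))
        feats = build_features(labeled, tbl, ctx, split="train")
        model = train(feats, seed=0)
        return model, g_prime, tbl, ctx

    def test_candidate_universe_size(self, fitted):
        model, g_prime, tbl, ctx = fitted
        d = sorted(g_prime.disease_nodes)[0]
        candidates = g_prime.gene_nodes - g_prime.genes_of(d)
        ranked = rank_candidates(model, g_prime, tbl, ctx, d)
        assert len(ranked) <= len(candidates)
        assert {g for g, _ in ranked} <= candidates

    def test_sorted_descending_with_threshold(self, fitted):
        model, g_prime, tbl, ctx = fitted
        for d in sorted(g_prime.disease_nodes):
            ranked = rank_candidates(model, g_prime, tbl, ctx, d)
            probs = [p for _, p in ranked]
            assert probs == sorted(probs, reverse=True)
            assert all(p >= 0.5 for p in probs)

    def test_disease_adjacent_to_all_genes_empty(self, fitted):
        model, _, tbl, ctx = fitted
        genes = {"a", "b"}
        g = HetGraph(
            disease_nodes={"d"},
            gene_nodes=genes,
            gd_edges={("a", "d"), ("b", "d")},
        )
        tbl2 = embed_graph(g, EmbeddingConfig(dimensions=16, epochs=2, seed=1))
        ctx2 = GdpsContext(graph=g, matrix=ctx.matrix)
        assert rank_candidates(model, g, tbl2, ctx2, "d") == []

    def test_unknown_disease(self, fitted):
        model, g_prime, tbl, ctx = fitted
        with pytest.raises(DiscoveryError):
            rank_candidates(model, g_prime, tbl, ctx, "nope")


class TestClusterSuccess:
    def test_two_separated_groups(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(0.2, 0.01, 10)
        hi = rng.normal(0.8, 0.01, 10)
        probs = {f"d{i}": v for i, v in enumerate(np.concatenate([lo, hi]))}
        model = cluster_success(probs)
        assert model.k == 2
        assert model.centers == sorted(model.centers)
        for i in range(10):
            assert model.assignment[f"d{i}"] == 0
            assert model.assignment[f"d{i + 10}"] == 1

    def test_constant_values_single_effective_cluster(self):
        probs = {f"d{i}": 0.5 for i in range(10)}
        model = cluster_success(probs)
        assert model.k == 1
        assert set(model.assignment.values()) == {0}

    def test_too_few_diseases(self):
        with pytest.raises(DiscoveryError):
            cluster_success({"d0": 0.5})

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 1, 15)
        probs = {f"d{i}": v for i, v in enumerate(values)}
        shuffled = {k: probs[k] for k in reversed(sorted(probs))}
        m1 = cluster_success(probs)
        m2 = cluster_success(shuffled)
        assert m1.assignment == m2.assignment
        assert m1.k == m2.k

    def test_band_mapping_from_overlaps(self):
        probs = {"a": 0.1, "b": 0.12, "c": 0.9, "e": 0.92}
        overlaps = {"a": 0.2, "b": 0.0, "c": 1.0, "e": 1.0}
        model = cluster_success(probs, overlaps=overlaps)
        assert model.overlap_band[model.assignment["a"]] == "low"
        assert model.overlap_band[model.assignment["c"]] == "high"

    def test_dp_beats_lloyd_restarts(self):
        """The DP solution is globally optimal: its WCSS never exceeds
        the best of many Lloyd restarts (sklearn KMeans oracle)."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(7)
        for trial in range(5):
            x = np.sort(rng.uniform(0, 1, 40))
            for k in (2, 3, 5):
                _, wcss = _kmeans_1d_dp(x, k)
                km = KMeans(n_clusters=k, n_init=20, random_state=trial).fit(
                    x.reshape(-1, 1)
                )
                assert wcss <= km.inertia_ + 1e-9


class TestCompareClusters:
    def test_disjoint_supports_significant(self):
        rng = np.random.default_rng(1)
        groups = {
            0: rng.uniform(0.0, 0.2, 15),
            1: rng.uniform(0.4, 0.6, 15),
            2: rng.uniform(0.8, 1.0, 15),
        }
        report = compare_clusters(groups)
        assert report["omnibus"]["p"] < 0.001
        assert all(v["p"] < 0.01 for v in report["pairwise"].values())
        assert report["multiplicity_correction"] == "none"

    def test_two_groups_matches_rank_sum(self):
        """With two tie-free groups the omnibus test reduces to the
        normal-approximation rank-sum test."""
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 22)
        report = compare_clusters({0: a, 1: b})
        _, p_rs = stats.ranksums(a, b)
        assert report["omnibus"]["p"] == pytest.approx(p_rs, abs=1e-10)

    def test_type_one_error_rate_near_alpha(self):
        """Under the null (identical distributions) the omnibus test
        rejects at about the nominal rate."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            g1, g2 = rng.normal(size=12), rng.normal(size=12)
            _, p = stats.kruskal(g1, g2)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_small_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="excluded"):
            report = compare_clusters(
                {0: rng.normal(size=10), 1: [0.5], 2: rng.normal(size=10)}
            )
        assert report["skipped_clusters"] == [1]

    def test_insufficient_clusters_error(self):
        with pytest.raises(DiscoveryError):
            compare_clusters({0: [0.1], 1: [0.2]})


def test_mean_link_probability():
    ranked = {"d1": [("a", 0.9), ("b", 0.7)], "d2": [], "d3": [("c", 0.6)]}
    out = mean_link_probability(ranked)
    assert out == {"d1": pytest.approx(0.8), "d3": pytest.approx(0.6)}
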