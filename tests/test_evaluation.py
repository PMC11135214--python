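"""Evaluation metrics: edge scores, networks, hubs, communities."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import transkingdom as tk
from transkingdom.evaluation import (
    LotkaVolterraConfig,
    bias_test,
    community_scores,
    detect_communities,
    edge_auc,
    edge_partition,
    edge_r2,
    hub_r2,
    hub_scores,
    lv_keystoneness,
    mean_relative_edge_strength,
    threshold_network,
    top_n_accuracy,
)


def _sym(mat):
    mat = np.asarray(mat, dtype=float)
    return 0.5 * (mat + mat.T)


class TestEdgePartition:
    def test_four_taxon_enumeration(self):
        m = _sym(np.arange(16).reshape(4, 4))
        kingdom = np.array(["A", "A", "B", "B"])
        intra, cross = edge_partition(m, kingdom)
        assert intra.size == 2  # (0,1) and (2,3)
        assert cross.size == 4

    def test_single_kingdom_has_no_cross(self):
        m = np.eye(3)
        intra, cross = edge_partition(m, np.array(["A"] * 3))
        assert cross.size == 0 and intra.size == 3

    def test_benchmark_scale_counts(self):
        kingdom = np.array(["A"] * 250 + ["B"] * 250)
        m = np.eye(500)
        intra, cross = edge_partition(m, kingdom)
        assert intra.size + cross.size == 500 * 499 // 2 == 124_750
        assert cross.size == 250 * 250 == 62_500

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            edge_partition(np.ones((2, 3)), np.array(["A", "B"]))


class TestMeanRelativeEdgeStrength:
    def test_hand_arithmetic(self):
        m = np.zeros((4, 4))
        m[0, 1] = 2.0
        m[2, 3] = 1.0
        m[0, 2] = -1.0
        m[1, 3] = -1.0
        m = _sym(2 * m)  # _sym halves the off-diagonals
        kingdom = np.array(["A", "A", "B", "B"])
        mri, mrc = mean_relative_edge_strength(m, kingdom)
        assert mri == pytest.approx(0.75)
        assert mrc == pytest.approx(-0.25)

    def test_scale_invariance(self, small_model):
        cov = small_model.covariance
        out1 = mean_relative_edge_strength(cov, small_model.kingdom)
        out2 = mean_relative_edge_strength(17.3 * cov, small_model.kingdom)
        assert out1 == pytest.approx(out2)

    def test_balanced_truth_is_near_zero(self):
        """Ground-truth covariances with even sign balance have small mean
        relative edge strengths in both groups."""
        for seed in range(5):
            model = tk.generate_ground_truth(n_taxa=100, seed=seed)
            mri, mrc = mean_relative_edge_strength(model.covariance, model.kingdom)
            # ~200 edges of magnitude <=1 spread over 4950 pairs
            assert abs(mri) < 0.05 and abs(mrc) < 0.05

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mean_relative_edge_strength(np.eye(3), np.array(["A", "A", "B"]))


class TestBiasTest:
    def test_identical_groups_not_significant(self):
        vals = np.arange(20.0)
        assert bias_test(vals, vals) > 0.9

    def test_separated_groups_highly_significant(self):
        assert bias_test(np.arange(20.0) + 100, np.arange(20.0)) < 1e-6

    def test_minimal_groups_valid(self):
        p = bias_test(np.array([1.0]), np.array([2.0]))
        assert 0 < p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bias_test(np.array([]), np.array([1.0]))


class TestEdgeR2:
    @pytest.fixture
    def truth(self, small_model):
        return small_model.covariance

    def test_identity_is_perfect(self, truth, small_model):
        assert edge_r2(truth, truth, small_model.kingdom) == pytest.approx(1.0)

    def test_affine_invariance(self, truth, small_model):
        assert edge_r2(truth, 2 * truth + 3, small_model.kingdom) == pytest.approx(1.0)

    def test_matches_closed_form_ols(self, truth, small_model):
        rng = np.random.default_rng(0)
        est = truth.copy()
        iu, ju = np.triu_indices(truth.shape[0], k=1)
        flip = rng.random(iu.size) < 0.5
        est[iu[flip], ju[flip]] *= -1
        est[ju[flip], iu[flip]] = est[iu[flip], ju[flip]]
        t, e = truth[iu, ju], est[iu, ju]
        # closed-form OLS R^2 = 1 - SSR/SST with beta = cov/var
        beta = np.cov(t, e, ddof=1)[0, 1] / np.var(e, ddof=1)
        alpha = t.mean() - beta * e.mean()
        ssr = np.sum((t - alpha - beta * e) ** 2)
        sst = np.sum((t - t.mean()) ** 2)
        expected = 1 - ssr / sst
        got = edge_r2(truth, est, small_model.kingdom)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_constant_estimate_scores_zero(self, truth, small_model):
        assert edge_r2(truth, np.eye(truth.shape[0]), small_model.kingdom) == 0.0


def _brute_force_auc(labels, scores):
    """Fraction of positive-negative pairs ranked correctly (ties = 1/2)."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEdgeAuc:
    def test_identity_is_perfect(self, small_model):
        truth = small_model.covariance
        assert edge_auc(truth, truth, small_model.kingdom) == pytest.approx(1.0)

    def test_constant_scorer_is_half(self, small_model):
        truth = small_model.covariance
        est = np.ones_like(truth)
        assert edge_auc(truth, est, small_model.kingdom) == pytest.approx(0.5)

    def test_six_pair_toy(self):
        # 4 taxa -> 6 pairs; positives are the 1st and 3rd strongest scores
        truth = np.zeros((4, 4))
        truth[0, 1] = 1.0  # strongest score
        truth[1, 2] = 1.0  # third-strongest score
        truth = _sym(2 * truth)
        est = np.zeros((4, 4))
        pairs = [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (2, 3)]
        for (i, j), s in zip(pairs, [0.9, 0.8, 0.4, 0.3, 0.2, 0.1]):
            est[i, j] = est[j, i] = s
        kingdom = np.array(["A", "A", "B", "B"])
        assert edge_auc(truth, est, kingdom) == pytest.approx(0.875)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 10)  # <= 45 pairs
        truth = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        present = rng.random(iu.size) < 0.3
        if not present.any() or present.all():
            present[0] = True
            present[1] = False
        truth[iu[present], ju[present]] = rng.choice([-1, 1], present.sum())
        truth = _sym(truth + truth.T)
        est = _sym(rng.standard_normal((n, n)))
        # duplicate some scores to exercise the midrank convention
        est[iu[0], ju[0]] = est[iu[2], ju[2]]
        kingdom = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        got = edge_auc(truth, est, kingdom)
        expected = _brute_force_auc(truth[iu, ju] != 0, np.abs(est[iu, ju]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_strong_subset_excludes_weak_true_edges(self):
        truth = np.zeros((4, 4))
        truth[0, 1] = 2.0  # strong true edge
        truth[2, 3] = 0.1  # weak true edge: dropped entirely
        truth = _sym(2 * truth)
        est = _sym(np.full((4, 4), 0.5)) - 0.5 * np.eye(4)
        est[0, 1] = est[1, 0] = 0.9
        kingdom = np.array(["A", "A", "B", "B"])
        auc = edge_auc(truth, est, kingdom, strong_fraction=0.5)
        assert auc == pytest.approx(1.0)

    def test_no_positives_rejected(self):
        kingdom = np.array(["A", "B"])
        with pytest.raises(ValueError):
            edge_auc(np.eye(2), np.eye(2), kingdom)


class TestTopNAccuracy:
    def test_identity_is_perfect(self, small_model):
        truth = small_model.covariance
        n_edges = small_model.graph.n_edges
        out = top_n_accuracy(truth, truth, small_model.kingdom, (5, n_edges))
        assert out[5] == 1.0 and out[n_edges] == 1.0

    def test_sign_flip_scores_zero(self, small_model):
        truth = small_model.covariance
        out = top_n_accuracy(truth, -truth, small_model.kingdom, (10,))
        assert out[10] == 0.0

    def test_one_wrong_sign_among_top_three(self):
        truth = np.zeros((4, 4))
        truth[0, 1], truth[0, 2], truth[1, 2] = 3.0, 2.0, -1.0
        truth = _sym(2 * truth)
        est = np.abs(truth)  # the negative edge is inferred with wrong sign
        out = top_n_accuracy(truth, est, np.array(["A", "A", "B", "B"]), (3,))
        assert out[3] == pytest.approx(2 / 3)

    def test_oversized_n_rejected(self):
        with pytest.raises(ValueError):
            top_n_accuracy(np.eye(3), np.eye(3), np.array(["A", "A", "B"]), (4,))


class TestThresholdNetwork:
    def test_full_fraction_keeps_all_pairs(self):
        est = _sym(np.arange(9).reshape(3, 3))
        g = threshold_network(est, 1.0)
        assert g.number_of_edges() == 3

    def test_counting(self):
        est = _sym(np.random.default_rng(0).standard_normal((5, 5)))
        g = threshold_network(est, 0.1)  # 10 pairs -> 1 edge
        assert g.number_of_edges() == 1

    def test_tie_break_deterministic(self):
        est = np.ones((4, 4)) - np.eye(4)
        g1 = threshold_network(est, 0.5)
        g2 = threshold_network(est, 0.5)
        assert sorted(g1.edges) == sorted(g2.edges)
        assert g1.number_of_edges() == 3  # ceil(0.5 * 6)

    def test_signed_weights_stored(self):
        est = np.zeros((3, 3))
        est[0, 1] = est[1, 0] = -2.0
        g = threshold_network(est, 0.34)
        assert g[0][1]["weight"] == -2.0
        assert g[0][1]["abs_weight"] == 2.0


class TestHubScores:
    def test_star_betweenness_and_degree(self):
        g = nx.star_graph(4)  # node 0 is the hub
        g = nx.Graph(g)
        bet = hub_scores(g, "betweenness")
        assert bet[0] == pytest.approx(1.0)
        assert np.allclose(bet[1:], 0.0)
        deg = hub_scores(g, "degree")
        assert deg[0] == pytest.approx(1.0)
        assert np.allclose(deg[1:], 0.25)

    def test_cycle_eigenvector_uniform(self):
        g = nx.cycle_graph(4)
        ev = hub_scores(g, "eigenvector")
        assert np.allclose(ev, ev[0])

    def test_isolated_nodes_score_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edge(0, 1)
        for metric in ("betweenness", "degree", "eigenvector"):
            s = hub_scores(g, metric)
            assert s[2] == 0.0 and s[3] == 0.0

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            hub_scores(nx.path_graph(3), "pagerank")


class TestHubR2:
    def test_identity_and_affine(self):
        x = np.array([0.1, 0.5, 0.9, 0.2])
        assert hub_r2(x, x) == pytest.approx(1.0)
        assert hub_r2(x, 3 * x + 1) == pytest.approx(1.0)

    def test_constant_estimate_scores_zero(self):
        assert hub_r2(np.array([1.0, 2.0]), np.array([3.0, 3.0])) == 0.0


class TestLvKeystoneness:
    def test_no_interactions_no_impact(self):
        est = np.diag([1.0, 2.0, 3.0])
        scores = lv_keystoneness(est)
        assert np.all(scores < 1e-6)

    def test_disconnected_blocks_are_independent(self):
        est = np.eye(4)
        est[0, 1] = est[1, 0] = 0.8
        est[2, 3] = est[3, 2] = -0.5
        cfg = LotkaVolterraConfig()
        scores = lv_keystoneness(est, cfg)
        # knocking out taxon 0 perturbs taxon 1 but not taxa 2, 3: verify via
        # the analytic interior equilibrium of the reduced system
        a = est - np.diag(np.diag(est))
        a = a * (cfg.interaction_scale / np.abs(a).max()) - np.eye(4)
        base = np.linalg.solve(-a, np.ones(4))
        keep = np.array([False, True, True, True])
        sub = np.linalg.solve(-a[np.ix_(keep, keep)], np.ones(3))
        expected = np.sum(np.abs(base[keep] - sub)) / np.sum(base[keep] + sub)
        assert scores[0] == pytest.approx(expected, abs=1e-4)
        assert scores[0] > 0

    def test_strong_interactor_scores_highest(self):
        """3-taxon chain: the analytic-equilibrium oracle agrees and the
        strongly coupled taxon dominates."""
        est = np.eye(3)
        est[0, 1] = est[1, 0] = 1.0   # strong pair
        est[1, 2] = est[2, 1] = 0.2   # weak link
        cfg = LotkaVolterraConfig()
        scores = lv_keystoneness(est, cfg)
        a = est - np.diag(np.diag(est))
        a = a * (cfg.interaction_scale / np.abs(a).max()) - np.eye(3)
        base = np.linalg.solve(-a, np.ones(3))
        expected = []
        for k in range(3):
            keep = np.arange(3) != k
            sub = np.linalg.solve(-a[np.ix_(keep, keep)], np.ones(2))
            expected.append(
                np.sum(np.abs(base[keep] - sub)) / np.sum(base[keep] + sub)
            )
        assert np.allclose(scores, expected, atol=1e-4)
        assert np.argmax(scores) == np.argmax(expected)


class TestCommunities:
    def test_two_cliques_recovered(self):
        g = nx.union(nx.complete_graph(5), nx.complete_graph(5), rename=("a", "b"))
        g = nx.convert_node_labels_to_integers(g)
        nx.set_edge_attributes(g, 1.0, "abs_weight")
        parts = detect_communities(g, seed=0)
        assert sorted(map(sorted, parts)) == [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

    def test_edgeless_nodes_are_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        parts = detect_communities(g, seed=0)
        assert sorted(map(sorted, parts)) == [[0], [1], [2], [3]]

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_partition_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        truth = np.repeat([0, 1], n // 2)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                p = 0.8 if truth[i] == truth[j] else 0.02
                if rng.random() < p:
                    g.add_edge(i, j, abs_weight=1.0)
        parts = detect_communities(g, seed=seed)
        labels = np.empty(n, dtype=int)
        for c, nodes in enumerate(parts):
            for v in nodes:
                labels[v] = c
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_community_scores_identity(self):
        parts = [{0, 1, 2}, {3, 4}]
        ev = community_scores(parts, parts)
        assert np.allclose(ev.overlap_scores, 1.0)
        assert np.allclose(ev.inclusion_scores, 1.0)

    def test_nested_community_scores(self):
        recon = [{0, 1}, {2, 3, 4, 5}]
        truth = [{0, 1, 2, 3}, {4, 5}]
        ev = community_scores(recon, truth)
        # {0,1} inside a truth community of size 4: inclusion 1, overlap 0.5
        assert ev.inclusion_scores[0] == pytest.approx(1.0)
        assert ev.overlap_scores[0] == pytest.approx(0.5)

    def test_split_community_inclusion(self):
        recon = [{0, 1, 2, 3}]
        truth = [{0, 1, 8, 9}, {2, 3, 10, 11}]
        with pytest.raises(ValueError):
            community_scores(recon, truth)
        truth = [{0, 1}, {2, 3}]
        ev = community_scores(recon, truth)
        assert ev.inclusion_scores[0] == pytest.approx(0.5)

    def test_mismatched_nodes_rejected(self):
        with pytest.raises(ValueError):
            community_scores([{0, 1}], [{0, 2}])
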