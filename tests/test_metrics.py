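"""Thresholding, weighted graph metrics, null ensembles and AUC summaries."""

import numpy as np
import pytest

from plinet.connectivity import PLIMatrix
from plinet.metrics import (
    DEFAULT_SPARSITY_GRID,
    MetricCurve,
    RandomEnsemble,
    ThresholdedGraph,
    global_metrics,
    maslov_sneppen_rewire,
    proportional_threshold,
    random_ensemble,
    small_world_sigma,
    sparsity_sweep,
    strength_degree,
)

from conftest import (
    floyd_warshall_oracle,
    onnela_clustering_oracle,
    triangle_count_oracle,
)


def random_pli_matrix(rng, n, subject_id="S1"):
    v = rng.uniform(0.05, 1.0, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return PLIMatrix(
        subject_id=subject_id,
        channel_labels=tuple(f"E{i+1}" for i in range(n)),
        values=v,
        n_epochs=1,
    )


def graph_from_weights(W, sparsity=1.0):
    W = np.asarray(W, float)
    i, j = np.nonzero(np.triu(W, 1))
    return ThresholdedGraph(
        n_nodes=W.shape[0],
        edges=np.column_stack([i, j]),
        weights=W[i, j],
        sparsity=sparsity,
    )


def ring_lattice(n, k, weight=1.0):
    """Each node connected to its k nearest neighbours per side."""
    W = np.zeros((n, n))
    for i in range(n):
        for d in range(1, k + 1):
            j = (i + d) % n
            W[i, j] = W[j, i] = weight
    return graph_from_weights(W)


class TestProportionalThreshold:
    def test_sparsity_one_keeps_complete_graph(self, rng):
        mat = random_pli_matrix(rng, 6)
        g = proportional_threshold(mat, 1.0)
        assert g.n_edges == 15
        assert np.allclose(g.weight_matrix(), mat.values)

    def test_four_nodes_half_sparsity_keeps_three_heaviest(self):
        v = np.zeros((4, 4))
        weights = {(0, 1): 0.9, (0, 2): 0.1, (0, 3): 0.8,
                   (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.7}
        for (i, j), w in weights.items():
            v[i, j] = v[j, i] = w
        mat = PLIMatrix(subject_id="S", channel_labels=("a", "b", "c", "d"),
                        values=v, n_epochs=1)
        g = proportional_threshold(mat, 0.5)
        kept = {tuple(e) for e in g.edges}
        assert kept == {(0, 1), (0, 3), (2, 3)}
        assert sorted(g.weights) == [0.7, 0.8, 0.9]

    def test_edge_count_follows_rounding_identity(self, rng):
        for n, s in [(16, 0.25), (12, 0.1), (9, 0.5)]:
            g = proportional_threshold(random_pli_matrix(rng, n), s)
            assert g.n_edges == round(s * n * (n - 1) / 2)
            # binary mean degree is fixed by the edge count alone
            assert g.binary_degrees().mean() == pytest.approx(
                2 * g.n_edges / n
            )

    def test_exact_mean_degree_when_count_is_integral(self, rng):
        # s * N(N-1)/2 integral => binary mean degree == s * (N-1) exactly
        g = proportional_threshold(random_pli_matrix(rng, 16), 0.25)
        assert g.binary_degrees().mean() == 0.25 * 15

    def test_tie_break_is_stable_index_order(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        mat = PLIMatrix(subject_id="S", channel_labels=("a", "b", "c", "d"),
                        values=v, n_epochs=1)
        g = proportional_threshold(mat, 0.5)
        assert [tuple(e) for e in g.edges] == [(0, 1), (0, 2), (0, 3)]

    @pytest.mark.parametrize("s", [0.0, -0.1, 1.2])
    def test_invalid_sparsity_rejected(self, rng, s):
        with pytest.raises(ValueError, match="sparsity"):
            proportional_threshold(random_pli_matrix(rng, 5), s)


class TestStrengthDegree:
    def test_isolated_node_and_star_center(self):
        W = np.zeros((5, 5))
        for leaf in (1, 2, 3):
            W[0, leaf] = W[leaf, 0] = 1.0
        g = graph_from_weights(W)
        s = strength_degree(g)
        assert s[0] == 3.0
        assert s[4] == 0.0

    def test_matches_row_sum_oracle(self, rng):
        mat = random_pli_matrix(rng, 10)
        g = proportional_threshold(mat, 0.4)
        assert np.allclose(strength_degree(g), g.weight_matrix().sum(axis=1))


class TestGlobalMetrics:
    def test_complete_unit_graph_closed_form(self):
        W = np.ones((5, 5)) - np.eye(5)
        m = global_metrics(graph_from_weights(W))
        assert m["Cp"] == pytest.approx(1.0)
        assert m["Lp"] == pytest.approx(1.0)
        assert m["Eg"] == pytest.approx(1.0)
        assert m["Eloc"] == pytest.approx(1.0)

    def test_three_node_path_hand_computed(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        m = global_metrics(graph_from_weights(W))
        assert m["Lp"] == pytest.approx(4.0 / 3.0)
        assert m["Eg"] == pytest.approx(5.0 / 6.0)
        assert m["Cp"] == pytest.approx(0.0)

    def test_path_metrics_match_floyd_warshall_oracle(self, rng):
        for _ in range(3):
            mat = random_pli_matrix(rng, 12)
            g = proportional_threshold(mat, 0.3)
            dist = floyd_warshall_oracle(g.weight_matrix())
            off = ~np.eye(12, dtype=bool)
            finite = dist[off][np.isfinite(dist[off])]
            lp_oracle = finite.mean()
            inv = 1.0 / dist[off]
            inv[~np.isfinite(inv)] = 0.0
            eg_oracle = inv.mean()
            m = global_metrics(g)
            assert m["Lp"] == pytest.approx(lp_oracle, abs=1e-10)
            assert m["Eg"] == pytest.approx(eg_oracle, abs=1e-10)

    def test_clustering_matches_onnela_oracle(self, rng):
        for _ in range(3):
            g = proportional_threshold(random_pli_matrix(rng, 6), 0.6)
            cp_oracle = onnela_clustering_oracle(g.weight_matrix()).mean()
            assert global_metrics(g)["Cp"] == pytest.approx(cp_oracle, abs=1e-10)

    def test_eloc_matches_neighborhood_oracle(self, rng):
        g = proportional_threshold(random_pli_matrix(rng, 6), 0.6)
        W = g.weight_matrix()
        terms = []
        for v in range(6):
            nbrs = np.where(W[v] > 0)[0]
            if len(nbrs) < 2:
                terms.append(0.0)
                continue
            sub = W[np.ix_(nbrs, nbrs)]
            dist = floyd_warshall_oracle(sub)
            off = ~np.eye(len(nbrs), dtype=bool)
            inv = 1.0 / dist[off]
            inv[~np.isfinite(inv)] = 0.0
            terms.append(inv.mean())
        assert global_metrics(g)["Eloc"] == pytest.approx(
            np.mean(terms), abs=1e-10
        )

    def test_synchronization_is_laplacian_eigenratio(self, rng):
        g = proportional_threshold(random_pli_matrix(rng, 8), 0.5)
        W = g.weight_matrix()
        lap = np.diag(W.sum(1)) - W
        eig = np.sort(np.linalg.eigvalsh(lap))
        assert global_metrics(g)["Synchronization"] == pytest.approx(
            eig[1] / eig[-1], abs=1e-10
        )

    def test_assortativity_sign_on_constructed_graphs(self):
        # two stars joined by their centers: high-degree nodes attach to
        # low-degree leaves -> disassortative
        W = np.zeros((8, 8))
        for leaf in (2, 3, 4):
            W[0, leaf] = W[leaf, 0] = 1.0
        for leaf in (5, 6, 7):
            W[1, leaf] = W[leaf, 1] = 1.0
        W[0, 1] = W[1, 0] = 1.0
        m = global_metrics(graph_from_weights(W))
        assert m["Assortativity"] < 0

    def test_scale_property(self, rng):
        mat = random_pli_matrix(rng, 10)
        g1 = proportional_threshold(mat, 0.3)
        c = 2.5
        g2 = ThresholdedGraph(g1.n_nodes, g1.edges, c * g1.weights, g1.sparsity)
        m1, m2 = global_metrics(g1), global_metrics(g2)
        assert np.allclose(strength_degree(g2), c * strength_degree(g1))
        assert m2["Lp"] == pytest.approx(m1["Lp"] / c, rel=1e-12)
        assert m2["Eg"] == pytest.approx(m1["Eg"] * c, rel=1e-12)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError, match="2 nodes"):
            global_metrics(ThresholdedGraph(1, np.zeros((0, 2)), np.zeros(0), 0.5))


class TestRandomEnsemble:
    def test_members_preserve_degree_sequence_and_edge_count(self, rng):
        g = proportional_threshold(random_pli_matrix(rng, 12), 0.3)
        gen = np.random.default_rng(7)
        for _ in range(20):
            member = maslov_sneppen_rewire(g, gen)
            assert member.n_edges == g.n_edges
            assert np.array_equal(member.binary_degrees(), g.binary_degrees())
            assert sorted(member.weights) == sorted(g.weights)
            # no duplicates or self-loops
            pairs = {tuple(sorted(e)) for e in member.edges}
            assert len(pairs) == member.n_edges

    def test_rewiring_destroys_lattice_triangles(self, rng):
        g = ring_lattice(20, 2)
        src_triangles = triangle_count_oracle(g.edges, 20)
        gen = np.random.default_rng(3)
        counts = [
            triangle_count_oracle(maslov_sneppen_rewire(g, gen).edges, 20)
            for _ in range(10)
        ]
        assert np.mean(counts) < src_triangles

    def test_unswappable_graph_warns_and_copies(self):
        # two edges sharing structure with no valid swap: a triangle has
        # no degree-preserving double-edge swap
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[0, 2] = W[2, 0] = W[1, 2] = W[2, 1] = 1.0
        g = graph_from_weights(W)
        with pytest.warns(UserWarning, match="no valid"):
            ens = random_ensemble(g, n_random=5, seed=1)
        assert ens.degenerate

    def test_too_few_edges_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="2 edges"):
            random_ensemble(graph_from_weights(W), n_random=2, seed=0)


class TestSmallWorldSigma:
    def test_identical_ensemble_gives_one(self, rng):
        g = proportional_threshold(random_pli_matrix(rng, 10), 0.4)
        m = global_metrics(g)
        ens = RandomEnsemble(n_random=1, mean_cp_rand=m["Cp"],
                             mean_lp_rand=m["Lp"], source_edges=g.n_edges)
        assert small_world_sigma(g, ens) == pytest.approx(1.0)

    def test_rewired_ring_lattice_is_small_world(self):
        # Watts-Strogatz construction: a ring lattice with a small
        # fraction of shortcut edges keeps high clustering but gains
        # short paths, so sigma against the rewired null exceeds 1
        gen = np.random.default_rng(11)
        W = ring_lattice(30, 3).weight_matrix()
        for _ in range(5):  # ~5% shortcuts
            i, j = np.nonzero(np.triu(W, 1))
            pick = gen.integers(len(i))
            a, b = i[pick], j[pick]
            c = gen.integers(30)
            if c not in (a, b) and W[a, c] == 0:
                W[a, b] = W[b, a] = 0.0
                W[a, c] = W[c, a] = 1.0
        ws = graph_from_weights(W)
        ens = random_ensemble(ws, n_random=20, seed=5)
        assert small_world_sigma(ws, ens) > 1.0

    def test_random_graph_sigma_near_one(self, rng):
        g = proportional_threshold(random_pli_matrix(rng, 16), 0.3)
        ens = random_ensemble(g, n_random=20, seed=9)
        assert small_world_sigma(g, ens) == pytest.approx(1.0, abs=0.25)


class TestMetricCurveAuc:
    def test_constant_curve(self):
        grid = np.asarray(DEFAULT_SPARSITY_GRID)
        c = 3.7
        assert MetricCurve("m", grid, np.full(10, c)).auc == pytest.approx(
            0.45 * c
        )

    def test_identity_curve(self):
        grid = np.asarray(DEFAULT_SPARSITY_GRID)
        assert MetricCurve("m", grid, grid).auc == pytest.approx(0.12375)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            MetricCurve("m", [0.1, 0.1], [1.0, 2.0])


class TestSparsitySweep:
    def test_eg_monotone_in_sparsity(self, rng):
        mat = random_pli_matrix(rng, 16)
        prof = sparsity_sweep(mat, n_random=0, include_sigma=False)
        eg = prof.curves["Eg"].values
        assert np.all(np.diff(eg) >= -1e-12)

    def test_binary_degree_auc_constant_across_subjects(self, rng):
        # binary degree depends only on (N, sparsity), hence identical
        # AUC for every subject -- the reason the sweep tracks strength
        grid = np.asarray(DEFAULT_SPARSITY_GRID)
        aucs = []
        for sid in ("A", "B"):
            mat = random_pli_matrix(rng, 16, subject_id=sid)
            curve = [
                proportional_threshold(mat, s).binary_degrees().mean()
                for s in grid
            ]
            aucs.append(np.trapezoid(curve, grid))
        assert aucs[0] == pytest.approx(aucs[1], rel=1e-12)

    def test_degree_only_profile_matches_full_sweep_degrees(self, rng):
        mat = random_pli_matrix(rng, 12)
        fast = sparsity_sweep(mat, include_global=False)
        full = sparsity_sweep(mat, n_random=2, include_sigma=False)
        assert np.allclose(fast.degree_auc, full.degree_auc)
        assert set(fast.auc) == {"Degree"}
        assert "Lp" in full.auc and "Eg" in full.auc

    def test_derived_seeds_reproducible(self, rng):
        mat = random_pli_matrix(rng, 10)
        p1 = sparsity_sweep(mat, grid=(0.2, 0.4), n_random=5, seed=42)
        p2 = sparsity_sweep(mat, grid=(0.2, 0.4), n_random=5, seed=42)
        assert p1.auc["Sigma"] == p2.auc["Sigma"]
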