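"""Heterogeneity weighting, transitions, and the anti-shrinking diffusion."""

import numpy as np
import pytest
import scipy.sparse as sp

from celldiffuse.core_io import CellTable, RunConfig, ValidationError
from celldiffuse.diffusion import (
    DiffusionModel,
    HeterogeneityConfig,
    build_diffusion_model,
    build_transitions,
    diffuse,
    edge_weights,
    initialize_from_spots,
    latency,
    node_weights,
    sample_counts,
    spot_heterogeneity,
)
from celldiffuse.core_io import CellExpression
from celldiffuse.graph import CellGraph, FeatureSpace, build_feature_space, build_knn, knn_to_snn
from celldiffuse.histology import filter_cells_by_spots


def _graph_from_edges(n, edges, k=2):
    """Symmetric SNN graph with explicit weights."""
    rows, cols, vals = [], [], []
    for i, j, w in edges:
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return CellGraph(k=k, knn=np.zeros((n, k), dtype=int), snn_weights=W)


def _fs_morph(feats):
    feats = np.asarray(feats, dtype=float)
    n = feats.shape[0]
    return FeatureSpace(
        gen_block=np.zeros((n, 0)),
        geo_block=np.zeros((n, 0)),
        mor_block=feats,
    )


class TestSpotHeterogeneity:
    def test_single_label_spot_has_zero_entropy(self):
        cells = CellTable(
            cell_ids=np.array(["a", "b"]),
            centroids=np.zeros((2, 2)),
            spot_assignment=np.array([0, 0]),
        )
        hcfg = HeterogeneityConfig("entropy", labels=np.array(["x", "x"]))
        S = spot_heterogeneity(cells, _fs_morph(np.zeros((2, 1))), hcfg)
        assert S[0] == 0.0

    def test_even_two_label_spot_has_ln2_entropy(self):
        cells = CellTable(
            cell_ids=np.array(list("abcd")),
            centroids=np.zeros((4, 2)),
            spot_assignment=np.array([0, 0, 0, 0]),
        )
        hcfg = HeterogeneityConfig("entropy", labels=np.array(["x", "x", "y", "y"]))
        S = spot_heterogeneity(cells, _fs_morph(np.zeros((4, 1))), hcfg)
        assert S[0] == pytest.approx(np.log(2.0))

    def test_cv_mode_matches_hand_arithmetic(self):
        # spot 0 holds three cells with tabulated features; spot 1 one cell
        feats = np.array([[0.0, 2.0], [1.0, 4.0], [2.0, 6.0], [4.0, 0.0]])
        cells = CellTable(
            cell_ids=np.array(list("abcd")),
            centroids=np.zeros((4, 2)),
            spot_assignment=np.array([0, 0, 0, 1]),
        )
        S = spot_heterogeneity(cells, _fs_morph(feats), HeterogeneityConfig("cv"))
        # oracle: min-max rescale each column over all 4 cells, then mean CV
        lo, hi = feats.min(axis=0), feats.max(axis=0)
        X = (feats - lo) / (hi - lo)
        rows = X[:3]
        cv = rows.std(axis=0) / rows.mean(axis=0)
        assert S[0] == pytest.approx(cv.mean())
        assert S[1] == 0.0  # singleton spot

    def test_entropy_mode_requires_labels(self):
        with pytest.raises(ValidationError):
            HeterogeneityConfig("entropy")


class TestNodeWeightsAndLatency:
    def test_zero_heterogeneity_gives_unit_weight(self):
        assert node_weights(np.array([0.0]), kappa=1.0)[0] == 1.0

    def test_closed_form_at_ln2(self):
        assert node_weights(np.array([np.log(2.0)]), kappa=1.0)[0] == pytest.approx(0.5)

    def test_strictly_decreasing_in_heterogeneity(self):
        S = np.linspace(0, 3, 50)
        G = node_weights(S, kappa=2.0)
        assert np.all(np.diff(G) < 0)

    def test_latency_half_for_equal_weights(self):
        assert latency(0.7, 0.7, alpha=5.0) == pytest.approx(0.5)

    def test_latency_flat_at_zero_alpha(self):
        assert latency(1.0, 0.1, alpha=0.0) == pytest.approx(0.5)

    def test_latency_closed_form_steep(self):
        assert latency(1.0, 0.0, alpha=10.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-10.0)), abs=1e-9
        )

    def test_latency_favours_flow_from_homogeneous(self):
        assert latency(0.9, 0.3, alpha=5.0) > 0.5 > latency(0.3, 0.9, alpha=5.0)


class TestEdgeWeights:
    def test_three_cell_chain_matches_hand_computation(self):
        G = np.array([1.0, 0.8, 0.6])
        alpha = 2.0
        g = _graph_from_edges(3, [(0, 1, 0.4), (1, 2, 0.6)])
        eps = edge_weights(g, G, alpha).toarray()

        def lat(src, dst):
            return 1.0 / (1.0 + np.exp(-alpha * (G[src] - G[dst])))

        raw = np.array(
            [
                [G[0], lat(1, 0) * 0.4, 0.0],
                [lat(0, 1) * 0.4, G[1], lat(2, 1) * 0.6],
                [0.0, lat(1, 2) * 0.6, G[2]],
            ]
        )
        raw /= raw.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(eps, raw, atol=1e-12)

    def test_isolated_cell_row_is_pure_self_loop(self):
        g = _graph_from_edges(3, [(0, 1, 0.5)])
        eps = edge_weights(g, np.array([1.0, 1.0, 0.9]), alpha=5.0).toarray()
        np.testing.assert_allclose(eps[2], [0.0, 0.0, 1.0])

    def test_equal_node_weights_make_latencies_half(self):
        g = _graph_from_edges(2, [(0, 1, 0.8)])
        eps = edge_weights(g, np.array([0.7, 0.7]), alpha=5.0).toarray()
        # pre-normalisation off-diagonal is 0.5 * w
        assert eps[0, 1] / eps[0, 0] == pytest.approx(0.5 * 0.8 / 0.7)

    def test_rows_sum_to_one(self, rng):
        n = 15
        edges = [(i, (i + 1) % n, rng.uniform(0.2, 1.0)) for i in range(n)]
        eps = edge_weights(_graph_from_edges(n, edges), rng.uniform(0.3, 1.0, n), 3.0)
        np.testing.assert_allclose(np.asarray(eps.sum(axis=1)).ravel(), 1.0, atol=1e-12)


class TestBuildTransitions:
    def _eps(self, rng, n=8):
        edges = [(i, (i + 1) % n, rng.uniform(0.2, 1.0)) for i in range(n)]
        return edge_weights(_graph_from_edges(n, edges), rng.uniform(0.3, 1.0, n), 3.0)

    def test_rows_of_f_r_t_sum_to_one(self, rng):
        for n in (10, 100, 500):
            rng2 = np.random.default_rng(n)
            edges = [(i, (i + 1) % n, rng2.uniform(0.2, 1.0)) for i in range(n)]
            eps = edge_weights(
                _graph_from_edges(n, edges), rng2.uniform(0.3, 1.0, n), 3.0
            )
            F, R, T = build_transitions(eps, 0.8, -0.82)
            for M in (F, R, T):
                np.testing.assert_allclose(
                    np.asarray(M.sum(axis=1)).ravel(), 1.0, atol=1e-9
                )

    def test_mu_zero_limit_reduces_to_forward(self, rng):
        eps = self._eps(rng)
        F, R, T = build_transitions(eps, 0.8, 0.0)
        np.testing.assert_allclose(R.toarray(), np.eye(8), atol=1e-12)
        np.testing.assert_allclose(T.toarray(), F.toarray(), atol=1e-12)

    def test_three_cell_product_matches_dense_oracle(self):
        G = np.array([1.0, 0.7, 0.9])
        g = _graph_from_edges(3, [(0, 1, 0.5), (1, 2, 0.4)])
        eps = edge_weights(g, G, alpha=5.0)
        F, R, T = build_transitions(eps, 0.8, -0.82)
        e = eps.toarray()
        I = np.eye(3)
        Fo = 0.2 * I + 0.8 * e
        Ro = 1.82 * I - 0.82 * e
        To = Ro @ Fo
        To /= To.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(T.toarray(), To, atol=1e-12)

    def test_inflation_produces_negative_entries(self, rng):
        eps = self._eps(rng)
        _, R, _ = build_transitions(eps, 0.8, -0.82)
        assert R.toarray().min() < 0

    def test_unnormalised_eps_rejected(self):
        bad = sp.identity(3, format="csr") * 2.0
        with pytest.raises(ValidationError):
            build_transitions(bad, 0.8, -0.82)


class TestDiffuse:
    def _model(self, rng, n=12):
        edges = [(i, (i + 1) % n, rng.uniform(0.2, 1.0)) for i in range(n)] + [
            (i, (i + 2) % n, 0.3) for i in range(0, n, 2)
        ]
        G = rng.uniform(0.4, 1.0, n)
        eps = edge_weights(_graph_from_edges(n, edges), G, 4.0)
        F, R, T = build_transitions(eps, 0.8, -0.82)
        return DiffusionModel(
            G=G, S=np.zeros(n), eps=eps, F=F, R=R, T=T,
            smoothing_scale=0.8, inflation_scale=-0.82, alpha=4.0, kappa=1.0, n_iters=20,
        )

    def test_zero_steps_leave_input_unchanged(self, rng):
        model = self._model(rng)
        x0 = rng.uniform(0, 10, size=(12, 3))
        np.testing.assert_array_equal(diffuse(model.T, x0, 0), x0)

    def test_identity_transition_is_fixed_point(self, rng):
        x0 = rng.uniform(0, 10, size=(5, 2))
        out = diffuse(sp.identity(5, format="csr"), x0, 7, rescale="none")
        np.testing.assert_allclose(out, x0, atol=1e-12)

    def test_matches_dense_matrix_power_oracle(self, rng):
        model = self._model(rng, n=4)
        x0 = rng.uniform(0, 10, size=(4, 5))
        out = diffuse(model.T, x0, 3, rescale="none")
        oracle = np.linalg.matrix_power(model.T.toarray(), 3) @ x0
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_factored_form_equals_effective_transition(self, rng):
        model = self._model(rng)
        x0 = rng.uniform(0, 10, size=(12, 4))
        a = diffuse(model, x0, 5, rescale="none")
        b = diffuse(model.T, x0, 5, rescale="none")
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_negative_step_count_rejected(self, rng):
        with pytest.raises(ValidationError):
            diffuse(self._model(rng).T, np.zeros((12, 1)), -1)

    def test_rescale_maps_onto_reference_range(self, rng):
        model = self._model(rng)
        x0 = rng.uniform(0, 10, size=(12, 3))
        out = diffuse(model, x0, 10, rescale="minmax")
        assert np.all(out.min(axis=0) >= x0.min(axis=0) - 1e-9)
        assert np.all(out.max(axis=0) <= x0.max(axis=0) + 1e-9)

    def test_antishrinking_retains_more_variance_than_forward_only(self, rng):
        model = self._model(rng)
        x0 = rng.uniform(0, 10, size=(12, 6))
        n = 10
        x_taubin = diffuse(model, x0, n, rescale="none")
        xf = x0.copy()
        for _ in range(n):
            xf = model.F @ xf
        assert np.median(x_taubin.var(axis=0)) > np.median(xf.var(axis=0))

    def test_forward_only_variance_nonincreasing(self, rng):
        model = self._model(rng)
        x = rng.uniform(0, 10, size=(12, 6))
        prev = x.var(axis=0)
        for _ in range(8):
            x = model.F @ x
            cur = x.var(axis=0)
            assert np.all(cur <= prev + 1e-9)
            prev = cur

    def test_relative_change_nonincreasing_after_burn_in(self, rng):
        model = self._model(rng)
        x = rng.uniform(0, 10, size=(12, 4))
        deltas = []
        for _ in range(15):
            x_next = model.R @ (model.F @ x)
            deltas.append(
                np.linalg.norm(x_next - x) / max(np.linalg.norm(x), 1e-30)
            )
            x = x_next
        tail = deltas[3:]
        assert all(b <= a * (1 + 1e-6) for a, b in zip(tail, tail[1:]))


class TestAsymmetricFlow:
    def test_transition_toward_heterogeneous_cell_dominates(self):
        G = np.array([1.0, 0.5])  # cell 0 homogeneous, cell 1 heterogeneous
        g = _graph_from_edges(2, [(0, 1, 0.6)])
        eps = edge_weights(g, G, alpha=5.0)
        _, _, T = build_transitions(eps, 0.8, -0.82)
        Td = T.toarray()
        assert Td[1, 0] > Td[0, 1]


class TestHomogeneousLimit:
    def test_one_cell_per_spot_self_loop_graph_is_identity(self, rng):
        n = 6
        g = _graph_from_edges(n, [])  # no edges at all
        G = np.ones(n)  # every spot trivially homogeneous
        eps = edge_weights(g, G, alpha=5.0)
        F, R, T = build_transitions(eps, 0.8, -0.82)
        x0 = rng.uniform(0, 10, size=(n, 3))
        np.testing.assert_array_equal(diffuse(T, x0, 20, rescale="none"), x0)


class TestInitialization:
    def test_lognorm_space_copies_normalised_spot_rows(self, tiny_spots):
        from celldiffuse.graph import log_normalize

        cells = CellTable(
            cell_ids=np.array(["a", "b"]),
            centroids=np.array([[0.0, 0.0], [10.0, 0.0]]),
            spot_assignment=np.array([0, 1]),
        )
        x0 = initialize_from_spots(cells, tiny_spots, space="lognorm")
        expect = log_normalize(tiny_spots.dense())
        np.testing.assert_allclose(x0, expect[[0, 1]])

    def test_counts_space_per_cell_divides_by_enclosed_count(self, tiny_spots):
        tiny_spots.cells_per_spot = np.array([2, 1, 1, 1])
        cells = CellTable(
            cell_ids=np.array(["a", "b"]),
            centroids=np.array([[0.0, 0.0], [10.0, 0.0]]),
            spot_assignment=np.array([0, 1]),
        )
        x0 = initialize_from_spots(cells, tiny_spots, space="counts", scale="per_cell")
        np.testing.assert_allclose(x0[0], tiny_spots.dense()[0] / 2.0)
        np.testing.assert_allclose(x0[1], tiny_spots.dense()[1])


class TestSampleCounts:
    def _ce(self, mat):
        return CellExpression(
            cell_ids=np.array([f"c{i}" for i in range(mat.shape[0])]),
            matrix=mat,
            gene_ids=np.array([f"g{j}" for j in range(mat.shape[1])]),
        )

    def test_zero_mean_always_zero(self):
        out = sample_counts(self._ce(np.zeros((4, 3))), seed=0)
        assert out.dense().sum() == 0

    def test_seed_reproducible(self):
        ce = self._ce(np.full((5, 5), 3.0))
        a = sample_counts(ce, seed=42).dense()
        b = sample_counts(ce, seed=42).dense()
        np.testing.assert_array_equal(a, b)

    def test_poisson_moments(self):
        ce = self._ce(np.full((10_000, 1), 100.0))
        draws = sample_counts(ce, seed=3).dense()
        assert abs(draws.mean() - 100.0) < 3 * 10.0 / np.sqrt(10_000)

    def test_negative_means_rejected(self):
        with pytest.raises(ValidationError):
            sample_counts(self._ce(np.array([[-1.0]])), seed=0)


class TestEndToEndModel:
    def test_benchmark_model_row_stochastic(self, small_truth, small_spots):
        cells = filter_cells_by_spots(small_truth.to_cell_table(), small_spots)
        cfg = RunConfig(w_gen=0.0)
        fs = build_feature_space(cells, small_spots, cfg)
        graph = knn_to_snn(build_knn(fs, cfg.n_neighbors), cfg.snn_threshold)
        model = build_diffusion_model(
            cells, fs, graph, cfg, n_spots=small_spots.n_spots
        )
        for M in (model.F, model.R, model.T):
            np.testing.assert_allclose(
                np.asarray(M.sum(axis=1)).ravel(), 1.0, atol=1e-9
            )
        assert model.G.min() > 0 and model.G.max() <= 1.0
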