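"""Network blocks against straight-line reference recomputations, plus
model-level invariances (determinism, rigid motion, ablation switches)."""

import numpy as np
import pytest

from curvagn.dataset import featurize_complex
from curvagn.nn.autodiff import Tensor
from curvagn.nn.model import (
    ModelConfig,
    N_INTERACTION_CELLS,
    curvature_block,
    edge2edge,
    edge2node,
    forward,
    init_state,
    loss,
    node2edge,
    output_pool,
    pipool,
)
from curvagn.synthetic import random_rotation, rigid_transform

from conftest import random_complex


@pytest.fixture(scope="module")
def toy():
    """A small featurized complex plus a matching tiny model state."""
    cplx = random_complex(seed=41, n_ligand=4, n_protein=6)
    sample = featurize_complex(cplx)
    config = ModelConfig(
        n_paga_layers=2,
        n_heads=2,
        node_emb_dim=8,
        edge_emb_dim=6,
        curvature_emb_dim=5,
        mlp_hidden=(8, 4),
    )
    state = init_state(config, np.random.default_rng(99))
    return cplx, sample, config, state


def _fresh_state(config, seed=99):
    return init_state(config, np.random.default_rng(seed))


class TestCurvatureBlock:
    def test_profile_softmax_positive_and_normalized(self, toy):
        _, sample, config, state = toy
        # straight-line recompute of the profile branch
        raw = sample.curvature_profiles @ state["W_f"].data.T
        lrelu = np.where(raw > 0, raw, 0.01 * raw)
        e = np.exp(lrelu - lrelu.max(axis=1, keepdims=True))
        f = e / e.sum(axis=1, keepdims=True)
        assert (f > 0).all()
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_straight_line_recompute(self, toy):
        _, sample, config, state = toy
        crt = curvature_block(
            sample.curvature_profiles, sample.edge_distance, sample.cutoff_d,
            config, state,
        )
        raw = sample.curvature_profiles @ state["W_f"].data.T
        lrelu = np.where(raw > 0, raw, 0.01 * raw)
        e = np.exp(lrelu - lrelu.max(axis=1, keepdims=True))
        f = e / e.sum(axis=1, keepdims=True)
        onehot = np.zeros((sample.n_edges, config.distance_onehot_dim))
        onehot[np.arange(sample.n_edges), np.floor(sample.edge_distance).astype(int)] = 1
        d_emb = onehot @ state["W_d"].data.T
        crt_ref = np.maximum(np.hstack([d_emb, f]) @ state["W_fd"].data.T, 0.0)
        np.testing.assert_allclose(crt.data, crt_ref, atol=1e-10)

    def test_distance_one_hot_uses_integer_part(self, toy):
        _, sample, config, state = toy
        # distance 3.7 must land in bin 3 of {0..5}
        profiles = sample.curvature_profiles[:1]
        cfg = config
        w_d = state["W_d"].data
        out_37 = curvature_block(profiles, np.array([3.7]), 5.0, cfg, state)
        out_31 = curvature_block(profiles, np.array([3.1]), 5.0, cfg, state)
        out_41 = curvature_block(profiles, np.array([4.1]), 5.0, cfg, state)
        np.testing.assert_array_equal(out_37.data, out_31.data)  # same bin
        assert not np.array_equal(out_37.data, out_41.data)

    def test_distance_outside_range_rejected(self, toy):
        _, sample, config, state = toy
        with pytest.raises(ValueError, match="one-hot"):
            curvature_block(
                sample.curvature_profiles[:1], np.array([5.5]), 5.0, config, state
            )


class TestNode2Edge:
    def test_zero_weight_matrix_gives_zero_edges(self, toy):
        _, sample, config, _ = toy
        state = _fresh_state(config)
        state["W_ab_0"].data[:] = 0.0
        crt = curvature_block(
            sample.curvature_profiles, sample.edge_distance, sample.cutoff_d,
            config, state,
        )
        h_e = node2edge(Tensor(sample.node_features), crt, sample, config, state, 0)
        assert not h_e.data.any()

    def test_directedness_concatenation_order_matters(self, toy):
        _, sample, config, state = toy
        crt = curvature_block(
            sample.curvature_profiles, sample.edge_distance, sample.cutoff_d,
            config, state,
        )
        h_e = node2edge(Tensor(sample.node_features), crt, sample, config, state, 0)
        idx = {tuple(map(int, e)): k for k, e in enumerate(sample.edges)}
        diffs = 0
        for (i, j), k in idx.items():
            if not np.array_equal(h_e.data[k], h_e.data[idx[(j, i)]]):
                diffs += 1
        assert diffs > 0

    def test_matches_per_edge_recompute(self, toy):
        _, sample, config, state = toy
        crt = curvature_block(
            sample.curvature_profiles, sample.edge_distance, sample.cutoff_d,
            config, state,
        )
        h_e = node2edge(Tensor(sample.node_features), crt, sample, config, state, 0)
        w = state["W_ab_0"].data
        for k, (i, j) in enumerate(sample.edges[:20]):
            x = np.concatenate(
                [sample.node_features[i], sample.node_features[j], crt.data[k]]
            )
            np.testing.assert_allclose(h_e.data[k], np.maximum(w @ x, 0.0), atol=1e-10)


def _ref_edge2edge(h_e, sample, config, state, layer):
    """Per-edge loop over arcs, directly following the aggregation rule."""
    n_dom, de = config.n_angle_domains, config.edge_emb_dim
    out = np.zeros((sample.n_edges, n_dom * h_e.shape[1]))
    for t in range(sample.n_edges):
        blocks = []
        for q in range(1, n_dom + 1):
            m = h_e[t].copy()
            for s, tt, qq in zip(sample.arc_src, sample.arc_tgt, sample.arc_domain):
                if tt != t or qq != q:
                    continue
                w = state[f"W_eq_{layer}_{q}"].data
                b = state[f"b_eq_{layer}_{q}"].data
                alpha = np.tanh(w @ np.concatenate([h_e[t], h_e[s]]) + b)
                m = m + alpha * h_e[s]
            blocks.append(m)
        out[t] = np.concatenate(blocks)
    return out


class TestEdge2Edge:
    def test_zero_attention_returns_repeated_residual(self, toy):
        _, sample, config, _ = toy
        state = _fresh_state(config)
        for q in range(1, config.n_angle_domains + 1):
            state[f"W_eq_0_{q}"].data[:] = 0.0
            state[f"b_eq_0_{q}"].data[:] = 0.0
        h_e = Tensor(np.random.default_rng(1).normal(size=(sample.n_edges, 6)))
        out = edge2edge(h_e, sample, config, state, 0)
        np.testing.assert_array_equal(
            out.data, np.tile(h_e.data, (1, config.n_angle_domains))
        )

    def test_edge_without_incoming_arcs_keeps_residual(self, toy):
        _, sample, config, state = toy
        h_e = Tensor(np.random.default_rng(2).normal(size=(sample.n_edges, 6)))
        out = edge2edge(h_e, sample, config, state, 0)
        with_arcs = set(sample.arc_tgt.tolist())
        lonely = [t for t in range(sample.n_edges) if t not in with_arcs]
        for t in lonely:
            np.testing.assert_array_equal(
                out.data[t], np.tile(h_e.data[t], config.n_angle_domains)
            )

    def test_matches_arc_loop_recompute(self, toy):
        _, sample, config, state = toy
        h_e = Tensor(np.random.default_rng(3).normal(size=(sample.n_edges, 6)))
        out = edge2edge(h_e, sample, config, state, 1)
        ref = _ref_edge2edge(h_e.data, sample, config, state, 1)
        np.testing.assert_allclose(out.data, ref, atol=1e-10)

    def test_scalar_adaptive_collapses_attention_to_scalar(self, toy):
        _, sample, _, _ = toy
        config = ModelConfig(
            n_paga_layers=1, n_heads=1, node_emb_dim=8, edge_emb_dim=6,
            curvature_emb_dim=5, mlp_hidden=(8, 4), variant="scalar-adaptive",
        )
        state = _fresh_state(config)
        assert state["W_eq_0_1"].data.shape == (1, 12)
        h_e = Tensor(np.random.default_rng(4).normal(size=(sample.n_edges, 6)))
        out = edge2edge(h_e, sample, config, state, 0)
        assert np.isfinite(out.data).all()

    def test_vanilla_gat_attention_normalizes_over_neighbors(self, toy):
        _, sample, _, _ = toy
        config = ModelConfig(
            n_paga_layers=1, n_heads=1, node_emb_dim=8, edge_emb_dim=6,
            curvature_emb_dim=5, mlp_hidden=(8, 4), variant="vanilla-gat",
        )
        state = _fresh_state(config)
        for q in range(1, 7):
            state[f"W_eq_0_{q}"].data[:] = 0.0  # uniform scores
        h_e = Tensor(np.ones((sample.n_edges, 6)))
        out = edge2edge(h_e, sample, config, state, 0)
        # with all-one inputs and uniform softmax weights, each non-empty
        # (edge, domain) block is residual + mean of neighbours = 2
        q0 = sample.arc_domain - 1
        key = sample.arc_tgt * 6 + q0
        for t in range(min(sample.n_edges, 40)):
            for q in range(6):
                block = out.data[t, q * 6 : (q + 1) * 6]
                expected = 2.0 if (key == t * 6 + q).any() else 1.0
                np.testing.assert_allclose(block, expected, atol=1e-10)


class TestEdge2Node:
    def test_zero_attention_vector_gives_head_averaged_projection(self, toy):
        _, sample, config, _ = toy
        state = _fresh_state(config)
        for h in range(config.n_heads):
            state[f"v_0_{h}"].data[:] = 0.0
        h_nodes = Tensor(sample.node_features)
        crt = curvature_block(
            sample.curvature_profiles, sample.edge_distance, sample.cutoff_d,
            config, state,
        )
        h_e = node2edge(h_nodes, crt, sample, config, state, 0)
        h_ee = edge2edge(h_e, sample, config, state, 0)
        out = edge2node(h_ee, h_nodes, crt, sample, config, state, 0)
        expected = np.mean(
            [
                sample.node_features @ state[f"W_a_0_{h}"].data.T
                for h in range(config.n_heads)
            ],
            axis=0,
        )
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_identical_heads_equal_single_head(self, toy):
        _, sample, _, _ = toy
        cfg2 = ModelConfig(n_paga_layers=1, n_heads=2, node_emb_dim=8,
                           edge_emb_dim=6, curvature_emb_dim=5, mlp_hidden=(8, 4))
        cfg1 = ModelConfig(n_paga_layers=1, n_heads=1, node_emb_dim=8,
                           edge_emb_dim=6, curvature_emb_dim=5, mlp_hidden=(8, 4))
        s2, s1 = _fresh_state(cfg2), _fresh_state(cfg1)
        for key in ["W_e_0_0", "W_a_0_0", "W_dr_0_0", "v_0_0"]:
            s1[key].data[:] = s2[key].data
            s2[key.replace("_0_0", "_0_1")].data[:] = s2[key].data
        h_nodes = Tensor(sample.node_features)
        crt2 = curvature_block(sample.curvature_profiles, sample.edge_distance,
                               sample.cutoff_d, cfg2, s2)
        h_e = node2edge(h_nodes, crt2, sample, cfg2, s2, 0)
        h_ee = edge2edge(h_e, sample, cfg2, s2, 0)
        out2 = edge2node(h_ee, h_nodes, crt2, sample, cfg2, s2, 0)
        crt1 = curvature_block(sample.curvature_profiles, sample.edge_distance,
                               sample.cutoff_d, cfg1, s1)
        out1 = edge2node(h_ee, h_nodes, crt1, sample, cfg1, s1, 0)
        np.testing.assert_allclose(out2.data, out1.data, atol=1e-12)

    def test_matches_per_node_recompute(self, toy):
        _, sample, config, state = toy
        h_nodes = Tensor(sample.node_features)
        crt = curvature_block(sample.curvature_profiles, sample.edge_distance,
                              sample.cutoff_d, config, state)
        h_e = node2edge(h_nodes, crt, sample, config, state, 0)
        h_ee = edge2edge(h_e, sample, config, state, 0)
        out = edge2node(h_ee, h_nodes, crt, sample, config, state, 0)

        n, c = sample.n_nodes, config.n_heads
        ref = np.zeros((n, config.node_emb_dim))
        for h in range(c):
            he = h_ee.data @ state[f"W_e_0_{h}"].data.T
            ha = sample.node_features @ state[f"W_a_0_{h}"].data.T
            crt_p = crt.data @ state[f"W_dr_0_{h}"].data.T
            contrib = ha.copy()
            for k, (i, j) in enumerate(sample.edges):
                beta = np.tanh(
                    state[f"v_0_{h}"].data
                    @ np.concatenate([he[k], ha[j], crt_p[k]])
                )
                contrib[j] += beta * he[k]
            ref += contrib
        np.testing.assert_allclose(out.data, ref / c, atol=1e-9)


class TestPooling:
    def test_pipool_uniform_when_pooled_representations_vanish(self, toy):
        _, sample, config, _ = toy
        state = _fresh_state(config)
        state["W_h"].data[:] = 0.0
        h_e = Tensor(np.random.default_rng(5).normal(
            size=(sample.n_edges, config.edge2edge_out_dim)))
        z = pipool(h_e, sample, state)
        np.testing.assert_allclose(z.data, 1.0 / N_INTERACTION_CELLS, atol=1e-12)
        assert z.data.shape == (4, 9)

    def test_pipool_is_probability_table(self, toy):
        _, sample, config, state = toy
        h_e = Tensor(np.random.default_rng(6).normal(
            size=(sample.n_edges, config.edge2edge_out_dim)))
        z = pipool(h_e, sample, state)
        assert (z.data > 0).all()
        assert z.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_pipool_pools_only_protein_to_ligand_edges_by_type(self, toy):
        _, sample, config, state = toy
        h_e = Tensor(np.random.default_rng(7).normal(
            size=(sample.n_edges, config.edge2edge_out_dim)))
        cells_ref = np.zeros((N_INTERACTION_CELLS, config.edge_emb_dim))
        for e, cell in zip(sample.pipool_edge_idx, sample.pipool_cell):
            cells_ref[cell] += state["W_h"].data @ h_e.data[e]
        scores = cells_ref @ state["q_vec"].data
        expd = np.exp(scores - scores.max())
        np.testing.assert_allclose(
            pipool(h_e, sample, state).data.ravel(), expd / expd.sum(), atol=1e-10
        )

    def test_output_pool_invariant_to_node_order(self, toy):
        _, sample, config, state = toy
        h = np.random.default_rng(8).normal(size=(sample.n_nodes, config.node_emb_dim))
        y1 = output_pool(Tensor(h), state)
        y2 = output_pool(Tensor(h[::-1].copy()), state)
        # sum-pooling is permutation symmetric; float addition order still
        # shifts the last bits, so compare at machine precision
        assert float(y1.data) == pytest.approx(float(y2.data), rel=1e-12)

    def test_output_pool_zero_inputs_zero_bias_gives_zero(self, toy):
        _, sample, config, _ = toy
        state = _fresh_state(config)
        y = output_pool(Tensor(np.zeros((5, config.node_emb_dim))), state)
        assert float(y.data) == 0.0

    def test_output_pool_matches_manual_mlp(self, toy):
        _, sample, config, state = toy
        h = np.random.default_rng(9).normal(size=(4, config.node_emb_dim))
        g = h.sum(axis=0)
        g = np.maximum(state["mlp_W0"].data @ g + state["mlp_b0"].data, 0)
        g = np.maximum(state["mlp_W1"].data @ g + state["mlp_b1"].data, 0)
        ref = state["mlp_W2"].data @ g + state["mlp_b2"].data
        assert float(output_pool(Tensor(h), state).data) == pytest.approx(
            float(ref[0]), abs=1e-10
        )


class TestLoss:
    def test_exact_fit_gives_zero(self):
        z = np.full((4, 9), 1 / 36)
        assert float(loss(Tensor(5.0), 5.0, Tensor(z), z, 1.75).data) == 0.0

    def test_lambda_zero_reduces_to_absolute_error(self):
        z = np.zeros((4, 9))
        zt = np.random.default_rng(0).random((4, 9))
        got = float(loss(Tensor(3.0), 5.5, Tensor(zt), z, 0.0).data)
        assert got == pytest.approx(2.5, abs=1e-12)

    def test_hand_computed_two_item_batch(self):
        z1 = np.zeros((2, 2)); z1[0, 0] = 1.0
        zt1 = np.full((2, 2), 0.25)
        z2 = np.eye(2) / 2
        zt2 = np.array([[0.5, 0.0], [0.25, 0.25]])
        lam = 2.0
        l1 = loss(Tensor(1.0), 3.0, Tensor(zt1), z1, lam)
        l2 = loss(Tensor(4.0), 3.5, Tensor(zt2), z2, lam)
        total = float((l1 + l2).data)
        # item 1: |1-3| + 2 * sqrt(0.75^2 + 3 * 0.25^2) = 2 + 2*sqrt(0.75)
        # item 2: 0.5 + 2 * sqrt(0 + 0 + 0.25^2 + 0.25^2)
        expected = (2 + 2 * np.sqrt(0.75)) + (0.5 + 2 * np.sqrt(0.125))
        assert total == pytest.approx(expected, abs=1e-12)

    def test_l1_norm_option(self):
        z = np.zeros((1, 2))
        zt = np.array([[0.3, -0.2]])
        got = float(loss(Tensor(0.0), 0.0, Tensor(zt), z, 1.0, norm="l1").data)
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(Tensor(0.0), 0.0, Tensor(np.zeros((2, 2))), np.zeros((4, 9)), 1.0)


class TestForward:
    def test_evaluation_mode_is_deterministic(self, toy):
        _, sample, config, state = toy
        y1, z1 = forward(sample, config, state)
        y2, z2 = forward(sample, config, state)
        assert float(y1.data) == float(y2.data)
        np.testing.assert_array_equal(z1.data, z2.data)

    def test_rigid_motion_invariance_of_outputs(self, toy, rng):
        cplx, sample, config, state = toy
        y0, z0 = forward(sample, config, state)
        moved = rigid_transform(cplx, random_rotation(rng), rng.normal(size=3) * 8)
        sample_m = featurize_complex(moved)
        y1, z1 = forward(sample_m, config, state)
        assert float(y1.data) == pytest.approx(float(y0.data), rel=1e-5)
        np.testing.assert_allclose(z1.data, z0.data, rtol=1e-5)

    def test_no_curvature_variant_ignores_profiles(self, toy):
        cplx, sample, _, _ = toy
        config = ModelConfig(
            n_paga_layers=2, n_heads=2, node_emb_dim=8, edge_emb_dim=6,
            curvature_emb_dim=5, mlp_hidden=(8, 4), variant="no-curvature",
        )
        state = _fresh_state(config)
        y0, z0 = forward(sample, config, state)
        perturbed = featurize_complex(cplx)
        perturbed.curvature_profiles = perturbed.curvature_profiles + 3.0
        y1, z1 = forward(perturbed, config, state)
        assert float(y0.data) == float(y1.data)
        np.testing.assert_array_equal(z0.data, z1.data)

    def test_full_variant_depends_on_profiles(self, toy):
        cplx, sample, config, state = toy
        y0, _ = forward(sample, config, state)
        perturbed = featurize_complex(cplx)
        perturbed.curvature_profiles = perturbed.curvature_profiles + 3.0
        y1, _ = forward(perturbed, config, state)
        assert float(y0.data) != float(y1.data)

    def test_outputs_finite_and_z_normalized(self, toy):
        _, sample, config, state = toy
        y, z = forward(sample, config, state)
        assert np.isfinite(y.data).all()
        assert z.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_angle_domain_mismatch_rejected(self, toy):
        _, sample, _, _ = toy
        config = ModelConfig(n_paga_layers=1, n_heads=1, n_angle_domains=4,
                             node_emb_dim=8, edge_emb_dim=6, curvature_emb_dim=5,
                             mlp_hidden=(8, 4))
        state = _fresh_state(config)
        with pytest.raises(ValueError, match="angle domains"):
            forward(sample, config, state)
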