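"""Dual-graph network: convolution contracts, invariances, bridge, I/O."""

import numpy as np
import pytest

from chirsep.chem_graphs import Condition, build_dual_graph
from chirsep.errors import ContractError
from chirsep.qgeognn_model import (
    BOND_ONEHOT_DIM,
    GraphBatch,
    ModelConfig,
    QGeoGNN,
    _onehot_atoms,
    gin_conv,
)
from tests.conftest import ALANINE_R, ALANINE_S, _permute_dual_atoms


class TestGinConv:
    def test_isolated_node_identity(self):
        x = np.array([[1.0, 2.0, 3.0]])
        out = gin_conv(x, np.empty((2, 0)), eps=0.0)
        np.testing.assert_array_equal(out, x)

    def test_two_connected_nodes_sum(self):
        x = np.array([[1.0, 0.0], [0.0, 2.0]])
        edges = np.array([[0, 1], [1, 0]])
        out = gin_conv(x, edges, eps=0.0)
        expected = np.array([[1.0, 2.0], [1.0, 2.0]])  # a+b for both
        np.testing.assert_array_equal(out, expected)

    def test_epsilon_scales_self_term(self):
        x = np.array([[3.0, -1.0]])
        out = gin_conv(x, np.empty((2, 0)), eps=1.0)
        np.testing.assert_array_equal(out, 2 * x)

    def test_edge_features_enter_messages(self):
        x = np.zeros((2, 2))
        edges = np.array([[0, 1], [1, 0]])
        e = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gin_conv(x, edges, e)
        np.testing.assert_array_equal(out, np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            gin_conv(np.zeros((2, 2)), np.array([[0, 5], [5, 0]]))
        with pytest.raises(ContractError):
            gin_conv(np.zeros((2, 2)), np.array([[0, 1], [1, 0]]), np.zeros((3, 2)))


def _plain_gin_reference(model: QGeoGNN, batch: GraphBatch) -> np.ndarray:
    """Independent single-graph GIN on G, sharing the model's weights.

    Dense per-node loops; used as the equivalence oracle for the
    bridge-disabled network.
    """
    p = {k: t.data for k, t in model.params.items()}
    cfg = model.config
    nm = model.norm
    g_cont = (batch.g_edge_cont - nm.g_edge_mean) / nm.g_edge_std
    edge_in = np.hstack([batch.g_edge_cat, g_cont])
    x = batch.atom_onehot @ p["node_emb_g.W"] + p["node_emb_g.b"]
    for k in range(cfg.num_layers):
        e = edge_in @ p[f"edge_g.{k}.W"] + p[f"edge_g.{k}.b"]
        new = np.zeros_like(x)
        for i in range(batch.n_atoms):
            agg = np.zeros(cfg.embed_dim)
            for m in range(batch.g_src.size):
                if batch.g_dst[m] == i:
                    agg += x[batch.g_src[m]] + e[m]
            new[i] = (1 + cfg.eps) * x[i] + agg
        h = np.maximum(new @ p[f"mlp_g.{k}.0.W"] + p[f"mlp_g.{k}.0.b"], 0.0)
        x = h @ p[f"mlp_g.{k}.1.W"] + p[f"mlp_g.{k}.1.b"]
    reprs = np.zeros((batch.n_graphs, cfg.embed_dim))
    for i in range(batch.n_atoms):
        reprs[batch.atom_graph_ids[i]] += x[i]
    return reprs @ p["head.W"] + p["head.b"]


class TestPropagation:
    def test_output_has_three_finite_components(self, small_model):
        dual = build_dual_graph(ALANINE_S, Condition(0.05, 1.0), seed=0)
        pred = small_model.forward(dual)
        assert np.all(np.isfinite([pred.q10, pred.pred, pred.q90]))

    def test_inference_deterministic(self, small_model):
        dual = build_dual_graph(ALANINE_S, Condition(0.05, 1.0), seed=0)
        a, b = small_model.forward(dual), small_model.forward(dual)
        assert (a.q10, a.pred, a.q90) == (b.q10, b.pred, b.q90)

    def test_permutation_invariant_readout(self, small_model):
        """Renumbering the atoms of one conformer leaves the output unchanged."""
        cond = Condition(0.05, 1.0)
        rng = np.random.default_rng(0)
        for smi in ("CCO", "CC(C)CO", ALANINE_S):
            base = build_dual_graph(smi, cond, seed=0)
            out0 = small_model.forward(base)
            for _ in range(5):
                perm = list(map(int, rng.permutation(base.g.num_atoms)))
                out = small_model.forward(_permute_dual_atoms(smi, cond, perm))
                np.testing.assert_allclose(
                    [out.q10, out.pred, out.q90],
                    [out0.q10, out0.pred, out0.q90],
                    rtol=1e-5,
                )

    def test_bridge_disabled_matches_plain_gin_oracle(self):
        cfg = ModelConfig(num_layers=2, embed_dim=8, use_bridge=False)
        model = QGeoGNN(cfg, seed=5)
        duals = [
            build_dual_graph(s, Condition(0.05, 1.0), seed=0)
            for s in ["CCO", ALANINE_S, "C[C@H](O)c1ccccc1"]
        ]
        batch = GraphBatch(duals, cfg)
        ours = model.forward_batch(batch).data
        ref = _plain_gin_reference(model, batch)
        np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-9)

    def test_enantiomer_pair_outputs_differ(self, small_model, alanine_pair_duals):
        a, b = (small_model.forward(d) for d in alanine_pair_duals)
        assert abs(a.pred - b.pred) > 1e-8  # chiral tags reach the head

    def test_chiral_tag_gradient_reaches_output(self, small_model, small_model_config):
        """The chiral-tag feature block has nonzero influence on the output."""
        dual = build_dual_graph(ALANINE_S, Condition(0.05, 1.0), seed=0)
        batch = GraphBatch([dual], small_model_config)
        for p in small_model.params.values():
            p.grad = None
        out = small_model.forward_batch(batch)
        out.sum().backward()
        tag_block = slice(13, 17)  # chiral-tag one-hot columns of the atom features
        w = small_model.params["node_emb_g.W"]
        assert w.grad is not None
        assert np.abs(w.grad[tag_block, :]).max() > 0
        for p in small_model.params.values():
            p.grad = None


class TestBatchContracts:
    def test_mixed_layout_rejected(self, registry):
        cfg = ModelConfig(num_layers=1, embed_dim=8, multi_column=True)
        plain = build_dual_graph("CCO", Condition(0.05, 1.0), seed=0)
        with pytest.raises(ContractError):
            GraphBatch([plain], cfg)

    def test_empty_batch_rejected(self, small_model_config):
        with pytest.raises(ContractError):
            GraphBatch([], small_model_config)


def test_save_load_roundtrip(tmp_path, small_model, small_model_config):
    dual = build_dual_graph(ALANINE_S, Condition(0.05, 1.0), seed=0)
    before = small_model.forward(dual)
    path = tmp_path / "model.npz"
    small_model.save(str(path))
    loaded = QGeoGNN.load(str(path))
    after = loaded.forward(dual)
    assert (before.q10, before.pred, before.q90) == (after.q10, after.pred, after.q90)
    assert loaded.config == small_model_config


def test_onehot_covers_all_code_columns():
    codes = np.array([[0, 1, 2, 3, 4, 5, 6, 1, 2]])
    oh = _onehot_atoms(codes)
    assert oh.sum() == 9  # exactly one hot entry per feature column
    assert BOND_ONEHOT_DIM == 14
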