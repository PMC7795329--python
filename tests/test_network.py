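"""The self-attention enhanced spatial graph convolutional network.

The two spatial aggregation branches are checked against independent
loop-based oracles on small fixtures, plus structural invariants
(attention normalization, permutation equivariance, gate semantics) and
the block/model contracts.
"""

import numpy as np
import pytest

from skelemo import (ModelConfig, SkeletonGraph, SSTGCN, load_checkpoint,
                     save_checkpoint, spatial_partition)
from skelemo.autograd import Parameter, Tensor
from skelemo.network import (FULL_CHANNEL_PLAN, MultiHeadSpatialAttention,
                             SSGCBlock, SpatialGraphConv, attention_residual,
                             gated_combine)
from skelemo.nn import DTYPE


def chain_graph(v=3):
    return SkeletonGraph(num_joints=v,
                         edges=tuple((i, i + 1) for i in range(v - 1)),
                         center_joint=0)


# ----------------------------------------------------------------------
# independent loop-based oracles
# ----------------------------------------------------------------------

def graph_conv_oracle(f_in, adjacency, weight, bias, masks):
    """Dense triple-loop evaluation of the graph-convolutional branch.

    f_in: (C_in, T, V); weight: (C_in, K*C_out); masks: (K, V, V).
    """
    c_in, t, v = f_in.shape
    k = adjacency.shape[0]
    c_out = weight.shape[1] // k
    out = np.zeros((c_out, t, v))
    for ki in range(k):
        b = adjacency[ki] * masks[ki]
        for ti in range(t):
            for c in range(c_out):
                # 1x1 conv output channel (ki, c) at frame ti
                f_k = np.zeros(v)
                for vi in range(v):
                    f_k[vi] = (f_in[:, ti, vi] @ weight[:, ki * c_out + c]
                               + bias[ki * c_out + c])
                for w in range(v):
                    out[c, ti, w] += sum(f_k[vi] * b[vi, w] for vi in range(v))
    return out


def attention_oracle(f_in, wq, wk, wv, wo):
    """Explicit-loop scaled dot-product attention per frame.

    f_in: (C_in, T, V); wq/wk/wv: (H, C_in, d); wo: (H*d_v, C_out).
    """
    c_in, t, v = f_in.shape
    h, _, d_k = wq.shape
    d_v = wv.shape[2]
    c_out = wo.shape[1]
    out = np.zeros((c_out, t, v))
    for ti in range(t):
        a = f_in[:, ti, :].T  # (V, C_in)
        heads = []
        for hi in range(h):
            q, k, val = a @ wq[hi], a @ wk[hi], a @ wv[hi]
            s = np.zeros((v, d_v))
            for i in range(v):
                e = np.array([q[i] @ k[j] / np.sqrt(d_k) for j in range(v)])
                alpha = np.exp(e - e.max())
                alpha /= alpha.sum()
                for j in range(v):
                    s[i] += alpha[j] * val[j]
            heads.append(s)
        concat = np.concatenate(heads, axis=1)  # (V, H*d_v)
        out[:, ti, :] = (concat @ wo).T
    return out


# ----------------------------------------------------------------------
# graph-convolutional branch
# ----------------------------------------------------------------------

class TestSpatialGraphConv:
    def test_matches_loop_oracle(self, rng):
        graph = chain_graph(3)
        adj = spatial_partition(graph)
        layer = SpatialGraphConv(2, 2, adj, np.random.default_rng(3))
        layer.masks.data = rng.normal(size=layer.masks.shape).astype(DTYPE)
        f_in = rng.normal(size=(2, 1, 3)).astype(DTYPE)
        got = layer(Tensor(f_in[None])).data[0]
        want = graph_conv_oracle(f_in.astype(float), adj.subsets,
                                 layer.weight.data.astype(float),
                                 layer.bias.data.astype(float),
                                 layer.masks.data.astype(float))
        np.testing.assert_allclose(got, want, rtol=1e-5)

    def test_zero_adjacency_gives_zero_output(self, rng):
        from skelemo.graph import PartitionedAdjacency
        adj = PartitionedAdjacency(subsets=np.zeros((3, 4, 4)), normalized=False)
        layer = SpatialGraphConv(3, 5, adj, np.random.default_rng(0))
        out = layer(Tensor(rng.normal(size=(2, 3, 6, 4)).astype(DTYPE)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_all_ones_mask_is_identity_mask(self, rng):
        graph = chain_graph(4)
        adj = spatial_partition(graph)
        layer = SpatialGraphConv(2, 3, adj, np.random.default_rng(5))
        assert (layer.masks.data == 1).all()  # initialized to ones
        f_in = rng.normal(size=(1, 2, 2, 4)).astype(DTYPE)
        masked = layer(Tensor(f_in)).data
        # un-masked reference: fold A_k directly, no element-wise weights
        want = graph_conv_oracle(f_in[0].astype(float), adj.subsets,
                                 layer.weight.data.astype(float),
                                 layer.bias.data.astype(float),
                                 np.ones_like(adj.subsets))
        np.testing.assert_allclose(masked[0], want, rtol=1e-5)

    def test_shape_mismatch_names_dimension(self, rng):
        adj = spatial_partition(chain_graph(3))
        layer = SpatialGraphConv(2, 2, adj, np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            layer(Tensor(rng.normal(size=(1, 5, 2, 3)).astype(DTYPE)))
        with pytest.raises(ValueError, match="joints"):
            layer(Tensor(rng.normal(size=(1, 2, 2, 7)).astype(DTYPE)))


# ----------------------------------------------------------------------
# self-attention branch
# ----------------------------------------------------------------------

class TestMultiHeadSpatialAttention:
    def make(self, c_in=2, c_out=3, h=1, d=2, seed=11):
        return MultiHeadSpatialAttention(c_in, c_out, h, d, d,
                                         np.random.default_rng(seed))

    def test_matches_loop_oracle(self, rng):
        att = self.make()
        f_in = rng.normal(size=(2, 3, 3)).astype(DTYPE)  # (C, T, V)
        got = att(Tensor(f_in[None])).data[0]
        want = attention_oracle(f_in.astype(float),
                                att.w_query.data.astype(float),
                                att.w_key.data.astype(float),
                                att.w_value.data.astype(float),
                                att.w_out.data.astype(float))
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)

    def test_multihead_matches_oracle(self, rng):
        att = self.make(c_in=3, c_out=4, h=2, d=2, seed=21)
        f_in = rng.normal(size=(3, 2, 4)).astype(DTYPE)
        got = att(Tensor(f_in[None])).data[0]
        want = attention_oracle(f_in.astype(float),
                                att.w_query.data.astype(float),
                                att.w_key.data.astype(float),
                                att.w_value.data.astype(float),
                                att.w_out.data.astype(float))
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        att = self.make(c_in=3, c_out=4, h=2, d=2)
        x = Tensor(rng.normal(size=(2, 3, 4, 5)).astype(DTYPE))
        alpha = att.attention_weights(x)
        np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, rtol=1e-5)

    def test_identical_joints_give_uniform_attention(self):
        att = self.make(c_in=2, c_out=2, h=2, d=2)
        v = 5
        x = np.tile(np.array([0.3, -1.2], dtype=DTYPE)[None, :, None, None],
                    (1, 1, 3, v))
        alpha = att.attention_weights(Tensor(x))
        np.testing.assert_allclose(alpha, 1.0 / v, rtol=1e-5)

    def test_frame_independence(self, rng):
        """Perturbing frame t only changes the output at frame t."""
        att = self.make(c_in=2, c_out=2, h=1, d=2)
        x = rng.normal(size=(1, 2, 4, 3)).astype(DTYPE)
        base = att(Tensor(x)).data
        x2 = x.copy()
        x2[0, :, 2, :] += 1.0
        out2 = att(Tensor(x2)).data
        assert not np.allclose(out2[0, :, 2, :], base[0, :, 2, :])
        np.testing.assert_array_equal(np.delete(out2, 2, axis=2),
                                      np.delete(base, 2, axis=2))

    def test_joint_permutation_equivariance(self, rng):
        att = self.make(c_in=3, c_out=2, h=2, d=2)
        x = rng.normal(size=(2, 3, 2, 6)).astype(DTYPE)
        perm = np.random.default_rng(0).permutation(6)
        out_then_perm = att(Tensor(x)).data[..., perm]
        perm_then_out = att(Tensor(x[..., perm])).data
        np.testing.assert_allclose(perm_then_out, out_then_perm, rtol=1e-5,
                                   atol=1e-6)


class TestResidualAndGate:
    def test_identity_branch_when_channels_match(self, rng):
        f_in = Tensor(rng.normal(size=(1, 3, 2, 4)).astype(DTYPE))
        f_o = Tensor(np.zeros((1, 3, 2, 4), dtype=DTYPE))
        out = attention_residual(f_o, f_in, None)
        np.testing.assert_array_equal(out.data, f_in.data)

    def test_zero_input_keeps_attention_output(self, rng):
        f_o = Tensor(rng.normal(size=(1, 3, 2, 4)).astype(DTYPE))
        f_in = Tensor(np.zeros((1, 2, 2, 4), dtype=DTYPE))
        w_r = Parameter(rng.normal(size=(2, 3)).astype(DTYPE))
        out = attention_residual(f_o, f_in, w_r)
        np.testing.assert_array_equal(out.data, f_o.data)

    def test_projection_matches_matrix_product(self, rng):
        f_o = rng.normal(size=(1, 3, 2, 4)).astype(DTYPE)
        f_in = rng.normal(size=(1, 2, 2, 4)).astype(DTYPE)
        w_r = rng.normal(size=(2, 3)).astype(DTYPE)
        out = attention_residual(Tensor(f_o), Tensor(f_in), Parameter(w_r)).data
        want = f_o.copy().astype(float)
        for t in range(2):
            for v in range(4):
                want[0, :, t, v] += f_in[0, :, t, v].astype(float) @ w_r.astype(float)
        np.testing.assert_allclose(out, want, rtol=1e-5)

    def test_gate_semantics(self, rng):
        f_g = Tensor(rng.normal(size=(2, 3, 4)).astype(DTYPE))
        f_a = Tensor(rng.normal(size=(2, 3, 4)).astype(DTYPE))
        one = Tensor(np.ones((), dtype=DTYPE))
        zero = Tensor(np.zeros((), dtype=DTYPE))
        np.testing.assert_allclose(gated_combine(f_g, f_a, one).data,
                                   (f_g.data + f_a.data) / 2, rtol=1e-6)
        np.testing.assert_allclose(gated_combine(f_g, f_a, zero).data,
                                   f_g.data / 2, rtol=1e-6)
        np.testing.assert_allclose(gated_combine(f_g, f_g, one).data,
                                   f_g.data, rtol=1e-6)

    def test_gate_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shapes differ"):
            gated_combine(Tensor(np.zeros((2, 3))), Tensor(np.zeros((3, 2))),
                          Tensor(np.ones(())))


# ----------------------------------------------------------------------
# temporal convolution
# ----------------------------------------------------------------------

class TestTemporalConv:
    def test_unit_kernel_is_identity(self, rng):
        x = Tensor(rng.normal(size=(2, 3, 5, 4)).astype(DTYPE))
        w = Parameter(np.eye(3, dtype=DTYPE).reshape(3, 3, 1))
        b = Parameter(np.zeros(3, dtype=DTYPE))
        np.testing.assert_allclose(x.temporal_conv(w, b).data, x.data, rtol=1e-6)

    def test_stride_halves_time(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 128, 3)).astype(DTYPE))
        w = Parameter(np.zeros((2, 2, 9), dtype=DTYPE))
        b = Parameter(np.zeros(2, dtype=DTYPE))
        assert x.temporal_conv(w, b, stride=2).shape == (1, 2, 64, 3)
        # odd T: ceil division
        x2 = Tensor(rng.normal(size=(1, 2, 7, 3)).astype(DTYPE))
        assert x2.temporal_conv(w, b, stride=2).shape == (1, 2, 4, 3)

    def test_moving_average_on_ramp(self):
        """K_t=3 averaging kernel vs a hand-computed sliding mean."""
        t = 8
        x = np.zeros((1, 1, t, 1), dtype=DTYPE)
        x[0, 0, :, 0] = np.arange(t)
        w = Parameter(np.full((1, 1, 3), 1 / 3, dtype=DTYPE))
        b = Parameter(np.zeros(1, dtype=DTYPE))
        got = Tensor(x).temporal_conv(w, b).data[0, 0, :, 0]
        padded = np.concatenate([[0.0], np.arange(t), [0.0]])
        want = np.array([padded[i:i + 3].mean() for i in range(t)])
        np.testing.assert_allclose(got, want, rtol=1e-5)


# ----------------------------------------------------------------------
# block and full model
# ----------------------------------------------------------------------

class TestBlockAndModel:
    def test_block_output_shape_contract(self, upper_adj, rng):
        cfg = ModelConfig.tiny()
        for stride in (1, 2):
            block = SSGCBlock(3, 8, upper_adj, cfg, stride,
                              np.random.default_rng(0))
            block.eval()
            out = block(Tensor(rng.normal(size=(2, 3, 9, 10)).astype(DTYPE)))
            assert out.shape == (2, 8, -(-9 // stride), 10)

    def test_eval_mode_deterministic(self, upper_adj, rng):
        cfg = ModelConfig.tiny()
        block = SSGCBlock(3, 8, upper_adj, cfg, 1, np.random.default_rng(0))
        block.eval()
        x = Tensor(rng.normal(size=(2, 3, 6, 10)).astype(DTYPE))
        a, b = block(x).data, block(x).data
        np.testing.assert_array_equal(a, b)

    def test_default_channel_plan(self):
        assert ModelConfig().channels == (32, 32, 32, 32, 64, 64, 64,
                                          128, 128, 128)
        assert len(ModelConfig().channels) == 10

    def test_model_outputs_probabilities(self, upper_adj, rng):
        model = SSTGCN(ModelConfig.tiny(), upper_adj, rng=0)
        x = rng.normal(size=(3, 3, 8, 10)).astype(DTYPE)
        model.train()
        model(x)  # populate batch-norm running statistics
        model.eval()
        p = model(x).data
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-5)
        assert (p > 0).all() and (p < 1).all()

    def test_batch_permutation_equivariance(self, upper_adj, rng):
        model = SSTGCN(ModelConfig.tiny(), upper_adj, rng=0).eval()
        x = rng.normal(size=(5, 3, 8, 10)).astype(DTYPE)
        perm = np.array([3, 0, 4, 1, 2])
        base = model.logits(x).data
        # batch norm uses stored running stats in eval mode, so rows are
        # processed independently
        np.testing.assert_allclose(model.logits(x[perm]).data, base[perm],
                                   rtol=2e-4, atol=1e-5)

    def test_gate_zero_ignores_attention_parameters(self, upper_adj, rng):
        model = SSTGCN(ModelConfig.tiny(), upper_adj, rng=0).eval()
        x = rng.normal(size=(2, 3, 8, 10)).astype(DTYPE)
        for block in model.blocks:
            block.ssgc.gate.data = np.zeros((), dtype=DTYPE)
        base = model.logits(x).data
        scramble = np.random.default_rng(99)
        for block in model.blocks:
            att = block.ssgc.attention
            for p in (att.w_query, att.w_key, att.w_value, att.w_out):
                p.data = scramble.normal(size=p.shape).astype(DTYPE)
        np.testing.assert_array_equal(model.logits(x).data, base)

    def test_ungated_model_equals_gate_frozen_at_one(self, upper_adj, rng):
        cfg = ModelConfig.tiny()
        gated = SSTGCN(cfg, upper_adj, rng=0).eval()
        from dataclasses import replace
        ungated = SSTGCN(replace(cfg, gated=False), upper_adj, rng=0).eval()
        # same init seed, and r starts at 1, so forward passes agree
        x = rng.normal(size=(2, 3, 8, 10)).astype(DTYPE)
        np.testing.assert_allclose(ungated.logits(x).data, gated.logits(x).data,
                                   rtol=1e-5)
        # the frozen gate is not trainable
        n_gates = len(cfg.channels)
        assert (gated.num_parameters() - ungated.num_parameters()) == n_gates

    def test_parameter_count_closed_form(self, upper_adj):
        cfg = ModelConfig.benchmark()
        model = SSTGCN(cfg, upper_adj, rng=0)
        v, k, h = cfg.num_joints, 3, cfg.num_heads
        c_prev = cfg.in_channels
        total = 2 * c_prev * v  # input batch norm
        for c_out, stride in zip(cfg.channels, cfg.strides):
            d_k, d_v = cfg.head_dims(c_out)
            total += c_prev * k * c_out + k * c_out      # graph conv W + bias
            total += k * v * v                           # masks M_k
            total += h * c_prev * (2 * d_k + d_v)        # W_Q, W_K, W_V
            total += h * d_v * c_out                     # W_O
            if c_prev != c_out:
                total += c_prev * c_out                  # W_R
            total += 1                                   # gate r
            total += c_out * c_out * cfg.temporal_kernel + c_out  # T-conv
            total += 4 * c_out                           # two batch norms
            if not (c_prev == c_out and stride == 1):
                total += c_out * c_prev + c_out + 2 * c_out  # residual conv+BN
            c_prev = c_out
        total += c_prev * cfg.num_classes + cfg.num_classes  # output layer
        assert model.num_parameters() == total

    def test_wrong_input_shape_rejected(self, upper_adj, rng):
        model = SSTGCN(ModelConfig.tiny(), upper_adj, rng=0).eval()
        with pytest.raises(ValueError, match="joints"):
            model.logits(rng.normal(size=(1, 3, 8, 7)).astype(DTYPE))
        with pytest.raises(ValueError, match="channels"):
            model.logits(rng.normal(size=(1, 2, 8, 10)).astype(DTYPE))

    def test_checkpoint_roundtrip(self, upper_adj, rng, tmp_path):
        model = SSTGCN(ModelConfig.tiny(), upper_adj, rng=0).eval()
        x = rng.normal(size=(2, 3, 8, 10)).astype(DTYPE)
        path = tmp_path / "model.npz"
        save_checkpoint(path, model, upper_adj)
        loaded, adj = load_checkpoint(path)
        np.testing.assert_array_equal(loaded.logits(x).data,
                                      model.logits(x).data)
        np.testing.assert_array_equal(adj.subsets, upper_adj.subsets)
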