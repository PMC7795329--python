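"""Self-attention enhanced spatial-temporal graph convolutional network.

The classifier alternates two spatial aggregation mechanisms with
temporal convolutions on a fixed skeleton graph:

* **Graph-convolutional branch** — a 1×1 convolution maps the input to
  K·C_out channels, the result is split into K chunks f_k, and

      f_g = Σ_k f_k (A_k ⊗ M_k)

  where A_k are the spatial-configuration adjacency subsets (root /
  centripetal / centrifugal) and M_k are trainable element-wise masks
  initialized to one, so the static skeleton topology can be re-weighted
  but not rewired.

* **Self-attention branch** — multi-head scaled dot-product attention
  over the V joints, applied to every frame independently with shared
  weights: e_ij = (a_i W_Q)(a_j W_K)ᵀ/√d_k, α = softmax_j(e),
  s_i = Σ_j α_ij (a_j W_V); heads are concatenated, projected by W_O,
  and a residual (projected by W_R when channel counts differ) is added.
  This branch builds data-dependent connections between any pair of
  joints, supplementing the fixed graph.

* **Gating** — the two branches are averaged with a per-layer trainable
  scalar r on the attention branch, f_out = (f_g + r·f_a)/2, r
  initialized to 1.  Disabling gating freezes r at 1.

A basic block is this spatial layer followed by batch norm, ReLU, a
(K_t, 1) temporal convolution, batch norm, dropout, a block-level
residual connection, and ReLU.  The full model stacks 10 blocks with
output channels 32,32,32,32,64,64,64,128,128,128, global-average-pools
over time and joints, and classifies with a linear output layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Parameter, Tensor
from .graph import PartitionedAdjacency
from .nn import DTYPE, BatchNorm, Dropout, Linear, Module, kaiming

__all__ = [
    "ModelConfig",
    "SpatialGraphConv",
    "MultiHeadSpatialAttention",
    "SSGCLayer",
    "SSGCBlock",
    "SSTGCN",
    "attention_residual",
    "gated_combine",
    "temporal_conv",
    "save_checkpoint",
    "load_checkpoint",
]

FULL_CHANNEL_PLAN = (32, 32, 32, 32, 64, 64, 64, 128, 128, 128)
FULL_STRIDES = (1, 1, 1, 1, 2, 1, 1, 2, 1, 1)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the skeleton classifier.

    ``channels``/``strides`` define one basic block per entry; the
    default is the 10-block plan with temporal stride 2 at the two
    channel-doubling blocks.  ``num_heads`` attention heads use
    ``d_k = d_v = C_out / H`` unless overridden.
    """

    channels: tuple[int, ...] = FULL_CHANNEL_PLAN
    strides: tuple[int, ...] = FULL_STRIDES
    temporal_kernel: int = 9
    num_heads: int = 4
    d_k: int | None = None
    d_v: int | None = None
    num_classes: int = 4
    in_channels: int = 3
    num_joints: int = 10
    dropout: float = 0.5
    gated: bool = True

    def __post_init__(self):
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if self.temporal_kernel % 2 != 1:
            raise ValueError("temporal_kernel must be odd")
        if any(s not in (1, 2) for s in self.strides):
            raise ValueError("temporal strides must be 1 or 2")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")

    def head_dims(self, out_channels: int) -> tuple[int, int]:
        d_k = self.d_k or max(1, out_channels // self.num_heads)
        d_v = self.d_v or max(1, out_channels // self.num_heads)
        return d_k, d_v

    @classmethod
    def benchmark(cls, num_classes: int = 4) -> "ModelConfig":
        """Reduced 4-block stack used for CPU-scale experiments."""
        return cls(channels=(16, 16, 32, 32), strides=(1, 1, 2, 1),
                   temporal_kernel=5, num_heads=2, dropout=0.1,
                   num_classes=num_classes)

    @classmethod
    def tiny(cls, num_classes: int = 4, num_joints: int = 10) -> "ModelConfig":
        """2-block stack for quick smoke experiments and property tests."""
        return cls(channels=(8, 16), strides=(1, 2), temporal_kernel=3,
                   num_heads=2, dropout=0.0, num_classes=num_classes,
                   num_joints=num_joints)


class SpatialGraphConv(Module):
    """Graph-convolutional branch: f_g = Σ_k f_k (A_k ⊗ M_k)."""

    def __init__(self, in_channels: int, out_channels: int,
                 adj: PartitionedAdjacency, rng: np.random.Generator):
        k, v = adj.num_subsets, adj.num_joints
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.num_subsets = k
        self.adjacency = adj.subsets.astype(DTYPE)
        # W: 1x1 conv C_in -> K*C_out, applied per frame and joint
        self.weight = Parameter(kaiming(rng, (in_channels, k * out_channels),
                                        in_channels))
        self.bias = Parameter(np.zeros(k * out_channels, dtype=DTYPE))
        # M_k: element-wise masks on A_k, initialized to all ones
        self.masks = Parameter(np.ones((k, v, v), dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t, v = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        if v != self.adjacency.shape[1]:
            raise ValueError(f"expected V={self.adjacency.shape[1]} joints, got {v}")
        k, c_out = self.num_subsets, self.out_channels
        f = x.transpose(0, 2, 3, 1) @ self.weight + self.bias  # (N,T,V,K*C_out)
        f = f.reshape(n, t, v, k, c_out)
        out = None
        for i in range(k):
            b_i = Tensor(self.adjacency[i]) * self.masks[i]        # A_k ⊗ M_k
            f_i = f[:, :, :, i, :].transpose(0, 1, 3, 2)           # (N,T,C_out,V)
            term = f_i @ b_i                                       # Σ_v f[v] B[v,w]
            out = term if out is None else out + term
        return out.transpose(0, 2, 1, 3)  # (N, C_out, T, V)


class MultiHeadSpatialAttention(Module):
    """Multi-head scaled dot-product attention over joints, per frame."""

    def __init__(self, in_channels: int, out_channels: int, num_heads: int,
                 d_k: int, d_v: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.num_heads = num_heads
        self.d_k, self.d_v = d_k, d_v
        h = num_heads
        self.w_query = Parameter(kaiming(rng, (h, in_channels, d_k), in_channels))
        self.w_key = Parameter(kaiming(rng, (h, in_channels, d_k), in_channels))
        self.w_value = Parameter(kaiming(rng, (h, in_channels, d_v), in_channels))
        self.w_out = Parameter(kaiming(rng, (h * d_v, out_channels), h * d_v))

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Attention coefficients α of shape (N, T, H, V, V) (diagnostic)."""
        return self._attend(x)[1].data

    def _project(self, a2: Tensor, w: Parameter, d: int,
                 n: int, t: int, v: int) -> Tensor:
        # one (NTV, C) x (C, H*d) GEMM instead of many per-head products
        w2 = w.transpose(1, 0, 2).reshape(self.in_channels, self.num_heads * d)
        return (a2 @ w2).reshape(n, t, v, self.num_heads, d).transpose(0, 1, 3, 2, 4)

    def _attend(self, x: Tensor) -> tuple[Tensor, Tensor]:
        n, c, t, v = x.shape
        a2 = x.transpose(0, 2, 3, 1).reshape(n * t * v, c)
        q = self._project(a2, self.w_query, self.d_k, n, t, v)   # (N,T,H,V,d_k)
        k = self._project(a2, self.w_key, self.d_k, n, t, v)
        val = self._project(a2, self.w_value, self.d_v, n, t, v)
        e = (q @ k.transpose(0, 1, 2, 4, 3)) * (1.0 / np.sqrt(self.d_k))
        alpha = e.softmax(axis=-1)                            # rows sum to 1
        s = alpha @ val                                       # (N,T,H,V,d_v)
        return s, alpha

    def __call__(self, x: Tensor) -> Tensor:
        n, c, t, v = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        s, _ = self._attend(x)
        concat = s.transpose(0, 1, 3, 2, 4).reshape(n, t, v, self.num_heads * self.d_v)
        f_o = concat @ self.w_out                             # (N,T,V,C_out)
        return f_o.transpose(0, 3, 1, 2)


def attention_residual(f_o: Tensor, f_in: Tensor,
                       w_residual: Parameter | None) -> Tensor:
    """Residual over the attention branch: f_a = f_o + f_in (projected).

    When input and output channel counts differ, ``w_residual``
    (C_in × C_out) projects the input first.
    """
    if f_in.shape[1] == f_o.shape[1]:
        return f_o + f_in
    if w_residual is None:
        raise ValueError("channel counts differ but no residual projection given")
    projected = (f_in.transpose(0, 2, 3, 1) @ w_residual).transpose(0, 3, 1, 2)
    return f_o + projected


def gated_combine(f_g: Tensor, f_a: Tensor, gate) -> Tensor:
    """f_out = (f_g + r · f_a) / 2; with gating disabled r is fixed at 1."""
    if f_g.shape != f_a.shape:
        raise ValueError(f"branch shapes differ: {f_g.shape} vs {f_a.shape}")
    return (f_g + gate * f_a) * 0.5


def temporal_conv(x: Tensor, weight: Parameter, bias: Parameter,
                  stride: int = 1) -> Tensor:
    """(K_t, 1) convolution along time for every joint; T' = ceil(T/stride)."""
    return x.temporal_conv(weight, bias, stride=stride)


class SSGCLayer(Module):
    """Self-attention enhanced spatial graph convolutional layer.

    Combines the graph-convolutional branch and the attention branch
    (with its own residual) through the trainable gate r.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 adj: PartitionedAdjacency, num_heads: int, d_k: int, d_v: int,
                 rng: np.random.Generator, gated: bool = True):
        self.graph_conv = SpatialGraphConv(in_channels, out_channels, adj, rng)
        self.attention = MultiHeadSpatialAttention(in_channels, out_channels,
                                                   num_heads, d_k, d_v, rng)
        self.w_residual = (
            Parameter(kaiming(rng, (in_channels, out_channels), in_channels))
            if in_channels != out_channels else None
        )
        self.gated = gated
        # r initialized to 1; a plain Tensor when gating is ablated (frozen)
        self.gate = Parameter(np.ones((), dtype=DTYPE)) if gated \
            else Tensor(np.ones((), dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        f_g = self.graph_conv(x)
        f_o = self.attention(x)
        f_a = attention_residual(f_o, x, self.w_residual)
        return gated_combine(f_g, f_a, self.gate)


class SSGCBlock(Module):
    """Basic block: S-SGC → BN → ReLU → T-Conv → BN → dropout (+residual) → ReLU."""

    def __init__(self, in_channels: int, out_channels: int,
                 adj: PartitionedAdjacency, cfg: ModelConfig, stride: int,
                 rng: np.random.Generator):
        d_k, d_v = cfg.head_dims(out_channels)
        kt = cfg.temporal_kernel
        self.stride = stride
        self.ssgc = SSGCLayer(in_channels, out_channels, adj, cfg.num_heads,
                              d_k, d_v, rng, gated=cfg.gated)
        self.bn1 = BatchNorm(out_channels)
        self.tconv_weight = Parameter(
            kaiming(rng, (out_channels, out_channels, kt), out_channels * kt))
        self.tconv_bias = Parameter(np.zeros(out_channels, dtype=DTYPE))
        self.bn2 = BatchNorm(out_channels)
        self.dropout = Dropout(cfg.dropout, rng)
        # block-level residual: identity, or strided 1x1 projection
        self.identity_residual = in_channels == out_channels and stride == 1
        if not self.identity_residual:
            self.res_weight = Parameter(
                kaiming(rng, (out_channels, in_channels, 1), in_channels))
            self.res_bias = Parameter(np.zeros(out_channels, dtype=DTYPE))
            self.res_bn = BatchNorm(out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        if self.identity_residual:
            res = x
        else:
            res = self.res_bn(x.temporal_conv(self.res_weight, self.res_bias,
                                              stride=self.stride))
        y = self.ssgc(x)
        y = self.bn1(y).relu()
        y = y.temporal_conv(self.tconv_weight, self.tconv_bias, stride=self.stride)
        y = self.dropout(self.bn2(y))
        return (y + res).relu()


class SSTGCN(Module):
    """The full skeleton classifier (stack of basic blocks + linear head)."""

    def __init__(self, cfg: ModelConfig, adj: PartitionedAdjacency,
                 rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        if adj.num_joints != cfg.num_joints:
            raise ValueError(
                f"config expects V={cfg.num_joints}, adjacency has {adj.num_joints}")
        self.cfg = cfg
        self.data_bn = BatchNorm(cfg.in_channels * cfg.num_joints, axes=(0, 2))
        self.blocks = []
        c_prev = cfg.in_channels
        for c_out, stride in zip(cfg.channels, cfg.strides):
            self.blocks.append(SSGCBlock(c_prev, c_out, adj, cfg, stride, rng))
            c_prev = c_out
        self.head = Linear(c_prev, cfg.num_classes, rng)

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, T, V) input, got shape {x.shape}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        if x.shape[3] != self.cfg.num_joints:
            raise ValueError(
                f"expected V={self.cfg.num_joints} joints, got {x.shape[3]}")

    def features(self, x: np.ndarray | Tensor) -> Tensor:
        """Pooled embedding (N, C_last) before the output layer."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=DTYPE))
        self._check_input(x.data)
        n, c, t, v = x.shape
        # normalize each (channel, joint) trajectory over the batch
        h = x.transpose(0, 1, 3, 2).reshape(n, c * v, t)
        h = self.data_bn(h)
        h = h.reshape(n, c, v, t).transpose(0, 1, 3, 2)
        for block in self.blocks:
            h = block(h)
        return h.mean(axis=(2, 3))  # global average pool over T and V

    def logits(self, x: np.ndarray | Tensor) -> Tensor:
        """Pre-softmax class scores; the training loss consumes these."""
        return self.head(self.features(x))

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        """Class probabilities (rows sum to 1)."""
        return self.logits(x).softmax(axis=-1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class indices (lowest index wins ties)."""
        return np.argmax(self.logits(x).data, axis=1)


# ----------------------------------------------------------------------
# checkpointing: a self-describing npz (config JSON + parameter arrays)
# ----------------------------------------------------------------------

def save_checkpoint(path, model: SSTGCN, adj: PartitionedAdjacency) -> None:
    meta = {"config": asdict(model.cfg), "normalized_adjacency": adj.normalized}
    arrays = model.state_arrays()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             __adjacency__=adj.subsets, **arrays)


def load_checkpoint(path) -> tuple[SSTGCN, PartitionedAdjacency]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        cfg_dict["strides"] = tuple(cfg_dict["strides"])
        cfg = ModelConfig(**cfg_dict)
        adj = PartitionedAdjacency(subsets=np.asarray(data["__adjacency__"]),
                                   normalized=bool(meta["normalized_adjacency"]))
        model = SSTGCN(cfg, adj, rng=0)
        state = {k: data[k] for k in data.files
                 if k not in ("__meta__", "__adjacency__")}
        model.load_state_arrays(state)
    model.eval()
    return model, adj
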