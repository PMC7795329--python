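"""Minimal reverse-mode automatic differentiation over numpy arrays.

The graph-convolutional network in this package is trained by gradient
descent, so every tensor operation it uses is implemented here as a node
in a dynamically built computation graph.  The design follows the usual
tape-based pattern: each :class:`Tensor` records the operation that
produced it and a closure that propagates the upstream gradient to its
parents; :meth:`Tensor.backward` runs the closures in reverse
topological order.

Only the operations the network actually needs are provided: broadcast
arithmetic, batched ``matmul``, shape manipulation, reductions, ``relu``
/ ``exp`` / ``log`` / ``sqrt``, softmax, basic slicing and a strided 1-D
convolution along the time axis.  Everything computes in the dtype of
its inputs (the network uses float32 throughout).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were prepended by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over dims that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-dimensional array tracking gradients through operations."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    # construction helpers
    # ------------------------------------------------------------------
    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep python scalars in our dtype so float32 graphs stay float32
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    # graph plumbing
    # ------------------------------------------------------------------
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        tracked = tuple(p for p in parents if p.requires_grad)
        if tracked:
            out.requires_grad = True
            out._prev = tracked
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (10 blocks)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = grad.astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    # ------------------------------------------------------------------
    # arithmetic
    # ------------------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # ------------------------------------------------------------------
    # shape ops
    # ------------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape
        dtype = self.data.dtype
        parts = idx if isinstance(idx, tuple) else (idx,)
        basic = all(isinstance(p, (slice, int, np.integer)) for p in parts)

        def backward(g):
            full = np.zeros(shape, dtype=dtype)
            if basic:  # slices/ints never alias, so a direct add is safe
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------------
    # reductions and elementwise nonlinearities
    # ------------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
            else:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
                self._accum(np.broadcast_to(g, shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along ``axis`` (max-shift is constant)."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - inner))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------------
    # temporal convolution (the one bespoke kernel the network needs)
    # ------------------------------------------------------------------
    def temporal_conv(self, weight: "Tensor", bias: "Tensor", stride: int = 1):
        """1-D convolution along axis 2 of an ``(N, C, T, V)`` tensor.

        ``weight`` has shape ``(C_out, C_in, K_t)`` and is applied to every
        node independently with symmetric zero padding ``(K_t - 1) // 2``,
        so ``T_out = ceil(T / stride)``.
        """
        x, w = self, weight
        n, c_in, t, v = x.shape
        c_out, c_in_w, kt = w.shape
        if c_in_w != c_in:
            raise ValueError(
                f"temporal_conv: weight expects {c_in_w} input channels, got {c_in}"
            )
        pad = (kt - 1) // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (0, 0)))
        t_out = -(-t // stride)  # ceil division
        # windows: (N, C_in, T_out, V, K_t)
        win = np.lib.stride_tricks.sliding_window_view(xp, kt, axis=2)
        win = win[:, :, ::stride][:, :, :t_out]
        # contract over (C_in, K_t) as one GEMM
        out_data = np.tensordot(win, w.data, axes=([1, 4], [1, 2]))  # (N,T',V,C_out)
        out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
        out_data += bias.data.reshape(1, c_out, 1, 1)

        def backward(g):
            if w.requires_grad:
                gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))  # (C_out,C_in,K)
                w._accum(gw)
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gx_pad = np.zeros_like(xp)
                # (N,C_out,T',V) x (C_out,C_in,K) -> (N,T',V,C_in,K)
                contrib = np.tensordot(g, w.data, axes=(1, 0))
                contrib = contrib.transpose(0, 3, 1, 2, 4)  # (N,C_in,T',V,K)
                for k in range(kt):  # strided slices never alias for one tap
                    stop = k + (t_out - 1) * stride + 1
                    gx_pad[:, :, k:stop:stride, :] += contrib[..., k]
                x._accum(gx_pad[:, :, pad:pad + t, :])

        return self._make(out_data, (x, w, bias), backward)


class Parameter(Tensor):
    """A tensor registered as trainable (``requires_grad=True``)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row ``logits``.

    Computed as ``-mean(log_softmax(logits)[i, y_i])`` with the standard
    max-shift for stability; the shift is treated as a constant.
    """
    labels = np.asarray(labels)
    n, num_classes = logits.shape
    shift = logits.data.max(axis=1, keepdims=True)
    shifted = logits - Tensor(shift)
    logsumexp = shifted.exp().sum(axis=1, keepdims=True).log()
    log_probs = shifted - logsumexp
    onehot = np.zeros((n, num_classes), dtype=logits.data.dtype)
    onehot[np.arange(n), labels] = 1.0
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / n)
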