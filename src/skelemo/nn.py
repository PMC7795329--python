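"""Neural-network building blocks and the SGD optimizer.

Thin module system over :mod:`skelemo.autograd`: layers own
:class:`~skelemo.autograd.Parameter` tensors, `Module.parameters()`
collects them recursively, and ``train()``/``eval()`` toggle the
behaviour of batch normalization and dropout.  All parameters are
float32 and every random initialization draws from an explicitly passed
``numpy.random.Generator`` so runs are reproducible bit for bit.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor

DTYPE = np.float32


class Module:
    training: bool = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            candidates = value if isinstance(value, (list, tuple)) else [value]
            for item in candidates:
                if isinstance(item, Parameter) and id(item) not in seen:
                    seen.add(id(item))
                    yield item
                elif isinstance(item, Module):
                    yield from item.parameters()

    def _submodules(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            candidates = value if isinstance(value, (list, tuple)) else [value]
            for item in candidates:
                if isinstance(item, Module):
                    yield item

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # state dict keyed by attribute path, used by checkpointing
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            items = (
                [(f"{name}.{i}", v) for i, v in enumerate(value)]
                if isinstance(value, (list, tuple))
                else [(name, value)]
            )
            for key, item in items:
                path = f"{prefix}{key}"
                if isinstance(item, Parameter):
                    out[path] = item.data
                elif isinstance(item, Module):
                    out.update(item.state_arrays(prefix=path + "."))
                elif isinstance(item, np.ndarray):  # running BN statistics
                    out[path] = item
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            items = (
                [(f"{name}.{i}", v) for i, v in enumerate(value)]
                if isinstance(value, (list, tuple))
                else [(name, value)]
            )
            for key, item in items:
                path = f"{prefix}{key}"
                if isinstance(item, Parameter):
                    item.data = np.asarray(state[path], dtype=item.data.dtype)
                elif isinstance(item, Module):
                    item.load_state_arrays(state, prefix=path + ".")
                elif isinstance(item, np.ndarray):
                    setattr(self, name, np.asarray(state[path], dtype=item.dtype))


def kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-normal initialization, the convention for ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Linear(Module):
    """Affine map on the last axis: ``y = x W + b``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Parameter(kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis.

    ``axes`` are the reduction axes; for an (N, C, T, V) feature map with
    channels on axis 1 use ``axes=(0, 2, 3)``.  Running statistics are
    tracked with momentum 0.1 for evaluation mode.
    """

    def __init__(self, num_features: int, axes: tuple[int, ...] = (0, 2, 3),
                 eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(num_features, dtype=DTYPE))
        self.beta = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        self.axes = axes
        self.eps = eps
        self.momentum = momentum

    def _param_shape(self, ndim: int) -> tuple[int, ...]:
        shape = [1] * ndim
        channel_axis = next(i for i in range(ndim) if i not in self.axes)
        shape[channel_axis] = -1
        return tuple(shape)

    def __call__(self, x: Tensor) -> Tensor:
        shape = self._param_shape(x.ndim)
        if self.training:
            mean = x.mean(axis=self.axes, keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=self.axes, keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.reshape(-1)).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(DTYPE)
            xhat = (x - mean) * (var + self.eps) ** -0.5
        else:
            mean = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class SGD:
    """Stochastic gradient descent with momentum and optional weight decay."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data = p.data + v
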