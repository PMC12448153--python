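"""Neural-network building blocks: layers, parameter containers, Adam.

Layers are thin parameter holders whose ``__call__`` builds an autodiff
graph with :mod:`ncrfseg.autodiff`.  Parameters are named hierarchically
(``encoder.0.conv1.weight``) so checkpoints are flat name->array maps.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: tracks parameters, buffers and submodules by name."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}

    def add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(value)
        return self._buffers[name]

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer:" + name] = b.copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer:"):
                continue
            if name not in params:
                raise KeyError(f"unexpected parameter {name!r} in state dict")
            if params[name].data.shape != value.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            params[name].data = value.astype(params[name].data.dtype).copy()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        w = rng.normal(0.0, scale, size=(in_features, out_features)).astype(dtype)
        self.weight = self.add_param("weight", w)
        self.bias = self.add_param("bias", np.zeros(out_features, dtype=dtype))
        self.in_features = in_features
        self.out_features = out_features

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = ad.reshape(x, (-1, self.in_features))
        out = ad.matmul(flat, self.weight) + self.bias
        return ad.reshape(out, shape[:-1] + (self.out_features,))


class MLP(Module):
    """Fully connected stack with ReLU between layers, shared across pixels."""

    def __init__(self, widths: list[int], rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.layers = []
        for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
            layer = Linear(a, b, rng, dtype=dtype)
            self.add_module(f"layer{i}", layer)
            self.layers.append(layer)

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.relu(x)
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None, dtype=np.float32):
        super().__init__()
        k = kernel_size
        scale = np.sqrt(2.0 / (in_channels * k * k))
        w = rng.normal(0.0, scale, size=(k, k, in_channels, out_channels)).astype(dtype)
        self.weight = self.add_param("weight", w)
        self.bias = self.add_param("bias", np.zeros(out_channels, dtype=dtype))
        self.padding = k // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(channels, dtype=dtype))
        self.beta = self.add_param("beta", np.zeros(channels, dtype=dtype))
        self.eps = eps
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        return ad.instance_norm2d(x, self.gamma, self.beta, eps=self.eps)


class ConvBlock(Module):
    """conv3x3 -> InstanceNorm -> ReLU, twice."""

    def __init__(self, in_channels: int, out_channels: int, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = self.add_module("conv1", Conv2d(in_channels, out_channels, 3, rng, dtype=dtype))
        self.norm1 = self.add_module("norm1", InstanceNorm2d(out_channels, dtype=dtype))
        self.conv2 = self.add_module("conv2", Conv2d(out_channels, out_channels, 3, rng, dtype=dtype))
        self.norm2 = self.add_module("norm2", InstanceNorm2d(out_channels, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.relu(self.norm1(self.conv1(x)))
        return ad.relu(self.norm2(self.conv2(x)))


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class Adam:
    """Adam with L2 weight-decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
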