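"""Parameterized building blocks for the voxel model."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Minimal layer container with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {arr.shape}")
            p.data = arr.astype(np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv3d(Module):
    """'Same' 3-D convolution with He-normal initialization."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k ** 3
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = ad.parameter(rng.normal(0.0, std, size=(cout, cin, k, k, k)))
        self.bias = ad.parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias)


class ConvBlock(Module):
    """Convolution followed by ReLU."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.conv = Conv3d(cin, cout, k, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.conv(x))


class ChannelGate(Module):
    """Squeeze-and-excitation style channel attention.

    Global average pooling followed by two 1×1×1 convolutions (bottleneck,
    then expansion with a sigmoid) producing per-channel weights in (0, 1).
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        mid = max(1, channels // reduction)
        self.fc1 = Conv3d(channels, mid, 1, rng)
        self.fc2 = Conv3d(mid, channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        g = ad.global_avg_pool(x)
        g = ad.relu(self.fc1(g))
        return ad.sigmoid(self.fc2(g))


def pick(t: Tensor, i: int) -> Tensor:
    """Extract element ``i`` of a 1-D tensor as a broadcastable (1,1,1,1) scalar."""

    def backward(g):
        if t.requires_grad:
            gz = np.zeros_like(t.data)
            gz[i] = g.sum()
            t._accumulate(gz)

    return Tensor(t.data[i].reshape(1, 1, 1, 1), parents=(t,), backward=backward)
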