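"""Layer objects built on the autodiff core.

Initialization follows Xavier (Glorot) uniform throughout, seeded per layer
collection so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, max_pool2


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match model parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int, stride: int, rng: np.random.Generator):
        fan_in = in_channels * kernel * kernel
        fan_out = out_channels * kernel * kernel
        self.weight = Tensor(
            xavier_uniform(rng, (out_channels, in_channels, kernel, kernel), fan_in, fan_out),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Tensor(
            xavier_uniform(rng, (in_features, out_features), in_features, out_features),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MaxPool2(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return max_pool2(x)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep
    return x * Tensor(mask)
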