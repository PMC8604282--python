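"""Layer and optimiser primitives on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d, relu

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "Linear", "ReLU", "Sequential", "SGD"]


class Module:
    """Base class: anything with named parameters, discoverable recursively."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        # dedupe by identity: shared modules contribute their tensors once
        seen: dict[int, Tensor] = {}
        for _, p in self.named_parameters():
            seen.setdefault(id(p), p)
        return list(seen.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, k: int = 3, stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = _he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    """Learned upsampling; kernel size equals stride (exact, non-overlapping)."""

    def __init__(self, rng, in_ch: int, out_ch: int, stride: int):
        self.stride = stride
        self.weight = _he_init(rng, (in_ch, out_ch, stride, stride), in_ch)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, rng, in_features: int, out_features: int):
        self.weight = _he_init(rng, (in_features, out_features), in_features)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return relu(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def __call__(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
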