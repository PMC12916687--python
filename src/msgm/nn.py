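"""Small neural-network building blocks on top of :mod:`msgm.autodiff`."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor


class Module:
    """Parameter container with recursive discovery, torch-style but tiny."""

    training: bool = True

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            yield from _collect(value, seen)

    def named_parameters(self) -> Iterator[tuple[str, Tensor]]:
        seen: set[int] = set()
        for name, value in self.__dict__.items():
            for sub, p in _collect_named(value, seen):
                yield (f"{name}{sub}", p)

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value, seen: set[int]):
    if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
        seen.add(id(value))
        yield value
    elif isinstance(value, Module):
        for v in value.__dict__.values():
            yield from _collect(v, seen)
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _collect(item, seen)
    elif isinstance(value, dict):
        for item in value.values():
            yield from _collect(item, seen)


def _collect_named(value, seen: set[int], prefix: str = ""):
    if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
        seen.add(id(value))
        yield prefix, value
    elif isinstance(value, Module):
        for name, v in value.__dict__.items():
            yield from _collect_named(v, seen, f"{prefix}.{name}")
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _collect_named(item, seen, f"{prefix}.{i}")
    elif isinstance(value, dict):
        for k, item in value.items():
            yield from _collect_named(item, seen, f"{prefix}.{k}")


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    """Affine map on the last axis: y = x @ W + b."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = xavier_uniform(rng, in_features, out_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class AdamW:
    """Decoupled weight-decay Adam (the optimizer used for all training here)."""

    def __init__(self, params, lr: float = 3e-4, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
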