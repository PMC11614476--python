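"""Layers, parameter containers, checkpointing and the Adam optimizer.

Everything is built on the package's own reverse-mode engine
(:mod:`pldiffusion._tensor`).  Modules hold named parameters; ``state_dict``
keys are slash-separated module paths, which is also the checkpoint layout
(`numpy .npz` archive, self-describing).
"""

from __future__ import annotations

import json
from typing import Iterator

import numpy as np

from ._tensor import Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Embedding",
    "MLP",
    "Adam",
    "save_checkpoint",
    "load_checkpoint",
]

LAYERNORM_EPS = 1e-5


class Module:
    """Base class: children and parameters are discovered via attributes."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{path}/")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}/{i}/")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _param(rng: np.random.Generator, shape: tuple[int, ...], std: float) -> Tensor:
    if std == 0.0:
        return Tensor(np.zeros(shape), requires_grad=True)
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Linear(Module):
    """Affine map on the last axis; ``bias=False`` gives the no-bias variant."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = _param(rng, (d_in, d_out), std=1.0 / np.sqrt(d_in))
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        from ._tensor import einsum

        letters = "abcdef"[: x.ndim - 1]
        y = einsum(f"{letters}i,io->{letters}o", x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    """Normalization over the last axis with learned scale/offset."""

    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + LAYERNORM_EPS) ** -0.5
        return xc * inv * self.gamma + self.beta


class Embedding(Module):
    """Lookup table: integer tokens -> learned vectors."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.weight = _param(rng, (n_tokens, dim), std=1.0)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(indices, dtype=np.int64))


class MLP(Module):
    """Stack of Linear layers with ReLU between (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class Adam:
    """Standard Adam with bias correction; operates on a Module's parameters."""

    def __init__(self, module: Module, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(module.named_parameters())
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(p.data) for name, p in self.params}
        self.v = {name: np.zeros_like(p.data) for name, p in self.params}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_checkpoint(path, module: Module, config: dict | None = None) -> None:
    """Write parameters keyed by module path, plus a JSON config blob."""
    state = module.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(config or {}).encode(), dtype=np.uint8
    ).copy()
    np.savez(path, **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    config = json.loads(state.pop("__config__").tobytes().decode())
    return state, config
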