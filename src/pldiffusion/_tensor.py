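"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small, float64 tensor engine that supports exactly the operations the
attention trunk, the equivariant denoiser and the losses need: broadcasted
arithmetic, elementwise nonlinearities, reductions, reshapes, gather,
concatenation, a general (ellipsis-free) ``einsum`` and softmax.  Gradients
are accumulated by a topological backward sweep.

The engine is intentionally tiny rather than general: no in-place ops, no
higher-order gradients, scalar loss at the root.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "einsum"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from a scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            # iterative DFS post-order
            stack: list[tuple[Tensor, bool]] = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    if p.requires_grad and id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # ---------------------------------------------------------- elementwise
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log(self) -> "Tensor":
        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def sqrt(self) -> "Tensor":
        return self**0.5

    def sigmoid(self) -> "Tensor":
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def clip_min(self, floor: float) -> "Tensor":
        """max(x, floor); gradient passes where x > floor."""
        mask = self.data > floor

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor(np.maximum(self.data, floor), _parents=(self,), _backward=bw)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(a % self.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), _parents=(self,), _backward=bw)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows along the leading axis (embedding lookup)."""
        idx = np.asarray(indices, dtype=np.int64)
        out_data = self.data[idx]

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # --------------------------------------------------------------- softmax
    def softmax(self, axis: int) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log_softmax(self, axis: int) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor(out_data, _parents=(self,), _backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g: np.ndarray) -> None:
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor(out_data, _parents=tuple(tensors), _backward=bw)


def _parse_subscripts(spec: str, n_ops: int) -> tuple[list[str], str]:
    if "..." in spec:
        raise NotImplementedError("ellipsis not supported")
    if "->" not in spec:
        raise ValueError("explicit output subscripts required")
    lhs, out = spec.split("->")
    subs = lhs.split(",")
    if len(subs) != n_ops:
        raise ValueError("operand count mismatch")
    for s in subs:
        if len(set(s)) != len(s):
            raise NotImplementedError("repeated index within one operand")
    return subs, out


def einsum(spec: str, *operands: Tensor) -> Tensor:
    """Differentiable einsum (explicit output, no ellipsis, no diagonals)."""
    operands = tuple(as_tensor(o) for o in operands)
    subs, out_sub = _parse_subscripts(spec, len(operands))
    out_data = np.einsum(spec, *[o.data for o in operands])

    def bw(g: np.ndarray) -> None:
        for k, op in enumerate(operands):
            if not op.requires_grad:
                continue
            other_subs = [out_sub] + [subs[i] for i in range(len(operands)) if i != k]
            other_data = [g] + [operands[i].data for i in range(len(operands)) if i != k]
            avail = set("".join(other_subs))
            target = subs[k]
            reduced = "".join(c for c in target if c in avail)
            gk = np.einsum(f"{','.join(other_subs)}->{reduced}", *other_data)
            if reduced != target:
                # indices summed out in the forward pass: broadcast back
                for pos, c in enumerate(target):
                    if c not in avail:
                        gk = np.expand_dims(gk, pos)
                gk = np.broadcast_to(gk, op.shape).copy()
            op._accumulate(gk)

    return Tensor(out_data, _parents=operands, _backward=bw)
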