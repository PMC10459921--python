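"""Reverse-mode autodiff on numpy arrays.

A deliberately small engine: enough operator coverage for convolutional
backbones, transformer encoder–decoders, GANs, and IoU-family box losses,
with full broadcasting support.  Gradients are accumulated by a topological
backward sweep from the loss scalar.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

Arrayish = Union["Tensor", np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")
    __array_priority__ = 100  # keep numpy from hijacking reflected ops

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
        name: str = "",
    ):
        self.data = np.asarray(data, dtype=float)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward = _backward
        self._prev = tuple(p for p in _prev if p.requires_grad)
        self.name = name

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x: Arrayish) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other: Arrayish) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other: Arrayish) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other: Arrayish) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other: Arrayish) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: Arrayish) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        out._backward = _bwd
        return out

    def __rtruediv__(self, other: Arrayish) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, requires_grad=self.requires_grad, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = _bwd
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _bwd(g):
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.expand_dims(g, -1) * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = _bwd
        return out

    # -- elementwise nonlinearities --------------------------------------

    def _unary(self, value: np.ndarray, dvalue: np.ndarray) -> "Tensor":
        out = Tensor(value, requires_grad=self.requires_grad, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accumulate(g * dvalue)

        out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        v = np.exp(self.data)
        return self._unary(v, v)

    def log(self) -> "Tensor":
        return self._unary(np.log(self.data), 1.0 / self.data)

    def sqrt(self) -> "Tensor":
        v = np.sqrt(self.data)
        return self._unary(v, 0.5 / np.maximum(v, 1e-300))

    def tanh(self) -> "Tensor":
        v = np.tanh(self.data)
        return self._unary(v, 1.0 - v**2)

    def sigmoid(self) -> "Tensor":
        v = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return self._unary(v, v * (1.0 - v))

    def relu(self) -> "Tensor":
        return self._unary(np.maximum(self.data, 0.0), (self.data > 0).astype(float))

    def abs(self) -> "Tensor":
        return self._unary(np.abs(self.data), np.sign(self.data))

    def arctan(self) -> "Tensor":
        return self._unary(np.arctan(self.data), 1.0 / (1.0 + self.data**2))

    def maximum(self, other: Arrayish) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            np.maximum(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _bwd(g):
            mask = self.data >= other.data
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~mask, other.shape))

        out._backward = _bwd
        return out

    def minimum(self, other: Arrayish) -> "Tensor":
        other = self._lift(other)
        out = Tensor(
            np.minimum(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )

        def _bwd(g):
            mask = self.data <= other.data
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * ~mask, other.shape))

        out._backward = _bwd
        return out

    # -- reductions & shaping --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _prev=(self,),
        )

        def _bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(
            self.data.reshape(shape), requires_grad=self.requires_grad, _prev=(self,)
        )
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.shape)
        )
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(
            self.data.transpose(axes), requires_grad=self.requires_grad, _prev=(self,)
        )
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(inv)
        )
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _prev=(self,))

        def _bwd(g):
            if not self.requires_grad:
                return
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accumulate(buf)

        out._backward = _bwd
        return out


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _prev=tensors,
    )

    def _bwd(g):
        start = 0
        for t in tensors:
            n = t.shape[axis]
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + n)
            if t.requires_grad:
                t._accumulate(g[tuple(sl)])
            start += n

    out._backward = _bwd
    return out


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _prev=tensors,
    )

    def _bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(gp)

    out._backward = _bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, requires_grad=x.requires_grad, _prev=(x,))

    def _bwd(g):
        if x.requires_grad:
            gy = g * y
            x._accumulate(gy - y * gy.sum(axis=axis, keepdims=True))

    out._backward = _bwd
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    y = shifted - lse
    out = Tensor(y, requires_grad=x.requires_grad, _prev=(x,))

    def _bwd(g):
        if x.requires_grad:
            x._accumulate(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

    out._backward = _bwd
    return out
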