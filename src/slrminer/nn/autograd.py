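"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` runs the chain rule over the recorded graph in
reverse topological order.  The op set is exactly what the package's encoder
and sequence models need: broadcasting arithmetic, (batched) matmul, the
usual nonlinearities, stable ``softmax``/``log_softmax``/``logsumexp``
primitives, reshaping, concatenation, and integer gather (whose backward is a
scatter-add, covering embedding lookups and label indexing).

Everything is float32 and single-threaded numpy, so a fixed seed gives
bit-reproducible training runs.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, prev: Sequence["Tensor"] = (), requires_grad: bool = False):
        arr = np.asarray(data)
        # float64 inputs keep their precision (oracle-grade CRF arithmetic);
        # everything else becomes the float32 training dtype
        self.data = arr if arr.dtype == np.float64 else arr.astype(DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in prev)
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = tuple(prev)

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        if isinstance(x, (int, float)):
            return Tensor(np.asarray(x, dtype=DTYPE))
        return Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        return self * other.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))

        out._backward = _bw
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data * out.data))

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        out._backward = _bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _bw
        return out

    def gelu(self) -> "Tensor":
        # tanh approximation of the Gaussian error linear unit
        c = np.sqrt(2.0 / np.pi).astype(DTYPE)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = Tensor(0.5 * x * (1.0 + t), (self,))

        def _bw():
            if self.requires_grad:
                dt = (1.0 - t * t) * c * (1.0 + 3 * 0.044715 * x**2)
                self._accum(out.grad * (0.5 * (1.0 + t) + 0.5 * x * dt))

        out._backward = _bw
        return out

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def _bw():
            g = out.grad
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out

    __matmul__ = matmul

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            denom = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def logsumexp(self, axis: int = -1, keepdims: bool = False) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e.sum(axis=axis, keepdims=True)
        val = m + np.log(s)
        soft = e / s
        out = Tensor(val if keepdims else np.squeeze(val, axis=axis), (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(g * soft)

        out._backward = _bw
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                self._accum(y * (g - (g * y).sum(axis=axis, keepdims=True)))

        out._backward = _bw
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        y = shifted - lse
        out = Tensor(y, (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                self._accum(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        out._backward = _bw
        return out

    # -- shape & indexing --------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), (self,))

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)

        def _bw():
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        out._backward = _bw
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), (self,))

        def _bw():
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], (self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _bw
        return out

    @staticmethod
    def concatenate(tensors: Sequence["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _bw():
            for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(int(s), int(e))
                    t._accum(out.grad[tuple(sl)])

        out._backward = _bw
        return out

    @staticmethod
    def stack(tensors: Sequence["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

        def _bw():
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accum(np.take(out.grad, i, axis=axis))

        out._backward = _bw
        return out


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    t = Tensor(data)
    t.requires_grad = True
    return t
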