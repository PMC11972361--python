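"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations that
produced it; calling :meth:`Tensor.backward` on a scalar loss accumulates
gradients into every upstream tensor created with ``requires_grad=True``.
Only the operations needed by the dense networks in this package are
implemented (broadcasting elementwise arithmetic, matmul, reductions,
exp/log/sqrt, sigmoid, PReLU, concatenation and basic indexing).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def _needs(self) -> bool:
        return self.requires_grad or self._parents != () or self._backward is not None

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self._needs():
                self._accumulate(g)
            if other._needs():
                other._accumulate(g)

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self._needs():
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self._needs():
                self._accumulate(g * other.data)
            if other._needs():
                other._accumulate(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self._needs():
                self._accumulate(g / other.data)
            if other._needs():
                other._accumulate(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            if self._needs():
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self._needs():
                self._accumulate(g @ other.data.T)
            if other._needs():
                other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self._needs():
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def var(self, axis=None, keepdims: bool = False):
        """Population (divide-by-n) variance."""
        mu = self.mean(axis=axis, keepdims=True)
        return ((self - mu) ** 2).mean(axis=axis, keepdims=keepdims)

    def reshape(self, shape):
        shape = tuple(shape) if not np.isscalar(shape) else (shape,)

        def bw(g):
            if self._needs():
                self._accumulate(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bw)

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self._needs():
                self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            if self._needs():
                self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            if self._needs():
                self._accumulate(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self._needs():
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    def prelu(self, slope: "Tensor"):
        """PReLU activation: ``x if x > 0 else slope * x`` (learnable slope)."""
        slope = as_tensor(slope)
        pos = self.data > 0
        out_data = np.where(pos, self.data, slope.data * self.data)

        def bw(g):
            if self._needs():
                self._accumulate(np.where(pos, g, g * slope.data))
            if slope._needs():
                slope._accumulate(np.where(pos, 0.0, g * self.data))

        return Tensor(out_data, parents=(self, slope), backward=bw)

    def relu(self):
        pos = self.data > 0

        def bw(g):
            if self._needs():
                self._accumulate(np.where(pos, g, 0.0))

        return Tensor(np.where(pos, self.data, 0.0), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            if self._needs():
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t._needs():
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(out_data, parents=tuple(tensors), backward=bw)
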