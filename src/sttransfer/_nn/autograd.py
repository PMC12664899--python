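"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's networks need: dense and
sparse-constant matrix products, broadcasting arithmetic, the ELU / ReLU /
sigmoid / softmax nonlinearities, reductions, and the log-gamma function
(for the negative-binomial likelihood). Gradients are accumulated by a
topological backward sweep; correctness is checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus (optionally) a gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1))

        return Tensor(self.data**e, parents=(self,), backward=bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise functions ---------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, out_data + alpha))

        return Tensor(out_data, parents=(self,), backward=bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bw)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor(out_data, parents=(self,), backward=bw)

    def lgamma(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g * digamma(self.data))

        return Tensor(gammaln(self.data), parents=(self,), backward=bw)

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self.data - m
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True)) + m
        out_data = self.data - lse
        soft = np.exp(out_data)

        def bw(g):
            if self.requires_grad:
                self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor(out_data, parents=(self,), backward=bw)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def clip_min(self, lo: float):
        mask = self.data > lo

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(np.maximum(self.data, lo), parents=(self,), backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def spmm(a: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a differentiable dense one."""
    a = a.tocsr()

    def bw(g):
        if x.requires_grad:
            x._accum(a.T @ g)

    return Tensor(a @ x.data, parents=(x,), backward=bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bw,
    )
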