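"""Compact reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the recurrent link-prediction head needs:
matrix products, broadcasting add/mul, tanh/sigmoid/log, row gathering,
column-wise concatenation and reductions.  Gradients are accumulated by a
topological backward sweep; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- operations ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def tanh(self):
        y = np.tanh(self.data)
        return self._make(y, (self,), lambda g: (g * (1.0 - y * y),))

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(y, (self,), lambda g: (g * y * (1.0 - y),))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: (g / self.data,))

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the interior."""
        y = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)
        return self._make(y, (self,), lambda g: (g * mask,))

    def sum(self):
        return self._make(self.data.sum(), (self,),
                          lambda g: (np.full_like(self.data, g),))

    def mean(self):
        n = self.data.size
        return self._make(self.data.mean(), (self,),
                          lambda g: (np.full_like(self.data, g / n),))

    def reshape(self, *shape):
        orig = self.data.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(orig),))

    # ---- backward sweep --------------------------------------------------

    def backward(self):
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for parent, g in zip(t._parents, grads):
                if parent.requires_grad:
                    parent.grad = parent.grad + g if parent.grad is not None else g


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`, splitting the gradient back."""
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    cuts = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, cuts, axis=axis))

    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather_rows(x: Tensor, idx) -> Tensor:
    """Select rows `idx` of a 2-d tensor (gradient scatter-adds back)."""
    idx = np.asarray(idx, dtype=np.intp)
    data = x.data[idx]

    def backward(g):
        full = np.zeros_like(x.data)
        np.add.at(full, idx, g)
        return (full,)

    return x._make(data, (x,), backward)


class Adam:
    """Adam optimizer with bias-corrected first/second moment estimates."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
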