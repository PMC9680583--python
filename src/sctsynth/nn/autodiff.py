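"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine sized for the 2D convolutional
generators and discriminators this package trains on CPU.  Tensors wrap
``numpy`` arrays in NCHW layout (images) or 2D matrices (projected feature
stacks); every operation records a backward closure and ``Tensor.backward``
runs the tape in reverse topological order.

Gradient correctness of each primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        # dtype-preserving: float32 for the training path, float64 elsewhere
        self.data = np.asarray(data)
        if self.data.dtype not in (np.float32, np.float64):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
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
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray):
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = g.copy() if g.base is not None else g
        else:
            t.grad = t.grad + g

    # -- elementwise arithmetic ----------------------------------------------
    def _binary(self, other, fwd, bwd_self, bwd_other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            # python-scalar fast path: no wrapping, so float32 stays float32
            const = float(other)
            out = Tensor(fwd(self.data, const), parents=(self,))
            if out.requires_grad:
                def backward(g, a=self, const=const):
                    Tensor._accum(a, _unbroadcast(bwd_self(g, a.data, const),
                                                  a.data.shape))
                out._backward = backward
            return out
        other = as_tensor(other)
        out_data = fwd(self.data, other.data)
        out = Tensor(out_data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                Tensor._accum(a, _unbroadcast(bwd_self(g, a.data, b.data), a.data.shape))
                Tensor._accum(b, _unbroadcast(bwd_other(g, a.data, b.data), b.data.shape))
            out._backward = backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        if isinstance(other, (int, float, np.integer, np.floating)):
            return (-self) + float(other)
        return as_tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, p=p):
                Tensor._accum(a, g * p * a.data ** (p - 1))
            out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def backward(g, a=self, b=other):
                Tensor._accum(a, g @ b.data.T)
                Tensor._accum(b, a.data.T @ g)
            out._backward = backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self):
                Tensor._accum(a, g.T)
            out._backward = backward
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        if out.requires_grad:
            mask = self.data > 0
            def backward(g, a=self, mask=mask):
                Tensor._accum(a, g * mask)
            out._backward = backward
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     parents=(self,))
        if out.requires_grad:
            dt = self.data.dtype.type
            mask = np.where(self.data > 0, dt(1.0), dt(slope))
            def backward(g, a=self, mask=mask):
                Tensor._accum(a, g * mask)
            out._backward = backward
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, y=y):
                Tensor._accum(a, g * (1.0 - y * y))
            out._backward = backward
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, y=y):
                Tensor._accum(a, g * y * (1.0 - y))
            out._backward = backward
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, y=y):
                Tensor._accum(a, g * y)
            out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            def backward(g, a=self):
                Tensor._accum(a, g / a.data)
            out._backward = backward
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        if out.requires_grad:
            sign = np.sign(self.data)
            def backward(g, a=self, sign=sign):
                Tensor._accum(a, g * sign)
            out._backward = backward
        return out

    # -- reductions / reshapes ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def backward(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                Tensor._accum(a, np.broadcast_to(g, a.data.shape))
            out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            def backward(g, a=self):
                Tensor._accum(a, g.reshape(a.data.shape))
            out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
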