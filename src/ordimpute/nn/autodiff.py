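"""Minimal reverse-mode tensor autodiff on numpy.

Just the operations the package's neural imputers need: broadcasting
arithmetic, batched matmul, a fused linear layer, ReLU, softmax, layer
normalization, reshapes and reductions.  Gradients are accumulated by
topological traversal of the operation graph; every op's backward is
exact (verified against central finite differences in the test suite).

Float32 inputs stay float32 throughout (the transformer imputer trains
in single precision); anything else is promoted to float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "relu", "softmax", "layer_norm", "matmul", "linear"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype != np.float32:
            data = data.astype(np.float64, copy=False)
        self.data = data
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray, fresh: bool = True) -> None:
        """Add ``grad`` to this tensor's gradient.

        ``fresh=True`` promises the array is newly allocated and uniquely
        owned, so it can be adopted without a defensive copy.
        """
        if self.grad is None:
            self.grad = grad if fresh else grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = _unbroadcast(g, a.data.shape)
                a._accumulate(ga, fresh=ga is not g)
            if b.requires_grad:
                gb = _unbroadcast(g, b.data.shape)
                b._accumulate(gb, fresh=gb is not g)

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by plain scalars")
        return self * (1.0 / scalar)

    def square(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * 2.0 * a.data)

        return Tensor._make(self.data**2, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accumulate(g.reshape(old), fresh=False)

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g, a=self, inv=tuple(inv)):
            if a.requires_grad:
                a._accumulate(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        shape = self.data.shape

        def backward(g, a=self, axis=axis, keepdims=keepdims, shape=shape):
            if not a.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, shape), fresh=False)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    # -- autodiff ---------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""

    def backward(g, a=a, b=b):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._make(a.data @ b.data, (a, b), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Fused affine map ``x @ w + b`` over the last axis.

    Flattens the leading axes into a single GEMM; with small per-row
    matrices numpy's broadcast matmul would loop over the batch.
    """
    k, m = w.data.shape
    lead = x.data.shape[:-1]
    x2 = x.data.reshape(-1, k)
    out = x2 @ w.data
    out += b.data
    out = out.reshape(*lead, m)

    def backward(g, x=x, w=w, b=b, x2=x2, lead=lead, k=k, m=m):
        g2 = g.reshape(-1, m)
        if x.requires_grad:
            x._accumulate((g2 @ w.data.T).reshape(*lead, k))
        if w.requires_grad:
            w._accumulate(x2.T @ g2)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))

    return Tensor._make(out, (x, w, b), backward)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)

    def backward(g, a=x, out=out):
        if a.requires_grad:
            a._accumulate(g * (out > 0))

    return Tensor._make(out, (x,), backward)


def softmax(x: Tensor, bias: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis, optionally with an additive constant
    bias (e.g. a -inf attention mask) applied to the logits."""
    logits = x.data if bias is None else x.data + bias
    shifted = logits - logits.max(axis=-1, keepdims=True)
    y = np.exp(shifted)
    y /= y.sum(axis=-1, keepdims=True)

    def backward(g, a=x, y=y):
        if a.requires_grad:
            a._accumulate(y * (g - (g * y).sum(axis=-1, keepdims=True)))

    return Tensor._make(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis with learned scale/shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv):
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            gb = _unbroadcast(g, beta.data.shape)
            beta._accumulate(gb, fresh=gb is not g)
        if x.requires_grad:
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gx - m1 - xhat * m2))

    return Tensor._make(xhat * gamma.data + beta.data, (x, gamma, beta), backward)
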