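"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` (float64) and records the operations
applied to it; :meth:`Tensor.backward` runs reverse-mode accumulation over
the recorded graph.  Only the primitives needed by the models in this
package are provided (elementwise arithmetic with broadcasting, matmul,
reductions, gather/concat/reshape, and fused softmax / log-softmax /
standardize kernels for attention and layer normalization).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0 if other.requires_grad else self * Tensor(1.0 / other.data)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            self._accum(g * (self.data > 0.0))

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._from_op(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._from_op(out_data, (self,), backward)

    # -- fused kernels --------------------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._from_op(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def backward(g):
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._from_op(out_data, (self,), backward)

    def standardize(self, axis: int = -1, eps: float = 1e-5):
        """Zero-mean unit-variance normalization along ``axis`` (layer-norm core)."""
        mu = self.data.mean(axis=axis, keepdims=True)
        xc = self.data - mu
        var = (xc ** 2).mean(axis=axis, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv

        def backward(g):
            n = self.data.shape[axis]
            gm = g.mean(axis=axis, keepdims=True)
            gy = (g * out_data).mean(axis=axis, keepdims=True)
            self._accum(inv * (g - gm - out_data * gy))

        return Tensor._from_op(out_data, (self,), backward)

    def add_const(self, arr):
        """Add a non-differentiable array (attention masks etc.)."""
        arr = np.asarray(arr, dtype=np.float64)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))

        return Tensor._from_op(self.data + arr, (self,), backward)

    def mul_const(self, arr):
        """Multiply by a non-differentiable array (dropout / padding masks)."""
        arr = np.asarray(arr, dtype=np.float64)

        def backward(g):
            self._accum(_unbroadcast(g * arr, self.data.shape))

        return Tensor._from_op(self.data * arr, (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def fused_mlp(x: Tensor, w1: Tensor, b1: Tensor, w2: Tensor, b2: Tensor) -> Tensor:
    """relu(x @ w1 + b1) @ w2 + b2 as one graph node (2-D ``x`` only).

    Collapsing the seven elementary nodes of the two-layer MLP into one
    removes most of the Python graph overhead on the hot path.
    """
    z = x.data @ w1.data + b1.data
    h = np.maximum(z, 0.0)
    out_data = h @ w2.data + b2.data

    def backward(g):
        if b2.requires_grad:
            b2._accum(g.sum(axis=0))
        if w2.requires_grad:
            w2._accum(h.T @ g)
        gh = g @ w2.data.T
        gz = gh * (z > 0.0)
        if b1.requires_grad:
            b1._accum(gz.sum(axis=0))
        if w1.requires_grad:
            w1._accum(x.data.T @ gz)
        if x.requires_grad:
            x._accum(gz @ w1.data.T)

    return Tensor._from_op(out_data, (x, w1, b1, w2, b2), backward)


def fused_attention(q_in: Tensor, kv_in: Tensor,
                    wq: Tensor, bq: Tensor, wk: Tensor, bk: Tensor,
                    wv: Tensor, bv: Tensor, wo: Tensor, bo: Tensor,
                    heads: int, mask: np.ndarray | None = None) -> Tensor:
    """Complete multi-head scaled-dot-product attention as one graph node.

    Used on the hot path when the attention matrix itself is not needed
    downstream; the composed implementation remains for the alignment-
    supervised decoder cross-attention.
    """
    Lq, d = q_in.shape
    Lk = kv_in.shape[0]
    dh = wq.shape[1] // heads
    scale = 1.0 / np.sqrt(dh)
    Q = (q_in.data @ wq.data + bq.data).reshape(Lq, heads, dh).transpose(1, 0, 2)
    K = (kv_in.data @ wk.data + bk.data).reshape(Lk, heads, dh).transpose(1, 0, 2)
    V = (kv_in.data @ wv.data + bv.data).reshape(Lk, heads, dh).transpose(1, 0, 2)
    S = Q @ K.transpose(0, 2, 1) * scale
    if mask is not None:
        S = S + np.where(mask, 0.0, -1e9)
    S -= S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    A = E / E.sum(axis=-1, keepdims=True)
    O = (A @ V).transpose(1, 0, 2).reshape(Lq, heads * dh)
    out_data = O @ wo.data + bo.data

    def backward(g):
        if bo.requires_grad:
            bo._accum(g.sum(axis=0))
        if wo.requires_grad:
            wo._accum(O.T @ g)
        gO = (g @ wo.data.T).reshape(Lq, heads, dh).transpose(1, 0, 2)
        gA = gO @ V.transpose(0, 2, 1)
        gV = A.transpose(0, 2, 1) @ gO
        gS = A * (gA - (gA * A).sum(axis=-1, keepdims=True))
        gQ = gS @ K * scale
        gK = gS.transpose(0, 2, 1) @ Q * scale
        gQ = gQ.transpose(1, 0, 2).reshape(Lq, heads * dh)
        gK = gK.transpose(1, 0, 2).reshape(Lk, heads * dh)
        gV = gV.transpose(1, 0, 2).reshape(Lk, heads * dh)
        if wq.requires_grad:
            wq._accum(q_in.data.T @ gQ)
        if bq.requires_grad:
            bq._accum(gQ.sum(axis=0))
        if wk.requires_grad:
            wk._accum(kv_in.data.T @ gK)
        if bk.requires_grad:
            bk._accum(gK.sum(axis=0))
        if wv.requires_grad:
            wv._accum(kv_in.data.T @ gV)
        if bv.requires_grad:
            bv._accum(gV.sum(axis=0))
        if q_in.requires_grad:
            q_in._accum(gQ @ wq.data.T)
        if kv_in.requires_grad:
            kv_in._accum(gK @ wk.data.T + gV @ wv.data.T)

    return Tensor._from_op(out_data, (q_in, kv_in, wq, bq, wk, bk, wv, bv, wo, bo),
                           backward)


def fused_layer_norm(x: Tensor, gain: Tensor, shift: Tensor,
                     eps: float = 1e-5) -> Tensor:
    """standardize(x) * gain + shift as one graph node."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out_data = xn * gain.data + shift.data

    def backward(g):
        if shift.requires_grad:
            shift._accum(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if gain.requires_grad:
            gain._accum((g * xn).reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            gx = g * gain.data
            gm = gx.mean(axis=-1, keepdims=True)
            gy = (gx * xn).mean(axis=-1, keepdims=True)
            x._accum(inv * (gx - gm - xn * gy))

    return Tensor._from_op(out_data, (x, gain, shift), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._from_op(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)
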