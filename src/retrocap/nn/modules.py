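"""Neural-network building blocks (linear, layer norm, attention, FFN).

Parameter initialization is driven by an explicit ``numpy.random.Generator``
so that model construction is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate, fused_attention, fused_layer_norm, fused_mlp

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "FeedForward",
    "MultiHeadAttention",
    "sinusoidal_positions",
]


class Module:
    """Base class: recursively collects :class:`Tensor` parameters."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                params[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def set_training(self, flag: bool) -> None:
        for val in vars(self).values():
            if isinstance(val, Dropout):
                val.training = flag
            elif isinstance(val, Module):
                val.set_training(flag)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.set_training(flag)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    """Token embedding table; init scale 1/sqrt(dim) so that embeddings
    multiplied by sqrt(d_model) match the unit scale of the sinusoidal
    positional encodings."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 1.0 / np.sqrt(dim), size=(n, dim)),
                             requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return fused_layer_norm(x, self.gain, self.shift, eps=self.eps)


class Dropout(Module):
    """Inverted dropout; identity when ``training`` is False or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = self.rng.random(x.shape) < keep
        return x.mul_const(mask / keep)


class FeedForward(Module):
    """Two-layer MLP with ReLU, the FFN block used throughout the model."""

    def __init__(self, in_dim: int, hidden: int, out_dim: int, rng: np.random.Generator):
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            return fused_mlp(x, self.fc1.weight, self.fc1.bias,
                             self.fc2.weight, self.fc2.bias)
        return self.fc2(self.fc1(x).relu())


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``heads`` parallel heads.

    ``__call__`` returns ``(output, attn)`` where ``attn`` is the
    head-averaged attention matrix (queries x keys), used for the
    SMILES-alignment supervision and for inspection.
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 kv_dim: int | None = None):
        if d_model % heads:
            raise ValueError("d_model must be divisible by heads")
        kv_dim = kv_dim if kv_dim is not None else d_model
        self.heads = heads
        self.d_head = d_model // heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(kv_dim, d_model, rng)
        self.wv = Linear(kv_dim, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, q_in: Tensor, kv_in: Tensor, mask: np.ndarray | None = None,
                 need_attn: bool = True):
        if not need_attn:
            out = fused_attention(q_in, kv_in,
                                  self.wq.weight, self.wq.bias,
                                  self.wk.weight, self.wk.bias,
                                  self.wv.weight, self.wv.bias,
                                  self.wo.weight, self.wo.bias,
                                  self.heads, mask=mask)
            return out, None
        Lq = q_in.shape[0]
        Lk = kv_in.shape[0]
        h, dh = self.heads, self.d_head
        # (L, d) -> (heads, L, d_head)
        q = self.wq(q_in).reshape(Lq, h, dh).swapaxes(0, 1)
        k = self.wk(kv_in).reshape(Lk, h, dh).swapaxes(0, 1)
        v = self.wv(kv_in).reshape(Lk, h, dh).swapaxes(0, 1)
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(dh))
        if mask is not None:
            scores = scores.add_const(np.where(mask, 0.0, -1e9))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).swapaxes(0, 1).reshape(Lq, h * dh)
        return self.wo(out), attn.mean(axis=0)


def sinusoidal_positions(length: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding matrix of shape (length, d_model)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe
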