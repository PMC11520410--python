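"""Contrastive reaction-center captioner.

Two pieces:

* :func:`caption_weights` — sequence-aware node weighting.  Projected node
  embeddings are compared with every sequence-token embedding (cosine
  similarity), pooled over tokens and softmax-normalized over nodes to
  yield a per-node weight; the weighted node embeddings feed the
  dual-view fusion.
* :func:`contrastive_loss` — two learnable centers ``c_rc`` / ``c_nrc``
  pull the projected embeddings of reaction-center and non-center atoms
  toward their group centers while a margin term fixes the
  center-to-center separation at ``gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import FeedForward, Module, Tensor

__all__ = [
    "CaptionerState", "WeightedGraph", "Captioner",
    "contrastive_loss", "optimize_centers_demo",
]


@dataclass
class WeightedGraph:
    w: Tensor        # m node weights, non-negative, sum to 1
    H_w: Tensor      # m x d weighted node embeddings (w broadcast over H_g)
    H_hat: Tensor    # m x d projected node embeddings (feeds the contrastive loss)


class CaptionerState(Module):
    """Learnable group centers plus the fixed margin gamma."""

    def __init__(self, dim: int, gamma: float | np.ndarray = 1.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_rc = Tensor(rng.normal(0.0, 0.1, size=dim), requires_grad=True)
        self.c_nrc = Tensor(rng.normal(0.0, 0.1, size=dim), requires_grad=True)
        self.gamma = np.broadcast_to(np.asarray(gamma, dtype=np.float64), (dim,)).copy()


def _cosine_sim(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    an = a * ((a * a).sum(axis=-1, keepdims=True) + eps) ** -0.5
    bn = b * ((b * b).sum(axis=-1, keepdims=True) + eps) ** -0.5
    return an @ bn.swapaxes(0, 1)


def _dot_sim(a: Tensor, b: Tensor) -> Tensor:
    return (a @ b.swapaxes(0, 1)) * (1.0 / np.sqrt(a.shape[-1]))


_SIMILARITIES = {"cosine": _cosine_sim, "dot": _dot_sim}


class Captioner(Module):
    """Projection FFN + centers; owns the caption-weighting computation."""

    def __init__(self, graph_dim: int, seq_dim: int, rng: np.random.Generator,
                 gamma: float = 1.0, similarity: str = "cosine"):
        if similarity not in _SIMILARITIES:
            raise ValueError(f"unknown similarity {similarity!r}")
        self.proj = FeedForward(graph_dim, graph_dim, seq_dim, rng)
        self.state = CaptionerState(seq_dim, gamma=gamma, rng=rng)
        self.similarity = similarity

    def caption_weights(self, H_g: Tensor, H_s: Tensor,
                        token_mask: np.ndarray | None = None) -> WeightedGraph:
        """Weight graph nodes by their pooled similarity to the sequence.

        ``token_mask`` marks real (non-PAD) token positions; pooling is the
        arithmetic mean over those positions.
        """
        H_hat = self.proj(H_g)
        sim = _SIMILARITIES[self.similarity](H_hat, H_s)   # m x L
        if token_mask is not None:
            mask = np.asarray(token_mask, dtype=np.float64)
            pooled = (sim.mul_const(mask)).sum(axis=1) * (1.0 / max(mask.sum(), 1.0))
        else:
            pooled = sim.mean(axis=1)
        w = pooled.softmax(axis=0)
        H_w = H_g * w.reshape(-1, 1)
        return WeightedGraph(w=w, H_w=H_w, H_hat=H_hat)


def contrastive_loss(H_hat: Tensor, labels, state: CaptionerState) -> Tensor:
    """||c_nrc - c_rc + gamma||^2 + mean||h_rc - c_rc||^2 + mean||h_nrc - c_nrc||^2.

    A group-scatter term is dropped when its group is empty (identity
    reactions have no centers; fully-reactive toy graphs no non-centers).
    """
    atom_labels = np.asarray(labels.atom_labels)
    m = H_hat.shape[0]
    if m == 0:
        raise ValueError("contrastive loss undefined for an empty graph")
    if atom_labels.shape[0] != m:
        raise ValueError(f"{atom_labels.shape[0]} labels for {m} nodes")
    diff = state.c_nrc - state.c_rc + Tensor(state.gamma)
    loss = (diff * diff).sum()
    rc_idx = np.nonzero(atom_labels == 1)[0]
    nrc_idx = np.nonzero(atom_labels == 0)[0]
    if len(rc_idx):
        d = H_hat[rc_idx] - state.c_rc
        loss = loss + (d * d).sum(axis=1).mean()
    if len(nrc_idx):
        d = H_hat[nrc_idx] - state.c_nrc
        loss = loss + (d * d).sum(axis=1).mean()
    return loss


def optimize_centers_demo(H_hat: np.ndarray, labels, state: CaptionerState,
                          steps: int = 200, lr: float = 0.05) -> CaptionerState:
    """Plain gradient descent on the centers alone with embeddings frozen.

    The objective is a jointly convex quadratic in (c_rc, c_nrc), so fixed
    step-size descent contracts linearly to the unique stationary point
    (Adam's adaptive steps would keep wandering in its neighbourhood).
    """
    H = Tensor(np.asarray(H_hat, dtype=np.float64))
    for _ in range(steps):
        state.c_rc.grad = None
        state.c_nrc.grad = None
        loss = contrastive_loss(H, labels, state)
        loss.backward()
        state.c_rc.data -= lr * state.c_rc.grad
        state.c_nrc.data -= lr * state.c_nrc.grad
    return state
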