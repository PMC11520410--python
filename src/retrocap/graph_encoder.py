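"""Message-passing graph encoder with random-walk positional encoding.

The encoder maintains three streams — node embeddings ``h``, edge
embeddings ``e`` and positional embeddings ``p`` — updated per layer by
learnable message functions over the molecular graph, with residual
connections and layer normalization.  Two sigmoid heads score each atom
and each bond for membership in the reaction center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .nn import FeedForward, LayerNorm, Linear, Module, Tensor, concatenate

__all__ = [
    "GraphEncoderConfig", "GraphEmbeddings", "RCScores",
    "random_walk_pe", "GraphEncoder", "rc_loss",
]


def random_walk_pe(adjacency: np.ndarray, k: int) -> np.ndarray:
    """Return-probability positional encoding.

    Column ``t`` (t = 1..k) holds ``diag((D^-1 A)^t)``: the probability
    that a simple random walk started at each node is back at that node
    after ``t`` steps.  Isolated nodes get an all-zero row.
    """
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if k < 1:
        raise ValueError("k must be >= 1")
    m = A.shape[0]
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_deg = np.where(deg > 0, 1.0 / deg, 0.0)
    P = inv_deg[:, None] * A
    out = np.zeros((m, k))
    M = np.eye(m)
    for t in range(k):
        M = M @ P
        out[:, t] = np.diag(M)
    return out


@dataclass
class GraphEncoderConfig:
    layers: int = 3
    dim: int = 128            # shared node/edge embedding width
    rw_steps: int = 20        # k of the random-walk diffusion
    rbf_centers: int = 20
    dropout: float = 0.0

    def __post_init__(self):
        if self.dim <= 0 or self.rw_steps < 1 or self.layers < 0:
            raise ConfigError(f"invalid graph encoder config: {self}")


@dataclass
class GraphEmbeddings:
    H_g: Tensor   # m x d node embeddings
    E: Tensor     # n x d directed-edge embeddings
    P: Tensor     # m x d positional embeddings


@dataclass
class RCScores:
    atom_scores: Tensor   # m probabilities in (0, 1)
    bond_scores: Tensor   # one probability per undirected bond


class _MPGNNLayer(Module):
    def __init__(self, d: int, rng: np.random.Generator):
        self.msg_h = FeedForward(3 * d, d, d, rng)
        self.upd_h = FeedForward(3 * d, d, d, rng)
        self.upd_e = FeedForward(3 * d, d, d, rng)
        self.msg_p = FeedForward(2 * d, d, d, rng)
        self.upd_p = FeedForward(2 * d, d, d, rng)
        self.ln_h = LayerNorm(d)
        self.ln_e = LayerNorm(d)
        self.ln_p = LayerNorm(d)

    def __call__(self, h: Tensor, e: Tensor, p: Tensor,
                 src: np.ndarray, dst: np.ndarray, scatter: np.ndarray):
        S = Tensor(scatter)
        # node stream: aggregate messages from neighbours j -> i over edges
        msg = self.msg_h(concatenate([h[src], p[src], e], axis=-1))
        agg = S @ msg
        h_new = self.ln_h(h + self.upd_h(concatenate([h, p, agg], axis=-1)))
        # edge stream: endpoints + current edge state
        e_new = self.ln_e(e + self.upd_e(concatenate([h[src], h[dst], e], axis=-1)))
        # positional stream: neighbour positions modulated by edge state
        pmsg = self.msg_p(concatenate([p[src], e], axis=-1))
        p_new = self.ln_p(p + self.upd_p(concatenate([p, S @ pmsg], axis=-1)))
        return h_new, e_new, p_new


class GraphEncoder(Module):
    """MPNN over a featurized molecule; exposes embeddings and RC scores."""

    def __init__(self, cfg: GraphEncoderConfig, node_in: int, edge_in: int,
                 rng: np.random.Generator):
        d = cfg.dim
        self.cfg = cfg
        self.node_init = FeedForward(node_in + cfg.rw_steps, d, d, rng)
        self.pe_init_ffn = FeedForward(cfg.rw_steps, d, d, rng)
        self.edge_init = FeedForward(edge_in, d, d, rng)
        self.rbf_proj = Linear(cfg.rbf_centers, d, rng)
        self.layers = [_MPGNNLayer(d, rng) for _ in range(cfg.layers)]
        self.atom_head = FeedForward(d, d, 1, rng)
        self.bond_head = FeedForward(d, d, 1, rng)

    # -- core operations ------------------------------------------------------
    def init_embeddings(self, graph) -> GraphEmbeddings:
        """h0 = FFN([h_init; pe]); p0 = FFN(pe); e0 = FFN(e_init) + proj(RBF(d))."""
        if graph.pe_init.shape[1] != self.cfg.rw_steps:
            raise ConfigError(
                f"graph rw_steps {graph.pe_init.shape[1]} != config {self.cfg.rw_steps}")
        hp = np.concatenate([graph.node_features, graph.pe_init], axis=1)
        h0 = self.node_init(Tensor(hp))
        p0 = self.pe_init_ffn(Tensor(graph.pe_init))
        e0 = self.edge_init(Tensor(graph.edge_features)) + self.rbf_proj(Tensor(graph.rbf_dist))
        return GraphEmbeddings(H_g=h0, E=e0, P=p0)

    def mpgnn_forward(self, emb: GraphEmbeddings, graph) -> GraphEmbeddings:
        h, e, p = emb.H_g, emb.E, emb.P
        m = graph.num_nodes
        src = graph.edge_index[:, 0] if graph.num_edges else np.zeros(0, dtype=np.intp)
        dst = graph.edge_index[:, 1] if graph.num_edges else np.zeros(0, dtype=np.intp)
        scatter = getattr(graph, "_scatter_cache", None)
        if scatter is None or scatter.shape != (m, graph.num_edges):
            scatter = np.zeros((m, graph.num_edges))
            scatter[dst, np.arange(graph.num_edges)] = 1.0
            graph._scatter_cache = scatter
        for layer in self.layers:
            h, e, p = layer(h, e, p, src, dst, scatter)
            if not (np.isfinite(h.data).all() and np.isfinite(e.data).all()):
                raise FloatingPointError("non-finite embedding in MPNN layer")
        return GraphEmbeddings(H_g=h, E=e, P=p)

    def rc_scores(self, emb: GraphEmbeddings) -> RCScores:
        """Sigmoid heads; undirected-bond score = mean of its two directions."""
        atom = self.atom_head(emb.H_g).reshape(-1).sigmoid()
        n = emb.E.shape[0]
        edge = self.bond_head(emb.E).reshape(-1).sigmoid()
        if n:
            bond = edge.reshape(n // 2, 2).mean(axis=1)
        else:
            bond = edge.reshape(0)
        return RCScores(atom_scores=atom, bond_scores=bond)

    def __call__(self, graph) -> tuple[GraphEmbeddings, RCScores]:
        emb = self.mpgnn_forward(self.init_embeddings(graph), graph)
        return emb, self.rc_scores(emb)


def _bce(scores: Tensor, labels: np.ndarray) -> Tensor:
    y = np.asarray(labels, dtype=np.float64)
    if scores.shape[0] != y.shape[0]:
        raise ValueError(f"score/label length mismatch: {scores.shape} vs {y.shape}")
    s = scores * (1.0 - 2e-7) + 1e-7  # clamp away from {0, 1}
    return -(s.log().mul_const(y) + (1.0 - s).log().mul_const(1.0 - y)).mean()


def rc_loss(scores: RCScores, labels) -> Tensor:
    """Mean binary cross-entropy over atoms plus over bonds."""
    loss = _bce(scores.atom_scores, labels.atom_labels)
    if scores.bond_scores.shape[0]:
        loss = loss + _bce(scores.bond_scores, labels.bond_labels)
    return loss
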