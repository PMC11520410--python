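"""The end-to-end retrosynthesis network and its training loop.

Architecture: a uni-view transformer encoder over the product SMILES, a
dual-view stack whose layers cross-attend to captioner-weighted graph-node
embeddings, and an autoregressive transformer decoder that writes the
reactant SMILES.  Training is multi-task::

    L = L_LM + L_AG + L_CL + L_captioner

with the language-modelling NLL, a SMILES token-alignment loss on the
decoder cross-attention, binary cross-entropy on reaction-center scores,
and the contrastive captioner loss.  The four ablation variants
(plain transformer / graph concat / cross-attention without captioner /
full model) are the toggle settings of :class:`ModelConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from . import chem_io
from .chem_io import (
    MolGraph, RCLabels, Reaction, Vocabulary,
    align_atoms_to_tokens, build_graph, canonicalize, parse_molecule, tokenize,
)
from .errors import ConfigError
from .graph_encoder import GraphEncoder, GraphEncoderConfig, RCScores, rc_loss
from .nn import (
    Adam, Dropout, Embedding, FeedForward, LayerNorm, Linear, Module,
    MultiHeadAttention, Tensor, concatenate, sinusoidal_positions,
)
from .rcaptioner import Captioner, WeightedGraph, contrastive_loss

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "EncoderOutput", "LossBreakdown", "ReactionSample",
    "RetrosynthesisModel", "prepare_samples", "build_sample", "train",
    "save_checkpoint", "load_checkpoint", "ABLATIONS", "apply_ablation",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the reference full-scale setting,
    :meth:`small` is the desk-scale configuration used in the test suite."""

    uni_layers: int = 4
    dual_layers: int = 4
    dec_layers: int = 8
    d_model: int = 256
    heads: int = 8
    ffn_hidden: int = 512
    dropout: float = 0.3
    lr: float = 1e-3
    warmup_steps: int = 100      # linear LR warmup (optimizer steps)
    lr_decay: str = "cosine"     # "cosine" anneals to lr/100 over the run; "none" fixed
    ema_decay: float = 0.0       # Polyak averaging of weights for evaluation; 0 disables
    max_len: int = 256
    label_smoothing: float = 0.0
    tie_embedding: bool = False  # share the token embedding with the output layer
    gamma: float = 1.0
    similarity: str = "cosine"
    use_graph: bool = True
    use_cross_attention: bool = True
    use_captioner: bool = True
    use_class_token: bool = True
    conformer_policy: str = "topological_fallback"
    loss_weights: dict = field(default_factory=lambda: {
        "lm": 1.0, "ag": 1.0, "cl": 1.0, "captioner": 1.0})
    graph: GraphEncoderConfig = field(default_factory=GraphEncoderConfig)

    def __post_init__(self):
        if self.d_model % self.heads:
            raise ConfigError("d_model must be divisible by heads")
        if isinstance(self.graph, dict):
            self.graph = GraphEncoderConfig(**self.graph)

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        base = dict(uni_layers=2, dual_layers=2, dec_layers=2, d_model=64,
                    heads=4, ffn_hidden=128, dropout=0.1, max_len=160, lr=3e-3,
                    graph=GraphEncoderConfig(layers=2, dim=64, rw_steps=16))
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


ABLATIONS = {
    "transformer": dict(use_graph=False, use_cross_attention=False, use_captioner=False),
    "smiles-graph": dict(use_graph=True, use_cross_attention=False, use_captioner=False),
    "no-captioner": dict(use_graph=True, use_cross_attention=True, use_captioner=False),
    "full": dict(use_graph=True, use_cross_attention=True, use_captioner=True),
}


def apply_ablation(cfg: ModelConfig, name: str) -> ModelConfig:
    if name not in ABLATIONS:
        raise ConfigError(f"unknown ablation {name!r}; choose from {sorted(ABLATIONS)}")
    d = cfg.to_dict()
    d.update(ABLATIONS[name])
    return ModelConfig.from_dict(d)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class EncoderOutput:
    H_s: Tensor                       # L x d uni-view sequence embedding
    H: Tensor                         # L x d fused product representation
    rc: RCScores | None = None
    weighted: WeightedGraph | None = None


@dataclass
class LossBreakdown:
    lm: Tensor
    ag: Tensor
    cl: Tensor
    captioner: Tensor
    total: Tensor

    def to_floats(self) -> dict[str, float]:
        return {k: float(getattr(self, k).data) for k in
                ("lm", "ag", "cl", "captioner", "total")}


@dataclass
class ReactionSample:
    """One prepared training example (all model-facing strings are map-free)."""

    src_ids: np.ndarray               # product tokens (+ optional class token)
    tgt_ids: np.ndarray               # reactant tokens, no BOS/EOS
    graph: MolGraph
    labels: RCLabels
    align_pairs: list[tuple[int, int]]   # (decoder-input position, source position)
    product: str                      # canonical product SMILES
    reactants: str                    # canonical '.'-joined reactant SMILES
    class_label: int | None = None


# ---------------------------------------------------------------------------
# transformer layers
# ---------------------------------------------------------------------------

class _EncoderLayer(Module):
    def __init__(self, d, heads, hidden, rng, dropout):
        self.attn = MultiHeadAttention(d, heads, rng)
        self.ffn = FeedForward(d, hidden, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x, mask=None):
        xn = self.ln1(x)
        a, _ = self.attn(xn, xn, mask=mask, need_attn=False)
        x = x + self.drop(a)
        return x + self.drop(self.ffn(self.ln2(x)))


class _DualLayer(Module):
    """Self-attention, then graph fusion (cross-attention or concat), then FFN."""

    def __init__(self, d, heads, hidden, graph_dim, rng, dropout,
                 use_graph, use_cross):
        self.use_graph = use_graph
        self.use_cross = use_cross
        self.attn = MultiHeadAttention(d, heads, rng)
        if use_graph and use_cross:
            self.cross = MultiHeadAttention(d, heads, rng, kv_dim=graph_dim)
            self.ln_x = LayerNorm(d)
        elif use_graph:
            self.concat_proj = Linear(d + graph_dim, d, rng)
            self.ln_x = LayerNorm(d)
        self.ffn = FeedForward(d, hidden, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.drop = Dropout(dropout, rng)

    def __call__(self, z, H_w, mask=None):
        zn = self.ln1(z)
        a, _ = self.attn(zn, zn, mask=mask, need_attn=False)
        z = z + self.drop(a)
        if self.use_graph and self.use_cross:
            c, _ = self.cross(self.ln_x(z), H_w, need_attn=False)
            z = z + self.drop(c)
        elif self.use_graph:
            # graph context vector broadcast to every position, then projected
            g = H_w.mean(axis=0).reshape(1, -1)
            g_rep = Tensor(np.ones((z.shape[0], 1))) @ g
            z = z + self.drop(self.concat_proj(concatenate([self.ln_x(z), g_rep], axis=-1)))
        return z + self.drop(self.ffn(self.ln2(z)))


class _DecoderLayer(Module):
    def __init__(self, d, heads, hidden, rng, dropout):
        self.self_attn = MultiHeadAttention(d, heads, rng)
        self.cross = MultiHeadAttention(d, heads, rng)
        self.ffn = FeedForward(d, hidden, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ln3 = LayerNorm(d)
        self.drop = Dropout(dropout, rng)

    def __call__(self, y, H, causal_mask, need_attn=True):
        yn = self.ln1(y)
        a, _ = self.self_attn(yn, yn, mask=causal_mask, need_attn=False)
        y = y + self.drop(a)
        c, attn = self.cross(self.ln2(y), H, need_attn=need_attn)
        y = y + self.drop(c)
        return y + self.drop(self.ffn(self.ln3(y))), attn


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class RetrosynthesisModel(Module):
    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, rng: np.random.Generator):
        d, h, hid = cfg.d_model, cfg.heads, cfg.ffn_hidden
        self.cfg = cfg
        self.vocab = vocab
        self.embed = Embedding(len(vocab), d, rng)
        self.emb_drop = Dropout(cfg.dropout, rng)
        self.uni = [_EncoderLayer(d, h, hid, rng, cfg.dropout)
                    for _ in range(cfg.uni_layers)]
        gdim = cfg.graph.dim
        self.dual = [_DualLayer(d, h, hid, gdim, rng, cfg.dropout,
                                cfg.use_graph, cfg.use_cross_attention)
                     for _ in range(cfg.dual_layers)]
        if cfg.use_graph:
            self.graph_encoder = GraphEncoder(
                cfg.graph, chem_io.NODE_FEATURE_DIM, chem_io.EDGE_FEATURE_DIM, rng)
            self.captioner = Captioner(gdim, d, rng, gamma=cfg.gamma,
                                       similarity=cfg.similarity)
            self.fuse = Linear(2 * d, d, rng)
        self.dec = [_DecoderLayer(d, h, hid, rng, cfg.dropout)
                    for _ in range(cfg.dec_layers)]
        self.ln_enc = LayerNorm(d)       # final norms of the pre-LN stacks
        self.ln_dual = LayerNorm(d)
        self.ln_dec = LayerNorm(d)
        if cfg.tie_embedding:
            self.out_bias = Tensor(np.zeros(len(vocab)), requires_grad=True)
        else:
            self.out_proj = Linear(d, len(vocab), rng)
        self._pe_cache: dict[int, np.ndarray] = {}
        self._causal_cache: dict[int, np.ndarray] = {}
        self._scale = np.sqrt(d)

    # -- helpers --------------------------------------------------------------
    def _positions(self, L: int) -> np.ndarray:
        if L not in self._pe_cache:
            self._pe_cache[L] = sinusoidal_positions(L, self.cfg.d_model)
        return self._pe_cache[L]

    def _embed_seq(self, ids: np.ndarray) -> Tensor:
        if len(ids) > self.cfg.max_len:
            raise ValueError(f"sequence length {len(ids)} exceeds max_len {self.cfg.max_len}")
        x = (self.embed(ids) * self._scale).add_const(self._positions(len(ids)))
        return self.emb_drop(x)

    # -- core operations ------------------------------------------------------
    def uni_view_encode(self, ids: np.ndarray, pad_mask: np.ndarray | None = None) -> Tensor:
        """Standard transformer encoder stack over the token embeddings."""
        mask = None
        if pad_mask is not None:
            mask = np.broadcast_to(pad_mask[None, None, :],
                                   (1, len(ids), len(ids)))
        x = self._embed_seq(ids)
        for layer in self.uni:
            x = layer(x, mask=mask)
        return self.ln_enc(x)

    def dual_view_encode(self, H_s: Tensor, weighted: WeightedGraph | None,
                         pad_mask: np.ndarray | None = None) -> Tensor:
        mask = None
        if pad_mask is not None:
            L = H_s.shape[0]
            mask = np.broadcast_to(pad_mask[None, None, :], (1, L, L))
        z = H_s
        H_w = weighted.H_w if weighted is not None else None
        for layer in self.dual:
            z = layer(z, H_w, mask=mask)
        return self.ln_dual(z)

    def encode(self, ids: np.ndarray, graph: MolGraph | None,
               pad_mask: np.ndarray | None = None) -> EncoderOutput:
        H_s = self.uni_view_encode(ids, pad_mask)
        rc = None
        weighted = None
        if self.cfg.use_graph:
            if graph is None:
                raise ValueError("use_graph=True but no graph supplied")
            gemb, rc = self.graph_encoder(graph)
            if self.cfg.use_captioner:
                weighted = self.captioner.caption_weights(
                    gemb.H_g, H_s,
                    token_mask=pad_mask.astype(float) if pad_mask is not None else None)
            else:
                m = gemb.H_g.shape[0]
                weighted = WeightedGraph(w=Tensor(np.full(m, 1.0 / m)),
                                         H_w=gemb.H_g,
                                         H_hat=self.captioner.proj(gemb.H_g))
        z = self.dual_view_encode(H_s, weighted, pad_mask)
        if self.cfg.use_graph:
            H = self.fuse(concatenate([H_s, z], axis=-1))
        else:
            H = z
        return EncoderOutput(H_s=H_s, H=H, rc=rc, weighted=weighted)

    def decode(self, enc: EncoderOutput, dec_in: np.ndarray,
               collect_attn: bool = False):
        """Causal decoder over ``dec_in``; returns (logits, cross-attn maps)."""
        T = len(dec_in)
        y = self._embed_seq(dec_in)
        causal = self._causal_cache.get(T)
        if causal is None:
            causal = np.tril(np.ones((1, T, T), dtype=bool))
            self._causal_cache[T] = causal
        maps = []
        for layer in self.dec:
            y, attn = layer(y, enc.H, causal, need_attn=collect_attn)
            if collect_attn:
                maps.append(attn)
        y = self.ln_dec(y)
        if self.cfg.tie_embedding:
            logits = y @ self.embed.weight.swapaxes(0, 1) + self.out_bias
        else:
            logits = self.out_proj(y)
        return logits, maps

    def decode_step(self, enc: EncoderOutput, prefix: np.ndarray) -> np.ndarray:
        """Log-probabilities of the next token given a BOS-led prefix."""
        logits, _ = self.decode(enc, np.asarray(prefix, dtype=np.intp))
        return logits.log_softmax(axis=-1).data[-1]

    # -- losses ---------------------------------------------------------------
    def alignment_loss(self, attn_maps: list[Tensor],
                       align_pairs: list[tuple[int, int]]) -> Tensor:
        """Cross-entropy between averaged decoder cross-attention rows and
        the one-hot atom-map-derived token alignment."""
        if not align_pairs or not attn_maps:
            logger.warning("empty alignment: L_AG contributes 0")
            return Tensor(0.0)
        avg = attn_maps[0]
        for a in attn_maps[1:]:
            avg = avg + a
        avg = avg * (1.0 / len(attn_maps))
        rows = np.array([t for t, _ in align_pairs], dtype=np.intp)
        cols = np.array([s for _, s in align_pairs], dtype=np.intp)
        picked = avg[rows, cols]
        return -((picked + 1e-12).log()).mean()

    def total_loss(self, sample: ReactionSample) -> LossBreakdown:
        enc = self.encode(sample.src_ids, sample.graph)
        bos, eos = self.vocab.bos_id, self.vocab.eos_id
        dec_in = np.concatenate([[bos], sample.tgt_ids]).astype(np.intp)
        target = np.concatenate([sample.tgt_ids, [eos]]).astype(np.intp)
        logits, maps = self.decode(enc, dec_in, collect_attn=True)
        logp = logits.log_softmax(axis=-1)
        T = len(target)
        nll = -(logp[np.arange(T), target]).mean()
        if self.cfg.label_smoothing > 0:
            eps = self.cfg.label_smoothing
            nll = (1.0 - eps) * nll + eps * (-logp.mean())
        ag = self.alignment_loss(maps, sample.align_pairs)
        zero = Tensor(0.0)
        cl = rc_loss(enc.rc, sample.labels) if enc.rc is not None else zero
        rcap = (contrastive_loss(enc.weighted.H_hat, sample.labels, self.captioner.state)
                if self.cfg.use_captioner and enc.weighted is not None else zero)
        w = self.cfg.loss_weights
        total = w["lm"] * nll + w["ag"] * ag + w["cl"] * cl + w["captioner"] * rcap
        return LossBreakdown(lm=nll, ag=ag, cl=cl, captioner=rcap, total=total)


# ---------------------------------------------------------------------------
# sample preparation
# ---------------------------------------------------------------------------

def _write_with_order(rdmol: Chem.Mol, root: int = -1,
                      canonical: bool = True) -> tuple[str, list[int]]:
    """Write a map-free SMILES and the atom output order (output position ->
    original atom index)."""
    mol = Chem.Mol(rdmol)
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    smi = Chem.MolToSmiles(mol, canonical=canonical, rootedAtAtom=int(root))
    order = json.loads(mol.GetProp("_smilesAtomOutputOrder"))
    return smi, list(order)


def build_sample(rxn: Reaction, vocab: Vocabulary, cfg: ModelConfig,
                 product_root: int = -1) -> ReactionSample:
    """Prepare one reaction: rewrite both sides map-free (optionally rooted
    at ``product_root``), re-index RC labels and the atom-token alignment
    into the written order, featurize the product graph.

    """
    canonical = product_root < 0
    prod_smi, prod_order = _write_with_order(rxn.product.rdmol,
                                             root=product_root, canonical=canonical)
    prod_mol = parse_molecule(prod_smi)
    # position of each original atom in the rewritten product
    inv_prod = {orig: j for j, orig in enumerate(prod_order)}
    atom_map_new = {inv_prod[p]: ra for p, ra in rxn.atom_map.items()}
    relabel_rxn = Reaction(product=prod_mol, reactants=rxn.reactants,
                           class_label=rxn.class_label, atom_map=atom_map_new)
    labels = (chem_io.extract_reaction_center(relabel_rxn) if rxn.atom_map
              else RCLabels(atom_labels=np.zeros(prod_mol.num_atoms, dtype=np.int64),
                            bond_labels=np.zeros(prod_mol.rdmol.GetNumBonds(),
                                                 dtype=np.int64)))

    # reactant side: canonical writing per fragment.  Augmented (rooted)
    # product writings keep the canonical target so that every augmented
    # copy reinforces the same output string.
    reac_parts, reac_invs, offsets = [], {}, {}
    off = 0
    for i, mol in enumerate(rxn.reactants):
        smi, order = _write_with_order(mol.rdmol)
        reac_parts.append(smi)
        reac_invs[i] = {orig: j for j, orig in enumerate(order)}
        offsets[i] = off
        off += mol.num_atoms
    tgt_smi = ".".join(reac_parts)

    src_str = prod_smi
    if cfg.use_class_token and rxn.class_label is not None:
        src_str = f"[RX_{rxn.class_label}]" + src_str
    src_seq = tokenize(src_str)
    align_atoms_to_tokens(src_seq, prod_mol)
    tgt_seq = tokenize(tgt_smi)
    align_atoms_to_tokens(tgt_seq, parse_molecule(tgt_smi))

    align_pairs = []
    for p_new, (ri, ai) in atom_map_new.items():
        comb_idx = offsets[ri] + reac_invs[ri][ai]
        src_pos = src_seq.atom_to_token[p_new]
        tgt_pos = tgt_seq.atom_to_token[comb_idx] + 1   # +1: BOS shifts decoder input
        align_pairs.append((tgt_pos, src_pos))

    graph = (build_graph(prod_mol, conformer_policy=cfg.conformer_policy,
                         rw_steps=cfg.graph.rw_steps,
                         rbf_centers=cfg.graph.rbf_centers)
             if cfg.use_graph else
             build_graph(prod_mol, conformer_policy="topological_fallback",
                         rw_steps=cfg.graph.rw_steps,
                         rbf_centers=cfg.graph.rbf_centers))
    return ReactionSample(
        src_ids=np.asarray(vocab.encode(src_seq.tokens), dtype=np.intp),
        tgt_ids=np.asarray(vocab.encode(tgt_seq.tokens), dtype=np.intp),
        graph=graph, labels=labels, align_pairs=align_pairs,
        product=canonicalize(prod_smi), reactants=".".join(
            sorted(canonicalize(p) for p in reac_parts)),
        class_label=rxn.class_label)


def prepare_samples(reactions: list[Reaction], vocab: Vocabulary,
                    cfg: ModelConfig, augment: int = 0,
                    seed: int = 0) -> list[ReactionSample]:
    """Build model-ready samples; ``augment`` adds that many extra rooted
    product writings per reaction (root-enumeration augmentation)."""
    rng = np.random.default_rng(seed)
    out = []
    for rxn in reactions:
        out.append(build_sample(rxn, vocab, cfg))
        if augment > 0:
            n_atoms = rxn.product.num_atoms
            roots = rng.choice(n_atoms, size=min(augment, n_atoms), replace=False)
            for r in roots:
                out.append(build_sample(rxn, vocab, cfg, product_root=int(r)))
    return out


def vocabulary_from_reactions(reactions: list[Reaction]) -> Vocabulary:
    """Vocabulary over the canonical writings the model will actually see
    (product strings and '.'-joined reactant strings)."""
    smis = []
    for rxn in reactions:
        smi, _ = _write_with_order(rxn.product.rdmol)
        smis.append(smi)
        smis.append(".".join(_write_with_order(mol.rdmol)[0]
                             for mol in rxn.reactants))
    return Vocabulary.build(smis)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: RetrosynthesisModel, optimizer: Adam,
                    epoch: int, rng: np.random.Generator) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "model.npz", **model.state_dict())
    opt_state = optimizer.state_dict()
    np.savez(path / "optim.npz",
             **{f"m::{k}": v for k, v in opt_state["m"].items()},
             **{f"v::{k}": v for k, v in opt_state["v"].items()})
    model.vocab.save(path / "vocab.txt")
    meta = {"epoch": epoch, "t": opt_state["t"],
            "config": model.cfg.to_dict(),
            "rng_state": rng.bit_generator.state}
    (path / "meta.json").write_text(json.dumps(meta, default=str, indent=1))


def load_checkpoint(path) -> tuple[RetrosynthesisModel, Adam, int, np.random.Generator]:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    cfg = ModelConfig.from_dict(meta["config"])
    vocab = Vocabulary.load(path / "vocab.txt")
    model = RetrosynthesisModel(cfg, vocab, np.random.default_rng(0))
    with np.load(path / "model.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    with np.load(path / "optim.npz") as data:
        state = {"t": meta["t"], "m": {}, "v": {}}
        for k in data.files:
            kind, name = k.split("::", 1)
            state[kind][name] = data[k]
    optimizer.load_state_dict(state)
    rng = np.random.default_rng(0)
    st = meta["rng_state"]
    st["state"]["state"] = int(st["state"]["state"])
    st["state"]["inc"] = int(st["state"]["inc"])
    rng.bit_generator.state = st
    return model, optimizer, int(meta["epoch"]), rng


def train(samples: list[ReactionSample], cfg: ModelConfig, vocab: Vocabulary,
          seed: int, out_dir=None, epochs: int = 10, batch_size: int = 4,
          resume_from=None, callback=None) -> RetrosynthesisModel:
    """Adam training with gradient accumulation over ``batch_size`` samples.

    Deterministic given (samples, cfg, vocab, seed); logs a per-epoch
    :class:`LossBreakdown` to ``<out_dir>/metrics.csv`` and writes a
    checkpoint directory when ``out_dir`` is given.  Aborts on divergence
    (non-finite loss).
    """
    if not samples:
        raise ValueError("empty training set")
    if resume_from is not None:
        model, optimizer, start_epoch, rng = load_checkpoint(resume_from)
    else:
        ss = np.random.SeedSequence(seed)
        init_rng, rng = (np.random.default_rng(c) for c in ss.spawn(2))
        model = RetrosynthesisModel(cfg, vocab, init_rng)
        optimizer = Adam(model.parameters(), lr=cfg.lr)
        start_epoch = 0
    # dropout draws from the run rng so resumed runs replay the same stream
    _rebind_dropout_rng(model, rng)
    model.set_training(True)

    metrics_path = Path(out_dir) / "metrics.csv" if out_dir is not None else None
    if metrics_path is not None:
        metrics_path.parent.mkdir(parents=True, exist_ok=True)
        if start_epoch == 0 or not metrics_path.exists():
            metrics_path.write_text("epoch,lm,ag,cl,captioner,total\n")

    n = len(samples)
    steps_per_epoch = int(np.ceil(n / batch_size))
    total_steps = (start_epoch + epochs) * steps_per_epoch
    params = model.parameters()
    ema = ({k: p.data.copy() for k, p in params.items()}
           if cfg.ema_decay > 0 else None)
    for epoch in range(start_epoch, start_epoch + epochs):
        order = rng.permutation(n)
        sums = dict.fromkeys(("lm", "ag", "cl", "captioner", "total"), 0.0)
        optimizer.zero_grad()
        pending = 0
        for pos, idx in enumerate(order):
            breakdown = model.total_loss(samples[idx])
            tot = float(breakdown.total.data)
            if not np.isfinite(tot):
                raise FloatingPointError(
                    f"diverged at epoch {epoch} sample {idx}: loss={tot}")
            (breakdown.total * (1.0 / batch_size)).backward()
            pending += 1
            for k, v in breakdown.to_floats().items():
                sums[k] += v
            if pending == batch_size or pos == n - 1:
                optimizer.lr = _lr_at(cfg, optimizer.t + 1, total_steps)
                optimizer.step()
                optimizer.zero_grad()
                pending = 0
                if ema is not None:
                    d = min(cfg.ema_decay, (1 + optimizer.t) / (10 + optimizer.t))
                    for k, p in params.items():
                        ema[k] = d * ema[k] + (1.0 - d) * p.data
        means = {k: v / n for k, v in sums.items()}
        logger.info("epoch %d: %s", epoch,
                    " ".join(f"{k}={v:.4f}" for k, v in means.items()))
        if metrics_path is not None:
            with open(metrics_path, "a") as fh:
                fh.write(f"{epoch},{means['lm']:.6f},{means['ag']:.6f},"
                         f"{means['cl']:.6f},{means['captioner']:.6f},"
                         f"{means['total']:.6f}\n")
        if callback is not None:
            callback(epoch, means, model)
    model.set_training(False)
    if ema is not None:
        model.load_state_dict(ema)
    if out_dir is not None:
        save_checkpoint(out_dir, model, optimizer, start_epoch + epochs, rng)
    return model


def _lr_at(cfg: ModelConfig, step: int, total_steps: int) -> float:
    """Linear warmup then (optionally) cosine annealing to lr/100."""
    lr = cfg.lr
    if cfg.warmup_steps > 0 and step < cfg.warmup_steps:
        return lr * step / cfg.warmup_steps
    if cfg.lr_decay == "cosine" and total_steps > cfg.warmup_steps:
        frac = (step - cfg.warmup_steps) / max(1, total_steps - cfg.warmup_steps)
        frac = min(1.0, frac)
        floor = lr / 100.0
        return floor + 0.5 * (lr - floor) * (1.0 + np.cos(np.pi * frac))
    return lr


def _rebind_dropout_rng(module: Module, rng: np.random.Generator) -> None:
    for val in vars(module).values():
        if isinstance(val, Dropout):
            val.rng = rng
        elif isinstance(val, Module):
            _rebind_dropout_rng(val, rng)
        elif isinstance(val, (list, tuple)):
            for item in val:
                if isinstance(item, Module):
                    _rebind_dropout_rng(item, rng)
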