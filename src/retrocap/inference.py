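"""Decoding and evaluation: beam search, top-k exact-match / validity
metrics, and greedy iterative route planning against a buyable stock."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import build_graph, canonicalize, parse_molecule, tokenize
from .errors import DataError, ParseError
from .nn import no_grad
from .seq_model import EncoderOutput, RetrosynthesisModel

__all__ = [
    "BeamResult", "RouteNode", "encode_product", "beam_search",
    "topk_exact_match", "topk_validity", "plan_route", "route_to_text",
    "route_to_dict", "canonical_reactant_key",
]


@dataclass
class BeamResult:
    """Ranked candidate reactant strings with total log-probabilities.

    Candidates are sorted by descending (length-normalized) score and
    deduplicated by canonical reactant multiset, keeping the best-scoring
    writing of each candidate set."""

    candidates: list[tuple[str, float]]
    k: int
    incomplete: bool = False

    def smiles(self) -> list[str]:
        return [s for s, _ in self.candidates]


def canonical_reactant_key(smiles: str) -> tuple[str, ...] | None:
    """Order-insensitive canonical key of a '.'-joined reactant string;
    None when any part fails to parse."""
    try:
        return tuple(sorted(canonicalize(p) for p in smiles.split(".")))
    except ParseError:
        return None


def encode_product(model: RetrosynthesisModel, product_smiles: str,
                   class_label: int | None = None) -> EncoderOutput:
    """Canonicalize, tokenize and featurize a product, then run the encoder."""
    cfg = model.cfg
    canon = canonicalize(product_smiles)
    src = canon
    if cfg.use_class_token and class_label is not None:
        src = f"[RX_{class_label}]" + src
    ids = np.asarray(model.vocab.encode(tokenize(src).tokens), dtype=np.intp)
    graph = None
    if cfg.use_graph:
        graph = build_graph(parse_molecule(canon),
                            conformer_policy=cfg.conformer_policy,
                            rw_steps=cfg.graph.rw_steps,
                            rbf_centers=cfg.graph.rbf_centers)
    with no_grad():
        return model.encode(ids, graph)


def beam_decode(step_fn, bos: int, eos: int, width: int, max_len: int,
                banned: tuple[int, ...] = (),
                length_normalize: bool = True) -> tuple[list[tuple[list[int], float]], bool]:
    """Core beam search over ``step_fn(prefix) -> next-token log-probs``.

    Returns (hypotheses, incomplete): each hypothesis is the token list
    (BOS/EOS included for finished ones) with its length-normalized score,
    sorted best-first.  ``incomplete`` is True when no hypothesis reached
    EOS within ``max_len``.
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")

    def norm(logp: float, length: int) -> float:
        return logp / max(length, 1) if length_normalize else logp

    alive: list[tuple[list[int], float]] = [([bos], 0.0)]
    finished: list[tuple[list[int], float]] = []
    for _ in range(max_len):
        if not alive:
            break
        expansions: list[tuple[list[int], float]] = []
        for prefix, logp in alive:
            step_logp = np.array(step_fn(prefix), dtype=np.float64)
            for tok in banned:
                step_logp[tok] = -np.inf
            top = np.argsort(step_logp)[::-1][:width]
            for tok in top:
                expansions.append((prefix + [int(tok)], logp + float(step_logp[tok])))
        expansions.sort(key=lambda h: norm(h[1], len(h[0]) - 1), reverse=True)
        alive = []
        for prefix, logp in expansions:
            if prefix[-1] == eos:
                finished.append((prefix, logp))
            elif len(alive) < width:
                alive.append((prefix, logp))
            if len(finished) >= width and len(alive) >= width:
                break
    incomplete = not finished and bool(alive)
    pool = finished if finished else alive
    scored = sorted(((prefix, norm(logp, len(prefix) - 1)) for prefix, logp in pool),
                    key=lambda h: h[1], reverse=True)
    return scored, incomplete


def beam_search(model: RetrosynthesisModel, product_smiles: str,
                width: int = 10, max_len: int = 120,
                class_label: int | None = None,
                length_normalize: bool = True) -> BeamResult:
    """Length-normalized beam search over the decoder.

    EOS terminates a hypothesis; ``width`` = 1 reduces to greedy argmax
    rollout.  Hypotheses that never reach EOS within ``max_len`` are
    returned flagged incomplete.
    """
    vocab = model.vocab
    model.set_training(False)
    enc = encode_product(model, product_smiles, class_label=class_label)
    bos, eos, pad = vocab.bos_id, vocab.eos_id, vocab.pad_id
    with no_grad():
        hyps, incomplete = beam_decode(
            lambda prefix: model.decode_step(enc, np.asarray(prefix, dtype=np.intp)),
            bos=bos, eos=eos, width=width, max_len=max_len,
            banned=(pad,), length_normalize=length_normalize)
    scored = [("".join(vocab.decode([t for t in prefix if t not in (bos, eos)])),
               score) for prefix, score in hyps]

    best: dict[tuple | str, tuple[str, float]] = {}
    order: list[tuple | str] = []
    for smi, score in scored:
        key = canonical_reactant_key(smi)
        dict_key = key if key is not None else ("__invalid__", smi)
        if dict_key not in best:
            best[dict_key] = (smi, score)
            order.append(dict_key)
    candidates = [best[k] for k in order][:width]
    return BeamResult(candidates=candidates, k=width, incomplete=incomplete)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def topk_exact_match(preds: list[BeamResult], truths: list[str],
                     ks: list[int]) -> dict[int, float]:
    """Percentage of reactions whose true reactant set appears within the
    first k candidates (canonical, reactant-order-insensitive)."""
    if len(preds) != len(truths):
        raise DataError(f"{len(preds)} predictions vs {len(truths)} truths")
    truth_keys = []
    for t in truths:
        key = canonical_reactant_key(t)
        if key is None:
            raise DataError(f"unparseable ground-truth reactants: {t!r}")
        truth_keys.append(key)
    out = {}
    for k in ks:
        hits = 0
        for pred, truth in zip(preds, truth_keys):
            keys = [canonical_reactant_key(s) for s in pred.smiles()[:k]]
            hits += any(key == truth for key in keys if key is not None)
        out[k] = 100.0 * hits / len(preds) if preds else 0.0
    return out


def topk_validity(preds: list[BeamResult], ks: list[int]) -> dict[int, float]:
    """Percentage of the N x k candidate slots holding parseable SMILES;
    slots beyond a short beam count as invalid."""
    out = {}
    n = len(preds)
    for k in ks:
        valid = 0
        for pred in preds:
            for smi in pred.smiles()[:k]:
                if all(Chem.MolFromSmiles(p) is not None for p in smi.split(".")):
                    valid += 1
        out[k] = 100.0 * valid / (n * k) if n else 0.0
    return out


# ---------------------------------------------------------------------------
# route planning
# ---------------------------------------------------------------------------

@dataclass
class RouteNode:
    smiles: str                      # canonical
    in_stock: bool
    terminal: bool = False           # expansion stopped without stock hit
    reaction: str | None = None      # predicted reactant string used
    children: list["RouteNode"] = field(default_factory=list)

    @property
    def solved(self) -> bool:
        if self.in_stock:
            return True
        if not self.children:
            return False
        return all(c.solved for c in self.children)


def plan_route(model: RetrosynthesisModel, target: str, stock: set[str],
               max_depth: int = 6, class_label: int | None = None,
               max_len: int = 120) -> RouteNode:
    """Greedy iterative retrosynthesis: expand every non-stock molecule
    with the model's top-1 prediction until all leaves are buyable or
    ``max_depth`` is exhausted.  Molecules already in stock are never
    expanded; revisited molecules reuse their planned subtree."""
    stock_canon = {canonicalize(s) for s in stock}
    memo: dict[str, RouteNode] = {}

    def expand(smiles: str, depth: int) -> RouteNode:
        canon = canonicalize(smiles)
        if canon in memo:
            return memo[canon]
        node = RouteNode(smiles=canon, in_stock=canon in stock_canon)
        memo[canon] = node
        if node.in_stock:
            return node
        if depth >= max_depth:
            node.terminal = True
            return node
        beam = beam_search(model, canon, width=1, max_len=max_len,
                           class_label=class_label)
        if not beam.candidates:
            node.terminal = True
            return node
        pred = beam.candidates[0][0]
        parts = []
        for p in pred.split("."):
            if Chem.MolFromSmiles(p) is None:
                node.terminal = True
                return node
            parts.append(canonicalize(p))
        if set(parts) == {canon}:          # no-progress guard
            node.terminal = True
            return node
        node.reaction = pred
        node.children = [expand(p, depth + 1) for p in parts]
        return node

    return expand(target, 0)


def route_to_dict(node: RouteNode) -> dict:
    return {
        "smiles": node.smiles,
        "in_stock": node.in_stock,
        "terminal": node.terminal,
        "solved": node.solved,
        "reaction": node.reaction,
        "children": [route_to_dict(c) for c in node.children],
    }


def route_to_text(node: RouteNode, indent: int = 0) -> str:
    tag = " [stock]" if node.in_stock else (" [terminal]" if node.terminal else "")
    lines = ["  " * indent + node.smiles + tag]
    for c in node.children:
        lines.append(route_to_text(c, indent + 1))
    return "\n".join(lines)


def route_depth(node: RouteNode) -> int:
    if not node.children:
        return 0
    return 1 + max(route_depth(c) for c in node.children)


def save_route(node: RouteNode, path) -> None:
    with open(path, "w") as fh:
        json.dump(route_to_dict(node), fh, indent=1)
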