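"""Reaction SMILES I/O: parsing, canonicalization, tokenization, alignment,
reaction-center labelling, graph featurization and root-enumeration
augmentation.

Conventions
-----------
* One reaction per line, ``reactants>>product``; multiple reactants joined
  by ``.``; an optional leading class token ``[RX_k]`` (k = 1..10).
* Atom-map numbers pair product atoms with their reactant counterparts.
  They are supervision only: labels and alignments are derived from them,
  after which maps are stripped from everything the model sees.
* Hydrogens are implicit; all indices are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .errors import (
    AlignmentError,
    ConformerError,
    IntegrityError,
    LabelingError,
    ParseError,
    TokenizationError,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule", "Reaction", "RCLabels", "TokenSequence", "Vocabulary", "MolGraph",
    "parse_molecule", "parse_reaction", "canonicalize", "tokenize", "detokenize",
    "extract_reaction_center", "build_graph", "augment_roots",
    "align_atoms_to_tokens", "rbf_expand", "read_reaction_file",
    "write_reaction_file", "CLASS_TOKENS",
]

CLASS_TOKENS = tuple(f"[RX_{k}]" for k in range(1, 11))
_CLASS_RE = re.compile(r"^\[RX_(\d+)\]")

# The community-standard SMILES token pattern: bracket atoms are single
# tokens, Cl/Br are two-character, ring closures may use %nn.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|N|O|S|P|F|I|B|C|b|c|n|o|s|p|"
    r"\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)

# Tokens that spell an atom: any bracket token except class tokens, or a
# bare organic-subset element symbol.
_ATOM_TOKEN_RE = re.compile(r"^(\[(?!RX_)[^\]]+\]|Br|Cl|N|O|S|P|F|I|B|C|b|c|n|o|s|p)$")

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")  # + "other" slot


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Molecule:
    """A single molecule with its RDKit mol and raw SMILES writing."""

    smiles: str
    rdmol: Chem.Mol

    @property
    def num_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def atoms(self) -> list[tuple]:
        """(element, charge, degree, numH, aromatic, in_ring, map or None)."""
        out = []
        for a in self.rdmol.GetAtoms():
            out.append((a.GetSymbol(), a.GetFormalCharge(), a.GetDegree(),
                        a.GetTotalNumHs(), a.GetIsAromatic(), a.IsInRing(),
                        a.GetAtomMapNum() or None))
        return out

    @property
    def bonds(self) -> list[tuple]:
        """(i, j, bond order as double, conjugated, in_ring)."""
        out = []
        for b in self.rdmol.GetBonds():
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                        b.GetBondTypeAsDouble(), b.GetIsConjugated(), b.IsInRing()))
        return out

    def map_numbers(self) -> dict[int, int]:
        """atom index -> map number, for mapped atoms only."""
        return {a.GetIdx(): a.GetAtomMapNum()
                for a in self.rdmol.GetAtoms() if a.GetAtomMapNum()}


@dataclass
class Reaction:
    """One retrosynthesis training unit: product -> reactant set."""

    product: Molecule
    reactants: list[Molecule]
    class_label: int | None
    #: product atom index -> (reactant index, reactant atom index)
    atom_map: dict[int, tuple[int, int]]
    raw: str = ""

    def reactants_smiles(self) -> str:
        return ".".join(m.smiles for m in self.reactants)


@dataclass
class RCLabels:
    """Binary reaction-center indicators over product atoms and bonds."""

    atom_labels: np.ndarray
    bond_labels: np.ndarray


@dataclass
class TokenSequence:
    tokens: list[str]
    ids: list[int] = field(default_factory=list)
    #: product atom index -> token position (atom tokens only)
    atom_to_token: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tokens)


class Vocabulary:
    """Dense token -> index map with the special and class tokens built in."""

    PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
    SPECIALS = (PAD, BOS, EOS, UNK)

    def __init__(self, tokens: list[str] | None = None):
        self._tok2id: dict[str, int] = {}
        # '.' is structural (reactant separator) and must always tokenize
        for t in self.SPECIALS + CLASS_TOKENS + (".",):
            self._tok2id.setdefault(t, len(self._tok2id))
        for t in tokens or ():
            self._tok2id.setdefault(t, len(self._tok2id))
        self._id2tok = {i: t for t, i in self._tok2id.items()}

    def __len__(self) -> int:
        return len(self._tok2id)

    def __contains__(self, token: str) -> bool:
        return token in self._tok2id

    @property
    def pad_id(self) -> int:
        return self._tok2id[self.PAD]

    @property
    def bos_id(self) -> int:
        return self._tok2id[self.BOS]

    @property
    def eos_id(self) -> int:
        return self._tok2id[self.EOS]

    @property
    def unk_id(self) -> int:
        return self._tok2id[self.UNK]

    def encode(self, tokens: list[str]) -> list[int]:
        unk = self.unk_id
        return [self._tok2id.get(t, unk) for t in tokens]

    def decode(self, ids) -> list[str]:
        return [self._id2tok[int(i)] for i in ids]

    @classmethod
    def build(cls, smiles_iter) -> "Vocabulary":
        seen: dict[str, None] = {}
        for smi in smiles_iter:
            for t in tokenize(smi).tokens:
                seen.setdefault(t, None)
        return cls(sorted(seen))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(self._id2tok[i] + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path) as fh:
            toks = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        vocab = cls.__new__(cls)
        vocab._tok2id = {t: i for i, t in enumerate(toks)}
        if len(vocab._tok2id) != len(toks):
            raise IntegrityError("duplicate token in vocabulary file")
        vocab._id2tok = {i: t for t, i in vocab._tok2id.items()}
        return vocab


@dataclass
class MolGraph:
    """Dense feature view of one molecule for the graph encoder.

    Each undirected bond appears as two consecutive directed edges with
    identical initial features.
    """

    node_features: np.ndarray        # m x d_v
    edge_features: np.ndarray        # n x d_e  (n = 2 * bonds)
    edge_index: np.ndarray           # n x 2    (src, dst)
    adjacency: np.ndarray            # m x m binary
    pe_init: np.ndarray              # m x k random-walk features
    rbf_dist: np.ndarray             # n x B
    used_3d: bool = False            # whether a 3D conformer backed rbf_dist

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[0]


# ---------------------------------------------------------------------------
# parsing / canonicalization / tokenization
# ---------------------------------------------------------------------------

def parse_molecule(smiles: str) -> Molecule:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES fragment: {smiles!r}")
    return Molecule(smiles=smiles, rdmol=mol)


def _check_unique_maps(mols: list[Molecule], side: str) -> dict[int, tuple[int, int]]:
    seen: dict[int, tuple[int, int]] = {}
    for mi, mol in enumerate(mols):
        for ai, num in mol.map_numbers().items():
            if num in seen:
                raise IntegrityError(f"duplicate atom-map number {num} on {side} side")
            seen[num] = (mi, ai)
    return seen


def parse_reaction(line: str) -> Reaction:
    """Parse one ``[RX_k]reactants>>product`` line into a :class:`Reaction`."""
    raw = line.strip()
    text = raw
    class_label = None
    m = _CLASS_RE.match(text)
    if m:
        class_label = int(m.group(1))
        text = text[m.end():]
    if ">>" not in text:
        raise ParseError(f"missing '>>' in reaction line: {raw!r}")
    lhs, rhs = text.split(">>", 1)
    if not lhs or not rhs:
        raise ParseError(f"empty reaction side in: {raw!r}")
    reactants = [parse_molecule(s) for s in lhs.split(".")]
    product = parse_molecule(rhs)
    prod_maps = _check_unique_maps([product], "product")
    reac_maps = _check_unique_maps(reactants, "reactant")
    atom_map: dict[int, tuple[int, int]] = {}
    for num, (_, pidx) in prod_maps.items():
        if num in reac_maps:
            ri, ai = reac_maps[num]
            p_sym = product.rdmol.GetAtomWithIdx(pidx).GetSymbol()
            r_sym = reactants[ri].rdmol.GetAtomWithIdx(ai).GetSymbol()
            if p_sym != r_sym:
                raise IntegrityError(
                    f"map {num} pairs different elements {p_sym}/{r_sym}")
            atom_map[pidx] = (ri, ai)
    return Reaction(product=product, reactants=reactants,
                    class_label=class_label, atom_map=atom_map, raw=raw)


def canonicalize(smiles: str) -> str:
    """Canonical SMILES with atom maps stripped; idempotent."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def tokenize(smiles: str) -> TokenSequence:
    """Split a SMILES string into standard tokens; join(tokens) == input."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"no token pattern matches {smiles[pos]!r} at position {pos} in {smiles!r}")
        tokens.append(m.group(0))
        pos = m.end()
    return TokenSequence(tokens=tokens)


def detokenize(seq: TokenSequence) -> str:
    return "".join(seq.tokens)


def is_atom_token(token: str) -> bool:
    return _ATOM_TOKEN_RE.match(token) is not None


# ---------------------------------------------------------------------------
# reaction-center labels
# ---------------------------------------------------------------------------

def extract_reaction_center(rxn: Reaction) -> RCLabels:
    """Derive binary reaction-center labels on the product from atom maps.

    A product bond is a center iff its mapped atom pair is not bonded with
    the same order on the reactant side, or either endpoint is unmapped.
    An atom is a center iff it is incident to a center bond or its total
    hydrogen count / formal charge differs from its mapped reactant atom.
    """
    if not rxn.atom_map:
        raise LabelingError("cannot derive reaction centers without atom maps")
    prod = rxn.product.rdmol
    m = prod.GetNumAtoms()
    nb = prod.GetNumBonds()
    atom_labels = np.zeros(m, dtype=np.int64)
    bond_labels = np.zeros(nb, dtype=np.int64)

    # reactant bond orders keyed by (reactant idx, atom idx) pairs
    reac_bonds: dict[tuple, float] = {}
    for ri, mol in enumerate(rxn.reactants):
        for b in mol.rdmol.GetBonds():
            key = frozenset(((ri, b.GetBeginAtomIdx()), (ri, b.GetEndAtomIdx())))
            reac_bonds[key] = b.GetBondTypeAsDouble()

    for bi, b in enumerate(prod.GetBonds()):
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in rxn.atom_map or j not in rxn.atom_map:
            bond_labels[bi] = 1
            continue
        key = frozenset((rxn.atom_map[i], rxn.atom_map[j]))
        if reac_bonds.get(key) != b.GetBondTypeAsDouble():
            bond_labels[bi] = 1
        if bond_labels[bi]:
            atom_labels[i] = atom_labels[j] = 1

    for bi, b in enumerate(prod.GetBonds()):
        if bond_labels[bi]:
            atom_labels[b.GetBeginAtomIdx()] = 1
            atom_labels[b.GetEndAtomIdx()] = 1

    for pi, (ri, ai) in rxn.atom_map.items():
        pa = prod.GetAtomWithIdx(pi)
        ra = rxn.reactants[ri].rdmol.GetAtomWithIdx(ai)
        if (pa.GetTotalNumHs() != ra.GetTotalNumHs()
                or pa.GetFormalCharge() != ra.GetFormalCharge()):
            atom_labels[pi] = 1

    return RCLabels(atom_labels=atom_labels, bond_labels=bond_labels)


# ---------------------------------------------------------------------------
# graph featurization
# ---------------------------------------------------------------------------

def rbf_expand(dist: np.ndarray, n_centers: int = 20,
               d_min: float = 0.0, d_max: float = 6.0,
               width: float | None = None) -> np.ndarray:
    """Gaussian radial-basis expansion of distances.

    Centers are uniformly spaced on [d_min, d_max]; the width defaults to
    the center spacing.  A distance exactly at a center with that center's
    component evaluates to exp(0) = 1.
    """
    centers = np.linspace(d_min, d_max, n_centers)
    if width is None:
        width = centers[1] - centers[0] if n_centers > 1 else 1.0
    d = np.asarray(dist, dtype=np.float64)[..., None]
    return np.exp(-((d - centers) ** 2) / (2.0 * width ** 2))


@lru_cache(maxsize=4096)
def _conformer_distances(canonical: str) -> tuple[np.ndarray | None, bool]:
    """Heavy-atom pairwise distances from an MMFF-optimized 3D conformer.

    Returns (matrix, used_3d); matrix is None when embedding failed.
    Cached per canonical SMILES — conformer generation dominates
    featurization cost otherwise.
    """
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        return None, False
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = 0xF00D
    try:
        if AllChem.EmbedMolecule(molh, params) != 0:
            return None, False
        AllChem.MMFFOptimizeMolecule(molh)
    except Exception:
        return None, False
    conf = molh.GetConformer()
    pos = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff ** 2).sum(-1)), True


def _atom_feature(atom: Chem.Atom) -> np.ndarray:
    sym = atom.GetSymbol()
    el = np.zeros(len(ELEMENTS) + 1)
    el[ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)] = 1.0
    deg = np.zeros(6)
    deg[min(atom.GetDegree(), 5)] = 1.0
    nh = np.zeros(5)
    nh[min(atom.GetTotalNumHs(), 4)] = 1.0
    tail = np.array([atom.GetFormalCharge(),
                     float(atom.GetIsAromatic()),
                     float(atom.IsInRing())])
    return np.concatenate([el, deg, nh, tail])


_BOND_ORDERS = (1.0, 2.0, 3.0, 1.5)


def _bond_feature(bond: Chem.Bond) -> np.ndarray:
    order = np.zeros(len(_BOND_ORDERS) + 1)
    o = bond.GetBondTypeAsDouble()
    order[_BOND_ORDERS.index(o) if o in _BOND_ORDERS else len(_BOND_ORDERS)] = 1.0
    return np.concatenate([order, [float(bond.GetIsConjugated()),
                                   float(bond.IsInRing())]])


NODE_FEATURE_DIM = len(ELEMENTS) + 1 + 6 + 5 + 3
EDGE_FEATURE_DIM = len(_BOND_ORDERS) + 1 + 2


def build_graph(mol: Molecule, conformer_policy: str = "topological_fallback",
                rw_steps: int = 20, rbf_centers: int = 20) -> MolGraph:
    """Featurize one molecule for the graph encoder.

    ``conformer_policy``:
      * ``embed3d`` — require a force-field-optimized 3D conformer; raise
        :class:`ConformerError` if embedding fails.
      * ``topological_fallback`` — try 3D; on failure use graph
        shortest-path lengths as distances (deterministic).
    """
    from .graph_encoder import random_walk_pe  # pure function, no cycle at import

    if conformer_policy not in ("embed3d", "topological_fallback"):
        raise ValueError(f"unknown conformer policy: {conformer_policy!r}")
    rd = mol.rdmol
    m = rd.GetNumAtoms()
    node_features = np.array([_atom_feature(a) for a in rd.GetAtoms()]) \
        if m else np.zeros((0, NODE_FEATURE_DIM))

    adjacency = np.zeros((m, m))
    src, dst, efeats = [], [], []
    for b in rd.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adjacency[i, j] = adjacency[j, i] = 1.0
        f = _bond_feature(b)
        src += [i, j]
        dst += [j, i]
        efeats += [f, f]
    edge_index = (np.array([src, dst]).T if src
                  else np.zeros((0, 2), dtype=np.intp)).astype(np.intp)
    edge_features = np.array(efeats) if efeats else np.zeros((0, EDGE_FEATURE_DIM))

    dist, used_3d = _conformer_distances(canonicalize(mol.smiles)) if m > 1 else (None, False)
    if dist is None or dist.shape[0] != m:
        if conformer_policy == "embed3d" and m > 1:
            raise ConformerError(f"3D embedding failed for {mol.smiles!r}")
        dist = Chem.GetDistanceMatrix(rd) if m else np.zeros((0, 0))
        used_3d = False
    bond_d = np.array([dist[i, j] for i, j in edge_index]) if len(edge_index) else np.zeros(0)
    rbf_dist = rbf_expand(bond_d, n_centers=rbf_centers) if len(edge_index) \
        else np.zeros((0, rbf_centers))

    pe_init = random_walk_pe(adjacency, rw_steps)
    return MolGraph(node_features=node_features, edge_features=edge_features,
                    edge_index=edge_index, adjacency=adjacency,
                    pe_init=pe_init, rbf_dist=rbf_dist, used_3d=used_3d)


# ---------------------------------------------------------------------------
# augmentation / alignment
# ---------------------------------------------------------------------------

def augment_roots(smiles: str, count: int, seed: int) -> list[str]:
    """Up to ``count`` SMILES writings of one molecule rooted at different
    atoms, all canonicalizing identically.  The canonical form comes first;
    fewer strings are returned when symmetry collapses rooted writings."""
    if count < 1:
        raise ValueError("count must be >= 1")
    canon = canonicalize(smiles)
    out = [canon]
    if count == 1:
        return out
    mol = Chem.MolFromSmiles(canon)
    rng = np.random.default_rng(seed)
    order = rng.permutation(mol.GetNumAtoms())
    seen = {canon}
    for root in order:
        s = Chem.MolToSmiles(mol, canonical=False, rootedAtAtom=int(root))
        if s not in seen:
            seen.add(s)
            out.append(s)
            if len(out) == count:
                break
    return out


def align_atoms_to_tokens(seq: TokenSequence, mol: Molecule) -> TokenSequence:
    """Map the i-th atom of the left-to-right SMILES atom scan to the token
    position spelling it.  Requires ``seq`` to be tokenized from a SMILES
    writing of ``mol`` (atom counts must agree)."""
    positions = [p for p, t in enumerate(seq.tokens) if is_atom_token(t)]
    if len(positions) != mol.num_atoms:
        raise AlignmentError(
            f"{len(positions)} atom tokens vs {mol.num_atoms} atoms in molecule")
    seq.atom_to_token = {i: p for i, p in enumerate(positions)}
    return seq


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_reaction_file(path) -> list[Reaction]:
    """Read a UTF-8 reaction file (one reaction per line, '#' comments)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.append(parse_reaction(line))
            except (ParseError, IntegrityError) as exc:
                raise type(exc)(f"{path} line {ln}: {exc}") from exc
    return out


def write_reaction_file(path, lines) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
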