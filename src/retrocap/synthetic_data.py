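"""Template-driven generator of atom-mapped single-step reactions.

Each reaction is assembled forward from two random fragments by forming a
single bond (amide coupling, ester formation, Williamson ether, or aryl
C-C coupling), so the reaction center — the formed bond and its two
endpoint atoms — is known by construction.  Leaving fragments (the acid
hydroxyl, halide chlorine) appear on the reactant side without product
maps, exercising the unmapped-atom path of the label extractor.

The generator also composes two templates into 2-step chains whose leaf
precursors define a buyable stock set, for route-planning tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_io import RCLabels, Reaction, canonicalize, parse_reaction
from .errors import DataError, TemplateError

__all__ = [
    "Fragment", "ReactionTemplate", "GeneratorConfig", "GeneratedReaction",
    "TEMPLATES", "make_fragment", "make_fragments", "apply_template",
    "generate_reactions", "make_chain", "generate_dataset",
]


@dataclass
class Fragment:
    """A molecule with one designated attachment atom and its leaving atoms."""

    rdmol: Chem.Mol
    attach_idx: int
    leaving_idxs: list[int]
    role: str

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)


@dataclass(frozen=True)
class ReactionTemplate:
    """Single-bond-forming template; the retro step cuts exactly that bond."""

    name: str
    roles: tuple[str, str]
    class_id: int
    #: SMARTS identifying the role group, used by the uniqueness oracle
    role_patterns: tuple[str, str]


TEMPLATES: dict[str, ReactionTemplate] = {
    "amide": ReactionTemplate("amide", ("acid", "amine"), 1,
                              ("C(=O)[OX2H1]", "[NX3;H2;!$(NC=O)]")),
    "ester": ReactionTemplate("ester", ("acid", "alcohol"), 2,
                              ("C(=O)[OX2H1]", "[OX2H]")),
    "ether": ReactionTemplate("ether", ("halide", "alcohol"), 3,
                              ("[CX4][Cl]", "[OX2H]")),
    "biaryl": ReactionTemplate("biaryl", ("aryl_halide", "aryl_halide"), 4,
                               ("c[Cl]", "c[Cl]")),
}


@dataclass
class GeneratorConfig:
    n_reactions: int = 100
    seed: int = 0
    templates: tuple[str, ...] = ("amide", "ester", "ether", "biaryl")
    template_weights: tuple[float, ...] | None = None
    frag_size_range: tuple[int, int] = (2, 6)   # skeleton heavy-atom bounds
    class_labels: bool = True
    n_chains: int = 2

    def __post_init__(self):
        if self.n_reactions < 1:
            raise DataError("n_reactions must be >= 1")
        lo, hi = self.frag_size_range
        if lo < 1 or hi < lo:
            raise DataError(f"invalid fragment size bounds {self.frag_size_range}")
        unknown = set(self.templates) - set(TEMPLATES)
        if unknown:
            raise DataError(f"unknown templates: {sorted(unknown)}")


@dataclass
class GeneratedReaction:
    line: str
    reaction: Reaction
    labels: RCLabels
    template: str
    cut_bond_maps: tuple[int, int]   # atom-map numbers of the formed bond
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fragment construction
# ---------------------------------------------------------------------------

_VALENCE = {"C": 4}


def _random_skeleton(rng: np.random.Generator, n_atoms: int) -> tuple[Chem.RWMol, list[int]]:
    """Random carbon tree decorated with fluorine leaves and inserted ether
    oxygens; returns the editable mol and the carbon indices with free
    valence (candidates for group attachment)."""
    mol = Chem.RWMol()
    free: dict[int, int] = {}
    first = mol.AddAtom(Chem.Atom("C"))
    free[first] = 4
    for _ in range(n_atoms - 1):
        parents = [i for i, v in free.items() if v > 0]
        parent = int(rng.choice(parents))
        idx = mol.AddAtom(Chem.Atom("C"))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        free[parent] -= 1
        free[idx] = 3
    # fluorine decoration (inert leaf)
    for i in list(free):
        if free[i] > 1 and rng.random() < 0.12:
            f = mol.AddAtom(Chem.Atom("F"))
            mol.AddBond(i, f, Chem.BondType.SINGLE)
            free[i] -= 1
    # ether insertion: replace one C-C bond by C-O-C (no new H-bearing group)
    cc_bonds = [b for b in mol.GetBonds()
                if b.GetBeginAtom().GetSymbol() == "C"
                and b.GetEndAtom().GetSymbol() == "C"]
    if cc_bonds and rng.random() < 0.30:
        b = cc_bonds[int(rng.integers(len(cc_bonds)))]
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        mol.RemoveBond(i, j)
        o = mol.AddAtom(Chem.Atom("O"))
        mol.AddBond(i, o, Chem.BondType.SINGLE)
        mol.AddBond(o, j, Chem.BondType.SINGLE)
    carbons = [i for i, v in free.items() if v > 0]
    return mol, carbons


def _add_benzene(mol: Chem.RWMol) -> list[int]:
    ring = [mol.AddAtom(Chem.Atom("C")) for _ in range(6)]
    for k in range(6):
        a, b = ring[k], ring[(k + 1) % 6]
        bond_type = Chem.BondType.AROMATIC
        mol.AddBond(a, b, bond_type)
    for i in ring:
        mol.GetAtomWithIdx(i).SetIsAromatic(True)
    return ring


def make_fragment(role: str, rng: np.random.Generator,
                  size_range: tuple[int, int] = (2, 6)) -> Fragment:
    """Build one random fragment carrying exactly one group for ``role``."""
    lo, hi = size_range
    n = int(rng.integers(lo, hi + 1))
    if role == "aryl_halide":
        mol = Chem.RWMol()
        ring = _add_benzene(mol)
        # optional alkyl substituent
        if n >= 2 and rng.random() < 0.7:
            sub, sub_carbons = _random_skeleton(rng, max(1, n - 1))
            offset = mol.GetNumAtoms()
            mol.InsertMol(sub.GetMol())
            anchor = offset + int(rng.choice(sub_carbons))
            mol.AddBond(ring[0], anchor, Chem.BondType.SINGLE)
        cl = mol.AddAtom(Chem.Atom("Cl"))
        mol.AddBond(ring[3], cl, Chem.BondType.SINGLE)
        attach, leaving = ring[3], [cl]
    else:
        mol, carbons = _random_skeleton(rng, n)
        parent = int(rng.choice(carbons))
        if role == "acid":
            c = mol.AddAtom(Chem.Atom("C"))
            o1 = mol.AddAtom(Chem.Atom("O"))
            o2 = mol.AddAtom(Chem.Atom("O"))
            mol.AddBond(parent, c, Chem.BondType.SINGLE)
            mol.AddBond(c, o1, Chem.BondType.DOUBLE)
            mol.AddBond(c, o2, Chem.BondType.SINGLE)
            attach, leaving = c, [o2]
        elif role == "amine":
            nat = mol.AddAtom(Chem.Atom("N"))
            mol.AddBond(parent, nat, Chem.BondType.SINGLE)
            attach, leaving = nat, []
        elif role == "alcohol":
            o = mol.AddAtom(Chem.Atom("O"))
            mol.AddBond(parent, o, Chem.BondType.SINGLE)
            attach, leaving = o, []
        elif role == "halide":
            cl = mol.AddAtom(Chem.Atom("Cl"))
            mol.AddBond(parent, cl, Chem.BondType.SINGLE)
            attach, leaving = parent, [cl]
        else:
            raise TemplateError(f"unknown fragment role {role!r}")
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Fragment(rdmol=out, attach_idx=attach, leaving_idxs=leaving, role=role)


def make_fragments(cfg: GeneratorConfig, seed: int) -> list[Fragment]:
    """One fragment per role slot of each configured template (reproducible)."""
    rng = np.random.default_rng(seed)
    out = []
    for name in cfg.templates:
        for role in TEMPLATES[name].roles:
            out.append(make_fragment(role, rng, cfg.frag_size_range))
    return out


# ---------------------------------------------------------------------------
# template application
# ---------------------------------------------------------------------------

def _remove_leaving(frag: Fragment) -> tuple[Chem.Mol, int, dict[int, int]]:
    """Copy of the fragment minus its leaving atoms.

    Returns (mol, new attachment index, old->new index map for kept atoms).
    """
    mol = Chem.RWMol(frag.rdmol)
    for idx in sorted(frag.leaving_idxs, reverse=True):
        mol.RemoveAtom(idx)
    keep = [i for i in range(frag.rdmol.GetNumAtoms()) if i not in frag.leaving_idxs]
    old2new = {old: new for new, old in enumerate(keep)}
    out = mol.GetMol()
    return out, old2new[frag.attach_idx], old2new


def apply_template(tmpl: ReactionTemplate, frags: tuple[Fragment, Fragment],
                   class_labels: bool = True) -> GeneratedReaction:
    """Form the template bond between two fragments and emit the mapped
    retro reaction line plus its recorded reaction-center labels."""
    fragA, fragB = frags
    if (fragA.role, fragB.role) != tmpl.roles:
        raise TemplateError(
            f"template {tmpl.name} needs roles {tmpl.roles}, "
            f"got ({fragA.role}, {fragB.role})")
    prodA, attachA, mapA = _remove_leaving(fragA)
    prodB, attachB, mapB = _remove_leaving(fragB)
    nA = prodA.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(prodA, prodB))
    combined.AddBond(attachA, nA + attachB, Chem.BondType.SINGLE)
    product = combined.GetMol()
    Chem.SanitizeMol(product)

    # atom maps: product atom i -> i + 1; reactant shared atoms mirror them
    for atom in product.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    reacA = Chem.RWMol(fragA.rdmol)
    for old, new in mapA.items():
        reacA.GetAtomWithIdx(old).SetAtomMapNum(new + 1)
    reacB = Chem.RWMol(fragB.rdmol)
    for old, new in mapB.items():
        reacB.GetAtomWithIdx(old).SetAtomMapNum(nA + new + 1)

    prefix = f"[RX_{tmpl.class_id}]" if class_labels else ""
    line = (prefix + Chem.MolToSmiles(reacA.GetMol()) + "."
            + Chem.MolToSmiles(reacB.GetMol()) + ">>" + Chem.MolToSmiles(product))
    rxn = parse_reaction(line)

    map_a, map_b = attachA + 1, nA + attachB + 1
    prod_parsed = rxn.product.rdmol
    by_map = {a.GetAtomMapNum(): a.GetIdx() for a in prod_parsed.GetAtoms()}
    ia, ib = by_map[map_a], by_map[map_b]
    bond = prod_parsed.GetBondBetweenAtoms(ia, ib)
    atom_labels = np.zeros(prod_parsed.GetNumAtoms(), dtype=np.int64)
    bond_labels = np.zeros(prod_parsed.GetNumBonds(), dtype=np.int64)
    atom_labels[[ia, ib]] = 1
    bond_labels[bond.GetIdx()] = 1
    labels = RCLabels(atom_labels=atom_labels, bond_labels=bond_labels)
    return GeneratedReaction(line=line, reaction=rxn, labels=labels,
                             template=tmpl.name, cut_bond_maps=(map_a, map_b))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_reactions(cfg: GeneratorConfig) -> list[GeneratedReaction]:
    """``cfg.n_reactions`` reactions with pairwise-distinct products.

    All randomness flows from ``cfg.seed`` through independent spawned
    streams (template choice / fragment construction).
    """
    ss = np.random.SeedSequence(cfg.seed)
    pick_rng, frag_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    weights = cfg.template_weights
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        weights = weights / weights.sum()
    out: list[GeneratedReaction] = []
    seen_products: set[str] = set()
    attempts = 0
    while len(out) < cfg.n_reactions:
        attempts += 1
        if attempts > 60 * cfg.n_reactions:
            raise DataError("could not generate enough distinct products; "
                            "widen frag_size_range or reduce n_reactions")
        name = str(pick_rng.choice(list(cfg.templates), p=weights))
        tmpl = TEMPLATES[name]
        frags = tuple(make_fragment(r, frag_rng, cfg.frag_size_range)
                      for r in tmpl.roles)
        try:
            gen = apply_template(tmpl, frags, class_labels=cfg.class_labels)
        except (TemplateError, Chem.rdchem.KekulizeException):
            continue
        prod = canonicalize(gen.reaction.product.smiles)
        if prod in seen_products:
            continue
        seen_products.add(prod)
        out.append(gen)
    return out


def _amino_alcohol(rng: np.random.Generator,
                   size_range: tuple[int, int]) -> tuple[Fragment, int]:
    """Skeleton carrying an amine (the step-1 role group) plus a spectator
    hydroxyl that becomes the step-2 attachment point.

    Returns (fragment in the amine role, hydroxyl O index)."""
    lo, hi = size_range
    n = max(3, int(rng.integers(lo, hi + 1)))
    mol, carbons = _random_skeleton(rng, n)
    if len(carbons) < 2:
        raise TemplateError("skeleton too small for an amino-alcohol")
    c_n, c_o = rng.choice(carbons, size=2, replace=False)
    nat = mol.AddAtom(Chem.Atom("N"))
    mol.AddBond(int(c_n), nat, Chem.BondType.SINGLE)
    o = mol.AddAtom(Chem.Atom("O"))
    mol.AddBond(int(c_o), o, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Fragment(rdmol=out, attach_idx=nat, leaving_idxs=[], role="amine"), o


def make_chain(rng: np.random.Generator,
               size_range: tuple[int, int] = (2, 5),
               class_labels: bool = True) -> dict:
    """A 2-step synthetic route: amide coupling then ester formation.

    Step 1: acid A + amino-alcohol B -> intermediate P1 (amide, free OH).
    Step 2: acid C + P1 -> target P2 (ester on P1's hydroxyl).
    Returns target, the two mapped reaction lines (target step first) and
    the buyable stock (canonical leaf precursors A, B, C).
    """
    acid_a = make_fragment("acid", rng, size_range)
    amine_b, o_idx = _amino_alcohol(rng, size_range)
    step1 = apply_template(TEMPLATES["amide"], (acid_a, amine_b),
                           class_labels=class_labels)

    # P1 as an alcohol-role fragment: locate the spectator O via its map
    # number (B occupies product indices nA..; maps are index+1 there).
    nA = acid_a.rdmol.GetNumAtoms() - len(acid_a.leaving_idxs)
    keepB = [i for i in range(amine_b.rdmol.GetNumAtoms())]
    o_map = nA + keepB.index(o_idx) + 1
    p1_parsed = step1.reaction.product.rdmol
    o_in_p1 = next(a.GetIdx() for a in p1_parsed.GetAtoms()
                   if a.GetAtomMapNum() == o_map)
    # reparse map-free so bracket-atom explicit-H counts are recomputed,
    # then chase the oxygen through the writer's atom output order
    stripped = Chem.Mol(p1_parsed)
    for a in stripped.GetAtoms():
        a.SetAtomMapNum(0)
    smi = Chem.MolToSmiles(stripped)
    order = json.loads(stripped.GetProp("_smilesAtomOutputOrder"))
    p1_clean = Chem.MolFromSmiles(smi)
    p1_frag = Fragment(rdmol=p1_clean, attach_idx=order.index(o_in_p1),
                       leaving_idxs=[], role="alcohol")

    acid_c = make_fragment("acid", rng, size_range)
    step2 = apply_template(TEMPLATES["ester"], (acid_c, p1_frag),
                           class_labels=class_labels)
    stock = sorted({canonicalize(Chem.MolToSmiles(f.rdmol))
                    for f in (acid_a, amine_b, acid_c)})
    return {
        "target": canonicalize(step2.reaction.product.smiles),
        "intermediate": canonicalize(step1.reaction.product.smiles),
        "steps": [step2, step1],
        "stock": stock,
    }


def generate_dataset(cfg: GeneratorConfig, out_dir) -> dict:
    """Write train/valid/test reaction files (80/10/10 by reaction), RC
    label files, a stock list, 2-step route chains, and a manifest."""
    if cfg.n_reactions < 10:
        raise DataError("need n_reactions >= 10 for an 80/10/10 split")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gens = generate_reactions(cfg)
    ss = np.random.SeedSequence(cfg.seed + 1)
    split_rng, chain_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    order = split_rng.permutation(len(gens))
    n_test = max(1, len(gens) // 10)
    n_valid = max(1, len(gens) // 10)
    test_idx = order[:n_test]
    valid_idx = order[n_test:n_test + n_valid]
    train_idx = order[n_test + n_valid:]
    splits = {"train": train_idx, "valid": valid_idx, "test": test_idx}

    chains = []
    for _ in range(cfg.n_chains):
        for _try in range(40):
            try:
                chains.append(make_chain(chain_rng, class_labels=cfg.class_labels))
                break
            except (TemplateError, Chem.rdchem.KekulizeException):
                continue

    counts = {}
    for split, idxs in splits.items():
        lines = [gens[i].line for i in idxs]
        if split == "train":
            for ch in chains:
                lines.extend(g.line for g in ch["steps"])
        (out_dir / f"{split}.txt").write_text(
            "# retrocap synthetic reactions\n" + "".join(l + "\n" for l in lines))
        with open(out_dir / f"{split}.labels.tsv", "w") as fh:
            recs = [gens[i] for i in idxs]
            if split == "train":
                for ch in chains:
                    recs.extend(ch["steps"])
            for rid, g in enumerate(recs):
                atoms = ",".join(map(str, np.nonzero(g.labels.atom_labels)[0]))
                prod = g.reaction.product.rdmol
                pairs = []
                for bi in np.nonzero(g.labels.bond_labels)[0]:
                    b = prod.GetBondWithIdx(int(bi))
                    pairs.append(f"{b.GetBeginAtomIdx()}-{b.GetEndAtomIdx()}")
                fh.write(f"{rid}\t{atoms}\t{','.join(pairs)}\t{g.template}\n")
        counts[split] = len(lines)

    stock = sorted({s for ch in chains for s in ch["stock"]})
    (out_dir / "stock.txt").write_text("".join(s + "\n" for s in stock))
    (out_dir / "routes.json").write_text(json.dumps(
        [{"target": ch["target"], "intermediate": ch["intermediate"],
          "stock": ch["stock"]} for ch in chains], indent=1))

    template_mix = {}
    for g in gens:
        template_mix[g.template] = template_mix.get(g.template, 0) + 1
    manifest = {
        "seed": cfg.seed,
        "n_reactions": cfg.n_reactions,
        "templates": list(cfg.templates),
        "template_mix": template_mix,
        "class_labels": cfg.class_labels,
        "counts": counts,
        "n_chains": len(chains),
        "files": {s: f"{s}.txt" for s in splits} | {
            "stock": "stock.txt", "routes": "routes.json"},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
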