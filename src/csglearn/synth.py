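"""Synthetic molecule and reaction corpora with known structure.

A fragment grammar assembles small organic molecules (alkyl chains with
optional methyl branch and phenyl ring, capped by an alcohol, carboxylic
acid, primary amine, diene or alkene head), and five reaction templates —
RDKit reaction-SMARTS graph edits — turn them into labeled reactions:

====  ===================  ========================================  =========
id    template             record                                    Δbonds/Δrings
====  ===================  ========================================  =========
0     esterification       acid + alcohol -> ester + water           0 / 0
1     amidation            acid + amine -> amide + water             0 / 0
2     Diels–Alder          diene + alkene -> cyclohexene             −2 / −1
3     alcohol oxidation    primary alcohol -> aldehyde               0 / 0
4     aldehyde oxidation   aldehyde -> carboxylic acid               −1 / 0
====  ===================  ========================================  =========

Aldehyde oxidations draw their reactant from the aldehydes produced by
earlier alcohol oxidations, so those {aldehyde} nodes carry both an in- and
an out-edge — the synthesis graph then has 2-hop neighborhoods, the
connectivity the CSGNN exploits.  Atom conservation is
approximate, as in real reaction records that omit small by-products; the
learning method never requires balanced equations.

The default corpus (120 molecules, 5 templates, 300 reactions, seed 0) is
the fixture the test-suite trains on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Molecule, Reaction, parse_molecule, parse_reaction
from .graph import transformation_features
from .chem import default_bond_type_vocabulary

__all__ = [
    "ReactionTemplate",
    "GenerationError",
    "TEMPLATES",
    "generate_molecules",
    "generate_reactions",
    "generate_property_dataset",
    "make_property_dataset",
    "make_default_corpus",
]


class GenerationError(RuntimeError):
    """Raised when a corpus with the requested structure cannot be built."""


@dataclass(frozen=True)
class ReactionTemplate:
    """A reaction-SMARTS graph-edit rule with its expected delta signs."""

    template_id: int
    name: str
    smarts: str
    reactant_patterns: tuple[str, ...]
    extra_reactants: tuple[str, ...] = ()
    extra_products: tuple[str, ...] = ()
    expected_sign: tuple[int, int] = (0, 0)  # sign of (Δbonds, Δrings)

    def rdkit_reaction(self):
        return AllChem.ReactionFromSmarts(self.smarts)


TEMPLATES: tuple[ReactionTemplate, ...] = (
    ReactionTemplate(
        0,
        "esterification",
        "[C:1](=[O:2])[OX2H1:3].[OX2H1:4][C;!$(C=O):5]>>[C:1](=[O:2])[O:4][C:5]",
        ("[CX3](=O)[OX2H1]", "[OX2H1][C;!$(C=O)]"),
        extra_products=("O",),
        expected_sign=(0, 0),
    ),
    ReactionTemplate(
        1,
        "amidation",
        "[C:1](=[O:2])[OX2H1:3].[NX3;H2:4][C:5]>>[C:1](=[O:2])[N:4][C:5]",
        ("[CX3](=O)[OX2H1]", "[NX3;H2][C]"),
        extra_products=("O",),
        expected_sign=(0, 0),
    ),
    ReactionTemplate(
        2,
        "diels_alder",
        "[C:1]=[C:2][C:3]=[C:4].[C:5]=[C:6]>>[C:1]1[C:2]=[C:3][C:4][C:5][C:6]1",
        ("C=CC=C", "[C]=[C]"),
        expected_sign=(-1, -1),
    ),
    ReactionTemplate(
        3,
        "alcohol_oxidation",
        "[C;H2:1][OX2H1:2]>>[C;H1:1]=[O:2]",
        ("[CH2][OX2H1]",),
        expected_sign=(0, 0),
    ),
    ReactionTemplate(
        4,
        "aldehyde_oxidation",
        "[CX3;H1:1]=[O:2]>>[C:1](=[O:2])[O]",
        ("[CX3;H1]=[OX1]",),
        expected_sign=(-1, 0),
    ),
)


# ------------------------------------------------------------ molecule pool
_HEADS = ("alcohol", "acid", "amine", "diene", "alkene", "plain")


def _random_smiles(rng: np.random.Generator, head: str, max_heavy_atoms: int,
                   ring_prob: float) -> str:
    budget = max_heavy_atoms - 4  # reserve for the head group
    k = int(rng.integers(1, max(2, min(7, budget))))
    chain = "C" * k
    if k >= 2 and rng.random() < 0.4:
        pos = int(rng.integers(1, k))
        chain = chain[:pos] + "(C)" + chain[pos:]
    if rng.random() < ring_prob and max_heavy_atoms >= k + 9:
        chain = chain + ("c1ccccc1" if rng.random() < 0.6 else "C1CCCC1")
    if head == "alcohol":
        return "OC" + chain
    if head == "acid":
        return "OC(=O)" + chain
    if head == "amine":
        return "NC" + chain
    if head == "diene":
        return "C=CC=C" + chain
    if head == "alkene":
        return "C=C" + chain
    return chain


def generate_molecules(
    n: int,
    max_heavy_atoms: int = 14,
    seed: int = 0,
    ring_prob: float = 0.35,
) -> list[Molecule]:
    """n distinct valid molecules from the fragment grammar, seeded."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[Molecule] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise GenerationError(
                f"could not generate {n} distinct molecules (got {len(out)})"
            )
        head = _HEADS[len(out) % len(_HEADS)]
        mol = parse_molecule(_random_smiles(rng, head, max_heavy_atoms, ring_prob))
        if mol.canonical_id in seen:
            continue
        seen.add(mol.canonical_id)
        out.append(mol)
    return out


# --------------------------------------------------------------- reactions
def _match_pool(mols: Sequence[Molecule], pattern: str) -> list[int]:
    patt = Chem.MolFromSmarts(pattern)
    return [
        i
        for i, m in enumerate(mols)
        if Chem.MolFromSmiles(m.canonical_id).HasSubstructMatch(patt)
    ]


def _run_template(
    template: ReactionTemplate, reactant_smiles: Sequence[str]
) -> list[str] | None:
    """Apply a template; canonical product SMILES or None on failure."""
    rxn = template.rdkit_reaction()
    mols = [Chem.MolFromSmiles(s) for s in reactant_smiles]
    if any(m is None for m in mols):
        return None
    try:
        product_sets = rxn.RunReactants(tuple(mols))
    except Exception:
        return None
    for products in product_sets:
        smiles = []
        ok = True
        for p in products:
            try:
                Chem.SanitizeMol(p)
                smiles.append(Chem.MolToSmiles(p))
            except Exception:
                ok = False
                break
        if ok and smiles:
            return smiles
    return None


def generate_reactions(
    mols: Sequence[Molecule],
    templates: Sequence[ReactionTemplate] = TEMPLATES,
    n: int = 300,
    seed: int = 0,
    subpool_size: int = 12,
) -> list[Reaction]:
    """n template-labeled reactions over a molecule pool.

    Reactant choices are drawn from small per-template subpools so sides
    repeat, and aldehyde oxidations consume the aldehydes produced by
    earlier alcohol oxidations — both mechanisms create the node sharing
    (degree ≥ 2, nodes with in- and out-edges) that gives the CSG 2-hop
    structure.
    """
    if not templates:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    pools: dict[int, list[list[str]]] = {}
    for t in templates:
        slot_pools = []
        for pattern in t.reactant_patterns:
            matches = _match_pool(mols, pattern)
            perm = rng.permutation(len(matches))
            slot_pools.append(
                [mols[matches[i]].canonical_id for i in perm[: max(subpool_size, 1)]]
            )
        pools[t.template_id] = slot_pools
    by_name = {t.name: t for t in templates}
    reactions: list[Reaction] = []
    vocab = default_bond_type_vocabulary()

    def build(
        template: ReactionTemplate, rid: str, slot_pools: list[list[str]]
    ) -> Reaction | None:
        if any(not p for p in slot_pools):
            return None
        for _ in range(30):
            reactant_ids = [p[rng.integers(len(p))] for p in slot_pools]
            products = _run_template(template, reactant_ids)
            if products is None:
                continue
            left = list(reactant_ids) + list(template.extra_reactants)
            right = list(products) + list(template.extra_products)
            try:
                rxn = parse_reaction(
                    ".".join(left) + ">>" + ".".join(right),
                    reaction_id=rid,
                    class_label=template.template_id,
                )
            except Exception:
                continue
            tf = transformation_features(rxn, vocab)
            if (np.sign(tf.delta_bonds), np.sign(tf.delta_rings)) != template.expected_sign:
                raise GenerationError(
                    f"template {template.name} produced deltas "
                    f"({tf.delta_bonds}, {tf.delta_rings}) violating its sign pattern"
                )
            return rxn
        return None

    chained = by_name.get("aldehyde_oxidation")
    chain_source = by_name.get("alcohol_oxidation")
    aldehydes: list[str] = []
    for i in range(n):
        template = templates[i % len(templates)]
        rid = f"synth-{i:04d}"
        slot_pools = pools[template.template_id]
        if chained is not None and template.template_id == chained.template_id:
            # consume aldehydes made by earlier alcohol oxidations so the
            # {aldehyde} nodes carry both an in- and an out-edge
            if aldehydes:
                slot_pools = [aldehydes]
        rxn = build(template, rid, slot_pools)
        if rxn is None:
            raise GenerationError(
                f"no compatible molecules for template {template.name}"
            )
        if chain_source is not None and template.template_id == chain_source.template_id:
            aldehydes.append(rxn.products[0].canonical_id)
        reactions.append(rxn)
    return reactions


# -------------------------------------------------------------- properties
def generate_property_dataset(
    mols: Sequence[Molecule],
    rule: Callable[[Molecule], bool] | None = None,
    noise: float = 0.05,
    seed: int = 0,
) -> list[tuple[Molecule, int]]:
    """Binary labels from a structural predicate plus flip noise.

    Default predicate: the molecule contains a ring.  Raises if the
    resulting class balance leaves [0.2, 0.8].
    """
    rule = rule or (lambda m: m.ring_count > 0)
    rng = np.random.default_rng(seed)
    labels = [int(rule(m)) for m in mols]
    labels = [l ^ int(rng.random() < noise) for l in labels]
    balance = float(np.mean(labels))
    if not 0.2 <= balance <= 0.8:
        raise GenerationError(
            f"class balance {balance:.2f} outside [0.2, 0.8]; regenerate the pool"
        )
    return list(zip(mols, labels))


def make_property_dataset(
    n: int = 200,
    max_heavy_atoms: int = 14,
    noise: float = 0.05,
    seed: int = 0,
    rule: Callable[[Molecule], bool] | None = None,
    max_retries: int = 10,
) -> list[tuple[Molecule, int]]:
    """Generate molecules and labels, retrying pools until balance holds."""
    for attempt in range(max_retries):
        mols = generate_molecules(
            n, max_heavy_atoms=max_heavy_atoms, seed=seed + 1000 * attempt,
            ring_prob=0.5,
        )
        try:
            return generate_property_dataset(mols, rule=rule, noise=noise, seed=seed)
        except GenerationError:
            continue
    raise GenerationError("could not reach class balance after retries")


def make_default_corpus(seed: int = 0) -> tuple[list[Molecule], list[Reaction]]:
    """The default fixture: 120 molecules, 5 templates, 300 reactions."""
    mols = generate_molecules(120, seed=seed)
    reactions = generate_reactions(mols, TEMPLATES, n=300, seed=seed)
    return mols, reactions
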