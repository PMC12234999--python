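"""Molecule and reaction parsing, atom featurization and count statistics.

Molecules are parsed with RDKit and reduced to a light immutable record: the
canonical SMILES (molecular identity), the heavy-atom list with the four
attributes the model uses (element, formal charge, attached hydrogens,
ring membership), the heavy-atom bond list, and the SSSR ring count.
Hydrogens stay implicit throughout — bonds to hydrogens are never enumerated.

The count statistics NB (total bonds), NR (total rings) and NB_b (per
bond-type counts) are the integer inputs of transformation-relation
modeling: a reaction's relation embedding is a linear combination of learned
basis vectors weighted by reactant-minus-product differences of these counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "Atom",
    "Molecule",
    "Reaction",
    "BondType",
    "BondTypeVocabulary",
    "MoleculeParseError",
    "ReactionParseError",
    "parse_molecule",
    "parse_reaction",
    "reverse_reaction",
    "count_bonds",
    "count_rings",
    "count_bond_types",
    "AtomFeaturizer",
    "atom_feature_vector",
    "default_bond_type_vocabulary",
    "read_reaction_file",
    "write_reaction_file",
    "read_property_file",
    "write_property_file",
]


class MoleculeParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class ReactionParseError(ValueError):
    """Raised when a reaction-SMILES record is malformed."""


@dataclass(frozen=True)
class Atom:
    """Heavy atom with the four attributes used for featurization."""

    element: str
    formal_charge: int
    num_hydrogens: int
    in_ring: bool


@dataclass(frozen=True)
class Molecule:
    """Parsed molecular graph keyed by its canonical SMILES."""

    canonical_id: str
    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, str], ...]  # (atom_i, atom_j, bond-order tag)
    ring_count: int

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_bonds(self) -> int:
        return len(self.bonds)

    def __hash__(self) -> int:
        return hash(self.canonical_id)


@dataclass(frozen=True)
class Reaction:
    """A reactant multiset transforming into a product multiset."""

    reaction_id: str
    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    class_label: int | None = None

    @property
    def smiles(self) -> str:
        left = ".".join(m.canonical_id for m in self.reactants)
        right = ".".join(m.canonical_id for m in self.products)
        return f"{left}>>{right}"


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    The heavy-atom graph is kept as-is (aromatic bonds are one bond each,
    tagged AROMATIC; no kekulization) and the ring count is the size of the
    smallest set of smallest rings.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparsable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    atoms = tuple(
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            num_hydrogens=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondType().name)
        for b in mol.GetBonds()
    )
    ring_count = len(Chem.GetSSSR(mol))
    return Molecule(canonical_id=canonical, atoms=atoms, bonds=bonds, ring_count=ring_count)


def parse_reaction(
    line: str, reaction_id: str | None = None, class_label: int | None = None
) -> Reaction:
    """Parse one reaction-SMILES record ``reactants>>products``.

    An optional middle ``>agents>`` field is discarded; molecules within a
    side are dot-separated. Both sides must be non-empty and parseable.
    """
    parts = line.strip().split(">")
    if len(parts) == 3:  # reactants>agents>products
        left, _, right = parts
    elif len(parts) == 2:
        left, right = parts
    else:
        raise ReactionParseError(f"missing '>>' separator in record: {line!r}")
    if not left.strip() or not right.strip():
        raise ReactionParseError(f"empty reaction side in record: {line!r}")
    try:
        reactants = tuple(parse_molecule(s) for s in left.split("."))
        products = tuple(parse_molecule(s) for s in right.split("."))
    except MoleculeParseError as exc:
        raise ReactionParseError(f"bad molecule in record {line!r}: {exc}") from exc
    return Reaction(
        reaction_id=reaction_id or line.strip(),
        reactants=reactants,
        products=products,
        class_label=class_label,
    )


def reverse_reaction(rxn: Reaction) -> Reaction:
    """Swap reactant and product sides (used by orientation invariants)."""
    return Reaction(
        reaction_id=f"{rxn.reaction_id}::rev",
        reactants=rxn.products,
        products=rxn.reactants,
        class_label=rxn.class_label,
    )


# --------------------------------------------------------------- bond types
@dataclass(frozen=True)
class BondType:
    """Order-insensitive element pair plus a bond-order tag."""

    elem_a: str
    elem_b: str
    order: str  # SINGLE | DOUBLE | TRIPLE | AROMATIC

    def key(self) -> tuple[str, str, str]:
        a, b = sorted((self.elem_a, self.elem_b))
        return (a, b, self.order)


#: the 15-entry default vocabulary of common organic bond types; replaceable
#: through YAML/JSON config (see :func:`BondTypeVocabulary.load`).
_DEFAULT_BOND_TYPES = [
    ("C", "C", "SINGLE"),
    ("C", "C", "DOUBLE"),
    ("C", "C", "TRIPLE"),
    ("C", "C", "AROMATIC"),
    ("C", "O", "SINGLE"),
    ("C", "O", "DOUBLE"),
    ("C", "N", "SINGLE"),
    ("C", "N", "DOUBLE"),
    ("C", "N", "TRIPLE"),
    ("C", "N", "AROMATIC"),
    ("C", "S", "SINGLE"),
    ("N", "O", "SINGLE"),
    ("N", "O", "DOUBLE"),
    ("O", "S", "DOUBLE"),
    ("O", "P", "SINGLE"),
]


class BondTypeVocabulary:
    """Fixed ordered list of bond types; unmatched bonds fall in OTHER.

    The OTHER bucket is tracked for bookkeeping but excluded from the
    per-type count vector that feeds relation modeling.
    """

    def __init__(self, entries: Sequence[BondType]):
        self.entries = tuple(entries)
        self._index = {bt.key(): i for i, bt in enumerate(self.entries)}
        if len(self._index) != len(self.entries):
            raise ValueError("duplicate bond-type entries in vocabulary")

    @property
    def size(self) -> int:
        return len(self.entries)

    def index_of(self, elem_a: str, elem_b: str, order: str) -> int | None:
        """Vocabulary index of a bond, or None for the OTHER bucket."""
        a, b = sorted((elem_a, elem_b))
        return self._index.get((a, b, order))

    def save(self, path: str | Path) -> None:
        items = [
            {"elem_a": bt.elem_a, "elem_b": bt.elem_b, "order": bt.order}
            for bt in self.entries
        ]
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(items, indent=1))
        else:
            path.write_text(yaml.safe_dump(items))

    @classmethod
    def load(cls, path: str | Path) -> "BondTypeVocabulary":
        path = Path(path)
        text = path.read_text()
        items = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls([BondType(d["elem_a"], d["elem_b"], d["order"]) for d in items])


def default_bond_type_vocabulary() -> BondTypeVocabulary:
    return BondTypeVocabulary([BondType(a, b, o) for a, b, o in _DEFAULT_BOND_TYPES])


# ------------------------------------------------------------------- counts
def count_bonds(mols: Iterable[Molecule]) -> int:
    """NB: total heavy-atom bonds over a molecule multiset."""
    return sum(m.num_bonds for m in mols)


def count_rings(mols: Iterable[Molecule]) -> int:
    """NR: total SSSR ring count over a molecule multiset."""
    return sum(m.ring_count for m in mols)


def count_bond_types(
    mols: Iterable[Molecule], vocab: BondTypeVocabulary
) -> np.ndarray:
    """NB_b: per-vocabulary-entry bond counts (OTHER bonds excluded)."""
    counts = np.zeros(vocab.size, dtype=np.int64)
    for mol in mols:
        for i, j, order in mol.bonds:
            idx = vocab.index_of(mol.atoms[i].element, mol.atoms[j].element, order)
            if idx is not None:
                counts[idx] += 1
    return counts


# ------------------------------------------------------------ featurization
class AtomFeaturizer:
    """One-hot concatenation of (charge, element, H count, ring flag).

    Formal charge is clipped to [-2, 2] and hydrogen count to [0, 4];
    elements outside the vocabulary map to a trailing UNK bucket. The
    element vocabulary is frozen from a training corpus before encoding.
    """

    CHARGES = (-2, -1, 0, 1, 2)
    HCOUNTS = (0, 1, 2, 3, 4)

    def __init__(self, elements: Sequence[str]):
        self.elements = tuple(sorted(set(elements)))
        self._elem_index = {e: i for i, e in enumerate(self.elements)}

    @classmethod
    def from_molecules(cls, mols: Iterable[Molecule]) -> "AtomFeaturizer":
        elems = {a.element for m in mols for a in m.atoms}
        return cls(sorted(elems))

    @property
    def feature_dim(self) -> int:
        return len(self.CHARGES) + len(self.elements) + 1 + len(self.HCOUNTS) + 2

    def atom_vector(self, atom: Atom) -> np.ndarray:
        vec = np.zeros(self.feature_dim)
        charge = int(np.clip(atom.formal_charge, -2, 2))
        vec[charge + 2] = 1.0
        off = len(self.CHARGES)
        vec[off + self._elem_index.get(atom.element, len(self.elements))] = 1.0
        off += len(self.elements) + 1
        vec[off + int(np.clip(atom.num_hydrogens, 0, 4))] = 1.0
        off += len(self.HCOUNTS)
        vec[off + int(atom.in_ring)] = 1.0
        return vec

    def molecule_matrix(self, mol: Molecule) -> np.ndarray:
        return np.stack([self.atom_vector(a) for a in mol.atoms])


def atom_feature_vector(atom: Atom, featurizer: AtomFeaturizer) -> np.ndarray:
    """Binary feature vector of one atom (exactly four ones)."""
    return featurizer.atom_vector(atom)


# --------------------------------------------------------------------- I/O
def read_reaction_file(path: str | Path) -> list[Reaction]:
    """Read a reaction file: column 1 reaction-SMILES, optional integer label.

    Plain text or TSV; ``#`` comment lines and blank lines are skipped.
    Parse failures report the 1-based line number.
    """
    reactions = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        label = None
        if len(fields) > 1 and fields[1].strip():
            label = int(fields[1])
        try:
            reactions.append(
                parse_reaction(fields[0], reaction_id=f"line{lineno}", class_label=label)
            )
        except ReactionParseError as exc:
            raise ReactionParseError(f"line {lineno}: {exc}") from exc
    return reactions


def write_reaction_file(path: str | Path, reactions: Iterable[Reaction]) -> None:
    lines = []
    for rxn in reactions:
        if rxn.class_label is not None:
            lines.append(f"{rxn.smiles}\t{rxn.class_label}")
        else:
            lines.append(rxn.smiles)
    Path(path).write_text("\n".join(lines) + "\n")


def read_property_file(path: str | Path) -> list[tuple[Molecule, int]]:
    """Read a molecule property TSV with columns ``smiles`` and ``label``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"smiles", "label"}.issubset(df.columns):
        raise ValueError("property file needs 'smiles' and 'label' columns")
    return [(parse_molecule(s), int(l)) for s, l in zip(df["smiles"], df["label"])]


def write_property_file(
    path: str | Path, data: Iterable[tuple[Molecule, int]]
) -> None:
    lines = ["smiles\tlabel"]
    lines += [f"{mol.canonical_id}\t{label}" for mol, label in data]
    Path(path).write_text("\n".join(lines) + "\n")
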