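"""Chemical synthesis graph (CSG) construction.

Nodes are deduplicated molecule multisets — the reactant side or product side
of some reaction — keyed by the sorted tuple of member canonical SMILES, so a
set appearing as the product of one reaction and the reactant of another is a
single node. Each reaction contributes one directed edge reactant-node ->
product-node carrying integer transformation features: the
reactant-minus-product deltas of bond count, ring count and per-bond-type
counts. Traversing an edge against its direction negates the features, so
neighbor features are always oriented center -> neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    BondTypeVocabulary,
    Molecule,
    Reaction,
    count_bond_types,
    count_bonds,
    count_rings,
)

__all__ = [
    "TransformationFeatures",
    "CSGNode",
    "CSGEdge",
    "CSG",
    "member_key",
    "transformation_features",
    "build_csg",
    "neighbors",
    "export_edge_list",
    "import_edge_list",
]


def member_key(mols: Iterable[Molecule]) -> str:
    """Canonical multiset key: sorted member canonical SMILES joined by '.'."""
    return ".".join(sorted(m.canonical_id for m in mols))


@dataclass(frozen=True)
class TransformationFeatures:
    """Integer deltas (reactants minus products) annotating a CSG edge."""

    delta_bonds: int
    delta_rings: int
    delta_bond_types: tuple[int, ...]

    def __neg__(self) -> "TransformationFeatures":
        return TransformationFeatures(
            -self.delta_bonds,
            -self.delta_rings,
            tuple(-x for x in self.delta_bond_types),
        )

    def vector(self) -> np.ndarray:
        """Dense [delta_bonds, delta_rings, *delta_bond_types] vector."""
        return np.array(
            [self.delta_bonds, self.delta_rings, *self.delta_bond_types],
            dtype=np.float64,
        )

    @property
    def is_zero(self) -> bool:
        return (
            self.delta_bonds == 0
            and self.delta_rings == 0
            and all(x == 0 for x in self.delta_bond_types)
        )


@dataclass(frozen=True)
class CSGNode:
    node_id: int
    member_key: str
    members: tuple[Molecule, ...]


@dataclass(frozen=True)
class CSGEdge:
    source: int
    target: int
    features: TransformationFeatures
    reaction_id: str


def transformation_features(
    rxn: Reaction, vocab: BondTypeVocabulary
) -> TransformationFeatures:
    """Bond/ring/bond-type count deltas of one reaction (reactants − products)."""
    return TransformationFeatures(
        delta_bonds=count_bonds(rxn.reactants) - count_bonds(rxn.products),
        delta_rings=count_rings(rxn.reactants) - count_rings(rxn.products),
        delta_bond_types=tuple(
            (count_bond_types(rxn.reactants, vocab) - count_bond_types(rxn.products, vocab)).tolist()
        ),
    )


class CSG:
    """The synthesis graph: nodes, directed edges and two-way adjacency."""

    def __init__(self, nodes: Sequence[CSGNode], edges: Sequence[CSGEdge]):
        self.nodes = list(nodes)
        self.edges = list(edges)
        self.key_to_id = {n.member_key: n.node_id for n in self.nodes}
        # adjacency: node_id -> list of (edge index, True if node is source)
        self.adjacency: list[list[tuple[int, bool]]] = [[] for _ in self.nodes]
        for e_idx, edge in enumerate(self.edges):
            if not (0 <= edge.source < len(self.nodes) and 0 <= edge.target < len(self.nodes)):
                raise ValueError(f"edge {e_idx} references unknown node")
            self.adjacency[edge.source].append((e_idx, True))
            self.adjacency[edge.target].append((e_idx, False))

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def node_for(self, mols: Iterable[Molecule]) -> int | None:
        """Node id for a molecule multiset, or None if absent."""
        return self.key_to_id.get(member_key(mols))

    def degree(self, node_id: int) -> int:
        return len(self.adjacency[node_id])


def build_csg(reactions: Sequence[Reaction], vocab: BondTypeVocabulary) -> CSG:
    """Build the CSG from a reaction corpus.

    Sides are deduplicated corpus-wide by multiset key; duplicate reactions
    keep parallel edges distinguished by reaction_id.
    """
    if not reactions:
        raise ValueError("cannot build a CSG from an empty reaction list")
    nodes: list[CSGNode] = []
    key_to_id: dict[str, int] = {}

    def intern(mols: tuple[Molecule, ...]) -> int:
        key = member_key(mols)
        if key not in key_to_id:
            key_to_id[key] = len(nodes)
            nodes.append(CSGNode(len(nodes), key, mols))
        return key_to_id[key]

    edges = []
    for rxn in reactions:
        src = intern(rxn.reactants)
        dst = intern(rxn.products)
        edges.append(
            CSGEdge(src, dst, transformation_features(rxn, vocab), rxn.reaction_id)
        )
    return CSG(nodes, edges)


def neighbors(
    csg: CSG, node_id: int
) -> list[tuple[int, TransformationFeatures]]:
    """Both-direction neighbors with features oriented center -> neighbor.

    For an in-edge (neighbor -> center) the stored features are negated so
    that the linear delta semantics hold from the center's perspective.
    """
    if not (0 <= node_id < csg.num_nodes):
        raise KeyError(f"unknown node_id {node_id}")
    out = []
    for e_idx, is_source in csg.adjacency[node_id]:
        edge = csg.edges[e_idx]
        if is_source:
            out.append((edge.target, edge.features))
        else:
            out.append((edge.source, -edge.features))
    return out


# ---------------------------------------------------------------- edge list
def export_edge_list(csg: CSG, path: str | Path) -> None:
    """Write the edge list as inspectable TSV (one line per reaction edge)."""
    lines = []
    for edge in csg.edges:
        tf = edge.features
        lines.append(
            "\t".join(
                [
                    csg.nodes[edge.source].member_key,
                    csg.nodes[edge.target].member_key,
                    edge.reaction_id,
                    str(tf.delta_bonds),
                    str(tf.delta_rings),
                    ",".join(str(x) for x in tf.delta_bond_types),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def import_edge_list(path: str | Path) -> list[tuple[str, str, str, TransformationFeatures]]:
    """Read back an exported edge list (keys + features; molecules not reparsed)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        src, dst, rid, db, dr, dbt = line.split("\t")
        rows.append(
            (
                src,
                dst,
                rid,
                TransformationFeatures(
                    int(db), int(dr), tuple(int(x) for x in dbt.split(","))
                ),
            )
        )
    return rows
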