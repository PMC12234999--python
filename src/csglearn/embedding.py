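"""CSG node and relation embeddings: READ, CSGNN propagation, relations.

A CSG node (a reactant or product molecule set) gets its base embedding from
READ — the elementwise sum of its member-molecule embeddings.  The CSGNN then
refines node embeddings over the synthesis graph: at each of H layers a node
adds an attention-weighted sum of its neighbors' embeddings to its own
(residual) representation, with attention logits computed from the elementwise
product of center, neighbor and their transformation-relation embedding; the
final embedding is the average over layers 0..H.  H = 0 disables propagation
and recovers pure READ (the CSGNN-free variant).

A transformation relation is embedded linearly from its integer deltas:
``T = Δbonds·e_bond + Δrings·e_ring + Σ_j Δcount_j·e_bj``
with one learned basis vector per delta channel.

This module holds the reference (NumPy) implementations used at inference
time; training runs an equivalent vectorized autodiff path inside
:mod:`csglearn.model`, and the two are cross-checked in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .chem import BondTypeVocabulary, Reaction
from .graph import CSG, TransformationFeatures, neighbors, transformation_features

__all__ = [
    "RelationParams",
    "CSGNNParams",
    "NodeEmbeddingTable",
    "read",
    "relation_embedding",
    "attention_weights",
    "csgnn_propagate",
    "embed_reaction_sides",
]


class RelationParams:
    """Learned relation basis: rows [e_bond, e_ring, e_b1 .. e_bV] of a matrix."""

    def __init__(self, matrix: np.ndarray):
        if matrix.ndim != 2 or matrix.shape[0] < 3:
            raise ValueError("relation matrix must be (2 + vocab size) x d")
        self.matrix = np.asarray(matrix, dtype=np.float64)

    @property
    def e_bond(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def e_ring(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def e_bond_types(self) -> np.ndarray:
        return self.matrix[2:]

    @property
    def vocab_size(self) -> int:
        return self.matrix.shape[0] - 2

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CSGNNParams:
    """Per-layer attention weight vectors W_a (each maps a d-vector to a logit)."""

    attention_weights: list[np.ndarray]  # H arrays of shape (d,)

    @property
    def num_layers(self) -> int:
        return len(self.attention_weights)


@dataclass
class NodeEmbeddingTable:
    """Layer-indexed node embeddings plus the layer-averaged final table."""

    layers: list[np.ndarray]  # H+1 arrays of shape (n_nodes, d)

    @property
    def final(self) -> np.ndarray:
        return np.mean(self.layers, axis=0)


def read(member_embs: Sequence[np.ndarray]) -> np.ndarray:
    """READ: elementwise sum of member molecule embeddings."""
    if len(member_embs) == 0:
        raise ValueError("READ requires a non-empty molecule set")
    return np.sum(np.stack(member_embs), axis=0)


def relation_embedding(tf: TransformationFeatures, rp: RelationParams) -> np.ndarray:
    """Linear relation embedding from integer deltas."""
    vec = tf.vector()
    if vec.shape[0] != rp.matrix.shape[0]:
        raise ValueError(
            f"bond-type vocabulary mismatch: features have {vec.shape[0] - 2} "
            f"entries, relation params expect {rp.vocab_size}"
        )
    return vec @ rp.matrix


def attention_weights(
    center_emb: np.ndarray,
    neighbor_embs: Sequence[np.ndarray],
    neighbor_relations: Sequence[np.ndarray],
    w_a: np.ndarray,
) -> np.ndarray:
    """Softmax attention over a node's neighborhood.

    Logit of neighbor j is ``w_a · (center ⊙ neighbor_j ⊙ T_j)`` with T_j the
    relation embedding oriented center -> neighbor; an empty neighborhood
    yields an empty weight array.
    """
    if len(neighbor_embs) != len(neighbor_relations):
        raise ValueError("neighbor embedding and relation lists differ in length")
    if len(neighbor_embs) == 0:
        return np.zeros(0)
    logits = np.array(
        [w_a @ (center_emb * nb * rel) for nb, rel in zip(neighbor_embs, neighbor_relations)]
    )
    logits -= logits.max()
    exp = np.exp(logits)
    return exp / exp.sum()


def csgnn_propagate(
    csg: CSG, base: np.ndarray, rp: RelationParams, cp: CSGNNParams
) -> NodeEmbeddingTable:
    """Run H layers of attention aggregation over the whole CSG.

    ``base`` is the layer-0 table (one READ embedding per node).  Layer h+1 of
    node v is ``emb_h(v) + Σ_u π_{v→u} emb_h(u)`` over both-direction
    neighbors u with softmax weights π; the final table averages layers 0..H.
    """
    layers = [np.asarray(base, dtype=np.float64)]
    nbr_lists = [neighbors(csg, v) for v in range(csg.num_nodes)]
    rel_cache = [
        [relation_embedding(tf, rp) for _, tf in nbrs] for nbrs in nbr_lists
    ]
    for h in range(cp.num_layers):
        prev = layers[-1]
        nxt = prev.copy()
        w_a = cp.attention_weights[h]
        for v in range(csg.num_nodes):
            nbrs = nbr_lists[v]
            if not nbrs:
                continue
            ids = [u for u, _ in nbrs]
            weights = attention_weights(prev[v], [prev[u] for u in ids], rel_cache[v], w_a)
            nxt[v] = prev[v] + weights @ prev[ids]
        layers.append(nxt)
    return NodeEmbeddingTable(layers)


def embed_reaction_sides(
    rxn: Reaction,
    csg: CSG,
    node_table: NodeEmbeddingTable,
    encode_set: Callable[[Sequence], np.ndarray],
    rp: RelationParams,
    vocab: BondTypeVocabulary,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Embeddings (R, P, T) for one reaction.

    Sides whose molecule multiset is a CSG node use that node's refined
    embedding; unseen sides fall back to READ over freshly encoded members
    (equivalent to H = 0 for them).  ``encode_set`` maps a molecule list to
    the stacked (n, d) embedding matrix.
    """
    final = node_table.final

    def side_embedding(mols) -> np.ndarray:
        node_id = csg.node_for(mols)
        if node_id is not None:
            return final[node_id]
        return read(list(encode_set(list(mols))))

    r_emb = side_embedding(rxn.reactants)
    p_emb = side_embedding(rxn.products)
    t_emb = relation_embedding(transformation_features(rxn, vocab), rp)
    return r_emb, p_emb, t_emb
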