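"""Molecule encoder: L message-passing layers plus a graph-pooling readout.

Atoms start from the concatenated one-hot attribute vector, pass through L
GNN layers (GCN, GAT, GraphSAGE or TAG — each following its published
aggregation convention), and a pooling operator reduces the atom embeddings
of each molecule to one d-dimensional molecule embedding.  Sum pooling is the
default; avg, max, MLP-attention, SortPooling and Set2Set are available for
sensitivity studies.

Implementation: molecules are encoded in block-diagonal batches — all atom
feature rows stacked, per-architecture normalized adjacency as one sparse
matrix, and per-molecule contiguous atom segments for the readout.  ReLU is
applied between layers but not after the last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, concat, glorot_uniform, segment_max, spmm
from .chem import AtomFeaturizer, Molecule

__all__ = [
    "EncoderConfig",
    "BatchedGraph",
    "MoleculeEncoder",
    "segment_softmax",
    "encode_atoms",
    "pool",
    "encode_molecule",
]

GNN_TYPES = ("gcn", "gat", "sage", "tag")
POOLING_METHODS = ("sum", "avg", "max", "attention", "sortpool", "set2set")


@dataclass
class EncoderConfig:
    """Architecture hyperparameters of the molecule encoder.

    Defaults: 2 GNN layers, 64-dimensional embeddings, GCN aggregation and
    sum pooling.
    """

    gnn_type: str = "gcn"
    num_layers: int = 2
    hidden_dim: int = 64
    pooling: str = "sum"
    sortpool_k: int = 10
    set2set_steps: int = 3
    tag_hops: int = 2
    leaky_slope: float = 0.2

    def validate(self) -> None:
        if self.gnn_type not in GNN_TYPES:
            raise ValueError(f"unknown gnn_type {self.gnn_type!r}; expected one of {GNN_TYPES}")
        if self.pooling not in POOLING_METHODS:
            raise ValueError(
                f"unknown pooling {self.pooling!r}; expected one of {POOLING_METHODS}"
            )
        if self.num_layers < 1 or self.hidden_dim < 1:
            raise ValueError("num_layers and hidden_dim must be positive")


class BatchedGraph:
    """Block-diagonal batch of molecular graphs ready for encoding."""

    def __init__(self, mols: Sequence[Molecule], featurizer: AtomFeaturizer):
        self.mols = list(mols)
        self.featurizer = featurizer
        counts = [m.num_atoms for m in self.mols]
        self.n_atoms = int(np.sum(counts))
        self.n_mols = len(self.mols)
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.intp)
        self.seg_ids = np.repeat(np.arange(self.n_mols), counts)
        self.features = (
            np.concatenate([featurizer.molecule_matrix(m) for m in self.mols])
            if self.n_atoms
            else np.zeros((0, featurizer.feature_dim))
        )
        # undirected bond list in global atom indices
        src, dst = [], []
        for offset, mol in zip(self.starts, self.mols):
            for i, j, _ in mol.bonds:
                src += [offset + i, offset + j]
                dst += [offset + j, offset + i]
        self.bond_src = np.asarray(src, dtype=np.intp)
        self.bond_dst = np.asarray(dst, dtype=np.intp)
        n = self.n_atoms
        adj = sp.csr_matrix(
            (np.ones(len(self.bond_src)), (self.bond_dst, self.bond_src)), shape=(n, n)
        )
        deg = np.asarray(adj.sum(axis=1)).ravel()
        # GCN: sym-normalized adjacency with self-loops
        deg_hat = deg + 1.0
        d_inv_sqrt = 1.0 / np.sqrt(deg_hat)
        self.gcn_adj = (
            sp.diags(d_inv_sqrt) @ (adj + sp.eye(n, format="csr")) @ sp.diags(d_inv_sqrt)
        ).tocsr()
        # SAGE: row-normalized neighbor mean (zero row for isolated atoms)
        with np.errstate(divide="ignore"):
            d_inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
        self.mean_adj = (sp.diags(d_inv) @ adj).tocsr()
        # TAG: sym-normalized adjacency without self-loops
        d_inv_sqrt0 = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        self.sym_adj = (sp.diags(d_inv_sqrt0) @ adj @ sp.diags(d_inv_sqrt0)).tocsr()
        # GAT: directed edge list over neighbors ∪ self
        self.gat_src = np.concatenate([self.bond_src, np.arange(n)]).astype(np.intp)
        self.gat_dst = np.concatenate([self.bond_dst, np.arange(n)]).astype(np.intp)
        order = np.argsort(self.gat_dst, kind="stable")
        self.gat_src, self.gat_dst = self.gat_src[order], self.gat_dst[order]
        self.gat_scatter = sp.csr_matrix(
            (np.ones(len(self.gat_dst)), (self.gat_dst, np.arange(len(self.gat_dst)))),
            shape=(n, len(self.gat_dst)),
        )
        self.gat_starts = np.searchsorted(self.gat_dst, np.arange(n)).astype(np.intp)
        # per-molecule readout matrices
        self.pool_sum = sp.csr_matrix(
            (np.ones(n), (self.seg_ids, np.arange(n))), shape=(self.n_mols, n)
        )
        inv_counts = 1.0 / np.maximum(np.asarray(counts, dtype=np.float64), 1.0)
        self.pool_avg = (sp.diags(inv_counts) @ self.pool_sum).tocsr()
        self.seg_scatter = self.pool_sum  # (n_mols × n_atoms) indicator


def segment_softmax(scores: Tensor, starts: np.ndarray, seg_ids: np.ndarray,
                    scatter: sp.spmatrix) -> Tensor:
    """Softmax of an (N,1) score column within contiguous segments."""
    shift = np.maximum.reduceat(scores.data[:, 0], starts)[seg_ids][:, None]
    e = (scores - shift).exp()
    denom = spmm(scatter, e)
    return e / denom.gather_rows(seg_ids)


class MoleculeEncoder:
    """Parameterized molecule-graph encoder producing d-dim embeddings."""

    def __init__(self, config: EncoderConfig, featurizer: AtomFeaturizer,
                 rng: np.random.Generator | None = None):
        config.validate()
        self.config = config
        self.featurizer = featurizer
        rng = rng or np.random.default_rng(0)
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # ------------------------------------------------------------ parameters
    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        in_dim = self.featurizer.feature_dim
        d = cfg.hidden_dim
        for layer in range(cfg.num_layers):
            fi = in_dim if layer == 0 else d
            pre = f"enc.l{layer}"
            if cfg.gnn_type == "gcn":
                self._add(f"{pre}.W", glorot_uniform(rng, (fi, d)))
            elif cfg.gnn_type == "sage":
                self._add(f"{pre}.W_self", glorot_uniform(rng, (fi, d)))
                self._add(f"{pre}.W_neigh", glorot_uniform(rng, (fi, d)))
            elif cfg.gnn_type == "tag":
                for k in range(cfg.tag_hops + 1):
                    self._add(f"{pre}.W{k}", glorot_uniform(rng, (fi, d)))
            elif cfg.gnn_type == "gat":
                self._add(f"{pre}.W", glorot_uniform(rng, (fi, d)))
                self._add(f"{pre}.a_src", glorot_uniform(rng, (d, 1)))
                self._add(f"{pre}.a_dst", glorot_uniform(rng, (d, 1)))
            self._add(f"{pre}.b", np.zeros(d))
        if cfg.pooling == "attention":
            self._add("pool.att.W1", glorot_uniform(rng, (d, d)))
            self._add("pool.att.b1", np.zeros(d))
            self._add("pool.att.w2", glorot_uniform(rng, (d, 1)))
        elif cfg.pooling == "sortpool":
            self._add("pool.sort.W", glorot_uniform(rng, (cfg.sortpool_k * d, d)))
            self._add("pool.sort.b", np.zeros(d))
        elif cfg.pooling == "set2set":
            self._add("pool.s2s.Wx", glorot_uniform(rng, (2 * d, 4 * d)))
            self._add("pool.s2s.Wh", glorot_uniform(rng, (d, 4 * d)))
            self._add("pool.s2s.b", np.zeros(4 * d))
            self._add("pool.s2s.Wout", glorot_uniform(rng, (2 * d, d)))
            self._add("pool.s2s.bout", np.zeros(d))

    def load_params(self, arrays: dict[str, np.ndarray]) -> None:
        for name, tensor in self.params.items():
            if name not in arrays:
                raise ValueError(f"checkpoint missing encoder parameter {name!r}")
            if arrays[name].shape != tensor.data.shape:
                raise ValueError(
                    f"parameter {name!r} shape mismatch: "
                    f"{arrays[name].shape} vs {tensor.data.shape}"
                )
            tensor.data = np.asarray(arrays[name], dtype=np.float64)

    # --------------------------------------------------------------- forward
    def _layer(self, h: Tensor, batch: BatchedGraph, layer: int) -> Tensor:
        cfg = self.config
        p = self.params
        pre = f"enc.l{layer}"
        if cfg.gnn_type == "gcn":
            out = spmm(batch.gcn_adj, h @ p[f"{pre}.W"])
        elif cfg.gnn_type == "sage":
            out = h @ p[f"{pre}.W_self"] + spmm(batch.mean_adj, h) @ p[f"{pre}.W_neigh"]
        elif cfg.gnn_type == "tag":
            out = h @ p[f"{pre}.W0"]
            hop = h
            for k in range(1, cfg.tag_hops + 1):
                hop = spmm(batch.sym_adj, hop)
                out = out + hop @ p[f"{pre}.W{k}"]
        else:  # gat
            hw = h @ p[f"{pre}.W"]
            logits = (
                hw.gather_rows(batch.gat_src) @ p[f"{pre}.a_src"]
                + hw.gather_rows(batch.gat_dst) @ p[f"{pre}.a_dst"]
            ).leaky_relu(cfg.leaky_slope)
            att = segment_softmax(logits, batch.gat_starts, batch.gat_dst, batch.gat_scatter)
            out = spmm(batch.gat_scatter, att * hw.gather_rows(batch.gat_src))
        return out + p[f"{pre}.b"]

    def atom_layers(self, batch: BatchedGraph) -> list[Tensor]:
        """Per-layer atom embedding matrices, layer 0 = raw features."""
        h = Tensor(batch.features)
        layers = [h]
        for layer in range(self.config.num_layers):
            h = self._layer(h, batch, layer)
            if layer < self.config.num_layers - 1:
                h = h.relu()
            layers.append(h)
        return layers

    def _pool(self, h: Tensor, batch: BatchedGraph) -> Tensor:
        cfg, p = self.config, self.params
        if cfg.pooling == "sum":
            return spmm(batch.pool_sum, h)
        if cfg.pooling == "avg":
            return spmm(batch.pool_avg, h)
        if cfg.pooling == "max":
            return segment_max(h, batch.starts)
        if cfg.pooling == "attention":
            scores = (h @ p["pool.att.W1"] + p["pool.att.b1"]).tanh() @ p["pool.att.w2"]
            att = segment_softmax(scores, batch.starts, batch.seg_ids, batch.seg_scatter)
            return spmm(batch.pool_sum, att * h)
        if cfg.pooling == "sortpool":
            return self._sortpool(h, batch)
        return self._set2set(h, batch)

    def _sortpool(self, h: Tensor, batch: BatchedGraph) -> Tensor:
        # sort atoms within each molecule by the last channel (descending,
        # stable), keep top-k rows, zero-pad short molecules
        cfg = self.config
        k, d = cfg.sortpool_k, cfg.hidden_dim
        pad_row = h.data.shape[0]  # index of an appended all-zero row
        bounds = np.append(batch.starts, h.data.shape[0])
        idx = np.full((batch.n_mols, k), pad_row, dtype=np.intp)
        for m in range(batch.n_mols):
            a, b = bounds[m], bounds[m + 1]
            order = np.argsort(-h.data[a:b, -1], kind="stable")[:k]
            idx[m, : len(order)] = a + order
        padded = concat([h, Tensor(np.zeros((1, d)))], axis=0)
        flat = padded.gather_rows(idx.ravel()).reshape(batch.n_mols, k * d)
        return flat @ self.params["pool.sort.W"] + self.params["pool.sort.b"]

    def _set2set(self, h: Tensor, batch: BatchedGraph) -> Tensor:
        cfg, p = self.config, self.params
        d, n_mols = cfg.hidden_dim, batch.n_mols
        q_star = Tensor(np.zeros((n_mols, 2 * d)))
        hid = Tensor(np.zeros((n_mols, d)))
        cell = Tensor(np.zeros((n_mols, d)))
        for _ in range(cfg.set2set_steps):
            gates = q_star @ p["pool.s2s.Wx"] + hid @ p["pool.s2s.Wh"] + p["pool.s2s.b"]
            i = gates[:, :d].sigmoid()
            f = gates[:, d : 2 * d].sigmoid()
            o = gates[:, 2 * d : 3 * d].sigmoid()
            g = gates[:, 3 * d :].tanh()
            cell = f * cell + i * g
            hid = o * cell.tanh()
            scores = (h * hid.gather_rows(batch.seg_ids)).sum(axis=1, keepdims=True)
            att = segment_softmax(scores, batch.starts, batch.seg_ids, batch.seg_scatter)
            readout = spmm(batch.pool_sum, att * h)
            q_star = concat([hid, readout], axis=1)
        return q_star @ p["pool.s2s.Wout"] + p["pool.s2s.bout"]

    def encode_batch(self, batch: BatchedGraph) -> Tensor:
        """Embeddings of every molecule in the batch, shape (n_mols, d)."""
        return self._pool(self.atom_layers(batch)[-1], batch)

    def encode_molecules(self, mols: Sequence[Molecule]) -> np.ndarray:
        """Convenience inference path: plain ndarray of embeddings."""
        if not mols:
            return np.zeros((0, self.config.hidden_dim))
        return self.encode_batch(BatchedGraph(mols, self.featurizer)).data


# ------------------------------------------------ single-molecule helpers
def encode_atoms(
    mol: Molecule, encoder: MoleculeEncoder
) -> list[np.ndarray]:
    """Layer-indexed atom embedding matrices (layer 0 .. L) for one molecule."""
    batch = BatchedGraph([mol], encoder.featurizer)
    return [layer.data for layer in encoder.atom_layers(batch)]


def pool(
    atom_embs: np.ndarray, method: str, encoder: MoleculeEncoder, mol: Molecule
) -> np.ndarray:
    """Apply one pooling method to a final-layer atom embedding matrix."""
    if method not in POOLING_METHODS:
        raise ValueError(f"unknown pooling method {method!r}")
    saved = encoder.config.pooling
    encoder.config.pooling = method
    try:
        batch = BatchedGraph([mol], encoder.featurizer)
        out = encoder._pool(Tensor(atom_embs), batch).data[0]
    finally:
        encoder.config.pooling = saved
    return out


def encode_molecule(mol: Molecule, encoder: MoleculeEncoder) -> np.ndarray:
    """Full encoder pass for a single molecule: d-dimensional embedding."""
    return encoder.encode_molecules([mol])[0]
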