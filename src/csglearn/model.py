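"""The CSGL model: reaction-aware molecule representation learning.

:class:`CSGLModel` is built from a reaction corpus and owns everything the
optimization needs — the parsed molecules, the atom featurizer, the chemical
synthesis graph, the batched molecular graphs and the trainable parameters.
``fit()`` runs Adam on the margin-based translational loss and returns a
:class:`CSGLResults` carrying the trained parameters, the per-epoch loss
curve, the refined node-embedding table and the downstream evaluation
helpers (product ranking, reaction features, molecule embeddings).

Training uses a vectorized autodiff forward pass; the returned results
object recomputes node embeddings through the reference NumPy path in
:mod:`csglearn.embedding`, so inference is independent of the training
internals (the two are cross-checked in the test-suite).
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, glorot_uniform, spmm
from .chem import (
    AtomFeaturizer,
    BondTypeVocabulary,
    Molecule,
    Reaction,
    default_bond_type_vocabulary,
    parse_molecule,
    read_reaction_file,
)
from .embedding import (
    CSGNNParams,
    NodeEmbeddingTable,
    RelationParams,
    csgnn_propagate,
    read,
    relation_embedding,
)
from .encoder import BatchedGraph, EncoderConfig, MoleculeEncoder, segment_softmax
from .graph import CSG, build_csg, member_key, transformation_features
from .objective import TrainConfig, batch_loss_tensor, total_loss

__all__ = ["CSGLModel", "CSGLResults"]


class CSGLModel:
    """Translational-distance model over a chemical synthesis graph.

    Parameters
    ----------
    reactions : sequence of Reaction or reaction-SMILES strings
        The training corpus; the CSG is built from it.
    encoder_config : EncoderConfig, optional
        Molecule-encoder architecture (default: 2-layer GCN, d=64, sum pool).
    train_config : TrainConfig, optional
        Margin, regularization and Adam settings.
    with_csgnn : bool
        If False, train the CSGNN-free variant (pure READ node embeddings),
        the configuration used for transfer to classification/property tasks.
    csgnn_layers : int
        Number H of CSGNN aggregation layers (default 1).
    """

    def __init__(
        self,
        reactions: Sequence[Reaction | str],
        encoder_config: EncoderConfig | None = None,
        train_config: TrainConfig | None = None,
        with_csgnn: bool = True,
        csgnn_layers: int = 1,
        bond_vocab: BondTypeVocabulary | None = None,
    ):
        from .chem import parse_reaction

        self.reactions = [
            r if isinstance(r, Reaction) else parse_reaction(r) for r in reactions
        ]
        if len(self.reactions) < 2:
            raise ValueError("need at least 2 reactions to train")
        self.encoder_config = encoder_config or EncoderConfig()
        self.train_config = train_config or TrainConfig()
        self.encoder_config.validate()
        self.train_config.validate()
        self.bond_vocab = bond_vocab or default_bond_type_vocabulary()
        self.csgnn_layers = int(csgnn_layers) if with_csgnn else 0
        if self.csgnn_layers < 0:
            raise ValueError("csgnn_layers must be >= 0")

        # distinct molecules across the corpus
        self._mol_index: dict[str, int] = {}
        self.molecules: list[Molecule] = []
        for rxn in self.reactions:
            for mol in (*rxn.reactants, *rxn.products):
                if mol.canonical_id not in self._mol_index:
                    self._mol_index[mol.canonical_id] = len(self.molecules)
                    self.molecules.append(mol)
        self.featurizer = AtomFeaturizer.from_molecules(self.molecules)
        self.csg: CSG = build_csg(self.reactions, self.bond_vocab)

        rng = np.random.default_rng(self.train_config.seed)
        self.encoder = MoleculeEncoder(self.encoder_config, self.featurizer, rng)
        self.params: dict[str, Tensor] = dict(self.encoder.params)
        d = self.encoder_config.hidden_dim
        self.params["rel.E"] = Tensor(
            glorot_uniform(rng, (2 + self.bond_vocab.size, d))
        )
        for h in range(self.csgnn_layers):
            self.params[f"csgnn.att_{h}"] = Tensor(glorot_uniform(rng, (d, 1)))

        self._build_static_structures()

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "CSGLModel":
        """Build the model from a reaction file (see chem.read_reaction_file)."""
        return cls(read_reaction_file(path), **kwargs)

    # ---------------------------------------------------------------- static
    def _build_static_structures(self) -> None:
        import scipy.sparse as sp

        self.batch = BatchedGraph(self.molecules, self.featurizer)
        n_nodes, n_mols = self.csg.num_nodes, len(self.molecules)
        rows, cols, vals = [], [], []
        for node in self.csg.nodes:
            for mol in node.members:
                rows.append(node.node_id)
                cols.append(self._mol_index[mol.canonical_id])
                vals.append(1.0)
        self._node_member = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n_nodes, n_mols)
        )
        # per-reaction node indices and delta vectors
        self._rxn_r = np.array([e.source for e in self.csg.edges], dtype=np.intp)
        self._rxn_p = np.array([e.target for e in self.csg.edges], dtype=np.intp)
        self._rxn_tf = np.stack([e.features.vector() for e in self.csg.edges])
        # both-direction incidences sorted by center for segment softmax
        centers, nbrs, tf_rows = [], [], []
        for edge in self.csg.edges:
            vec = edge.features.vector()
            centers += [edge.source, edge.target]
            nbrs += [edge.target, edge.source]
            tf_rows += [vec, -vec]
        if centers:
            centers = np.asarray(centers, dtype=np.intp)
            nbrs = np.asarray(nbrs, dtype=np.intp)
            tf_rows = np.stack(tf_rows)
            order = np.argsort(centers, kind="stable")
            self._inc_center = centers[order]
            self._inc_nbr = nbrs[order]
            self._inc_tf = tf_rows[order]
            uniq, group_starts = np.unique(self._inc_center, return_index=True)
            self._inc_group_starts = group_starts.astype(np.intp)
            self._inc_group_ids = (
                np.searchsorted(uniq, self._inc_center).astype(np.intp)
            )
            n_inc = len(self._inc_center)
            self._inc_group_scatter = sp.csr_matrix(
                (np.ones(n_inc), (self._inc_group_ids, np.arange(n_inc))),
                shape=(len(uniq), n_inc),
            )
            self._inc_node_scatter = sp.csr_matrix(
                (np.ones(n_inc), (self._inc_center, np.arange(n_inc))),
                shape=(self.csg.num_nodes, n_inc),
            )
        else:  # pragma: no cover - build_csg guarantees edges
            self._inc_center = np.zeros(0, dtype=np.intp)

    # --------------------------------------------------------------- forward
    def _forward_nodes(self) -> tuple[Tensor, Tensor]:
        """(final node table, relation basis) as autodiff tensors."""
        mol_embs = self.encoder.encode_batch(self.batch)
        base = spmm(self._node_member, mol_embs)
        layers = [base]
        for h in range(self.csgnn_layers):
            prev = layers[-1]
            t_inc = Tensor(self._inc_tf) @ self.params["rel.E"]
            center = prev.gather_rows(self._inc_center)
            nbr = prev.gather_rows(self._inc_nbr)
            logits = (center * nbr * t_inc) @ self.params[f"csgnn.att_{h}"]
            att = segment_softmax(
                logits,
                self._inc_group_starts,
                self._inc_group_ids,
                self._inc_group_scatter,
            )
            update = spmm(self._inc_node_scatter, att * nbr)
            layers.append(prev + update)
        final = layers[0]
        for layer in layers[1:]:
            final = final + layer
        final = final * (1.0 / len(layers))
        return final, self.params["rel.E"]

    def loss_on(self, reaction_idx: np.ndarray) -> Tensor:
        """Total (regularized) autodiff loss on a batch of reaction indices."""
        return self._loss_and_terms(np.asarray(reaction_idx, dtype=np.intp))[0]

    def _loss_and_terms(self, idx: np.ndarray) -> tuple[Tensor, float, float]:
        """(total loss tensor, positive term, negative term) for one batch."""
        final, rel = self._forward_nodes()
        r = final.gather_rows(self._rxn_r[idx])
        p = final.gather_rows(self._rxn_p[idx])
        t = Tensor(self._rxn_tf[idx]) @ rel
        loss = batch_loss_tensor(r, t, p, self.train_config.margin)
        total = total_loss(loss, self.params.values(), self.train_config.l2_lambda)
        pos, neg = self._terms_numpy(r.data, t.data, p.data)
        return total, pos, neg

    def _terms_numpy(
        self, r: np.ndarray, t: np.ndarray, p: np.ndarray
    ) -> tuple[float, float]:
        resid = np.linalg.norm(r + t - p, axis=1)
        pos = float(resid.mean())
        b = r.shape[0]
        if b < 2:
            return pos, 0.0
        q = r + t
        dist = np.sqrt(
            np.maximum(
                (q**2).sum(1)[:, None] - 2 * q @ p.T + (p**2).sum(1)[None, :], 0.0
            )
        )
        hinge = np.maximum(self.train_config.margin - dist, 0.0)
        np.fill_diagonal(hinge, 0.0)
        return pos, float(hinge.sum() / (b * b - b))

    # ------------------------------------------------------------------- fit
    def fit(
        self,
        disp: int = 0,
        valid_reactions: Sequence[Reaction] | None = None,
        eval_every: int = 0,
        log_path: str | Path | None = None,
    ) -> "CSGLResults":
        """Optimize all parameters with Adam; returns a results object.

        ``valid_reactions`` with ``eval_every > 0`` records validation MRR on
        the per-epoch log. Training is deterministic for a fixed seed.
        """
        cfg = self.train_config
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self.params, lr=cfg.learning_rate)
        n = len(self.reactions)
        history = []
        t0 = time.perf_counter()
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_pos, epoch_neg, epoch_tot, n_batches = 0.0, 0.0, 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                opt.zero_grad()
                loss, pos, neg = self._loss_and_terms(idx)
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {loss.item()}"
                    )
                loss.backward()
                opt.step()
                epoch_pos += pos
                epoch_neg += neg
                epoch_tot += loss.item()
                n_batches += 1
            row = {
                "epoch": epoch,
                "pos_mean": epoch_pos / n_batches,
                "neg_mean": epoch_neg / n_batches,
                "total_loss": epoch_tot / n_batches,
            }
            if valid_reactions is not None and eval_every and (epoch + 1) % eval_every == 0:
                from .tasks import evaluate_product_prediction

                row["valid_mrr"] = evaluate_product_prediction(
                    valid_reactions, self._results_snapshot()
                ).mrr
            history.append(row)
            if disp and (epoch % disp == 0 or epoch == cfg.epochs - 1):
                print(
                    f"epoch {epoch:4d}  loss {row['total_loss']:.4f}  "
                    f"pos {row['pos_mean']:.4f}  neg {row['neg_mean']:.4f}"
                )
        fit_seconds = time.perf_counter() - t0
        results = self._results_snapshot()
        results.loss_history = pd.DataFrame(history)
        results.fit_seconds = fit_seconds
        if log_path is not None:
            results.loss_history.to_csv(log_path, sep="\t", index=False)
        return results

    def _results_snapshot(self) -> "CSGLResults":
        rel = RelationParams(self.params["rel.E"].data.copy())
        csgnn = CSGNNParams(
            [
                self.params[f"csgnn.att_{h}"].data[:, 0].copy()
                for h in range(self.csgnn_layers)
            ]
        )
        mol_embs = self.encoder.encode_molecules(self.molecules)
        base = self._node_member @ mol_embs
        table = csgnn_propagate(self.csg, base, rel, csgnn)
        return CSGLResults(
            encoder=self.encoder,
            bond_vocab=self.bond_vocab,
            rel_params=rel,
            csgnn_params=csgnn,
            node_keys=[node.member_key for node in self.csg.nodes],
            node_table=table,
            model=self,
        )


class CSGLResults:
    """Fitted CSGL parameters plus downstream evaluation helpers."""

    def __init__(
        self,
        encoder: MoleculeEncoder,
        bond_vocab: BondTypeVocabulary,
        rel_params: RelationParams,
        csgnn_params: CSGNNParams,
        node_keys: Sequence[str],
        node_table: NodeEmbeddingTable,
        loss_history: pd.DataFrame | None = None,
        model: CSGLModel | None = None,
    ):
        self.encoder = encoder
        self.bond_vocab = bond_vocab
        self.rel_params = rel_params
        self.csgnn_params = csgnn_params
        self.node_keys = list(node_keys)
        self.node_table = node_table
        self._key_to_row = {k: i for i, k in enumerate(self.node_keys)}
        self.loss_history = loss_history
        self.model = model
        self.fit_seconds: float | None = None
        self._emb_cache: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------ embeddings
    def encode_molecules(self, mols: Sequence[Molecule | str]) -> np.ndarray:
        """Embeddings of molecules (SMILES accepted), cached by canonical id."""
        parsed = [m if isinstance(m, Molecule) else parse_molecule(m) for m in mols]
        missing = [m for m in parsed if m.canonical_id not in self._emb_cache]
        if missing:
            embs = self.encoder.encode_molecules(missing)
            for mol, emb in zip(missing, embs):
                self._emb_cache[mol.canonical_id] = emb
        return np.stack([self._emb_cache[m.canonical_id] for m in parsed])

    def side_embedding(self, mols: Sequence[Molecule], refined: bool = True) -> np.ndarray:
        """Embedding of one molecule multiset.

        Sides present in the training CSG use the CSGNN-refined node table;
        unseen sides (and all sides when ``refined=False``) fall back to READ
        over freshly encoded molecules.
        """
        if refined:
            row = self._key_to_row.get(member_key(mols))
            if row is not None:
                return self.node_table.final[row]
        return read(list(self.encode_molecules(list(mols))))

    def embed_reaction_sides(
        self, rxn: Reaction
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(R, P, T) embeddings of one reaction under the fitted model."""
        r = self.side_embedding(rxn.reactants)
        p = self.side_embedding(rxn.products)
        t = relation_embedding(
            transformation_features(rxn, self.bond_vocab), self.rel_params
        )
        return r, p, t

    def reaction_feature(self, rxn: Reaction) -> np.ndarray:
        """Concatenated (READ reactants ‖ READ products) feature, length 2d."""
        r = read(list(self.encode_molecules(list(rxn.reactants))))
        p = read(list(self.encode_molecules(list(rxn.products))))
        return np.concatenate([r, p])

    # ------------------------------------------------------------ evaluation
    def evaluate_product_prediction(self, test_reactions: Sequence[Reaction]):
        from .tasks import evaluate_product_prediction

        return evaluate_product_prediction(test_reactions, self)

    # ----------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: config, vocabularies, weights, node table."""
        cfg = self.encoder.config
        meta = {
            "encoder_config": vars(cfg),
            "elements": list(self.encoder.featurizer.elements),
            "bond_vocab": [
                {"elem_a": bt.elem_a, "elem_b": bt.elem_b, "order": bt.order}
                for bt in self.bond_vocab.entries
            ],
            "csgnn_layers": self.csgnn_params.num_layers,
            "node_keys": self.node_keys,
        }
        arrays = {f"enc::{k}": v.data for k, v in self.encoder.params.items()}
        arrays["rel.E"] = self.rel_params.matrix
        for h, w in enumerate(self.csgnn_params.attention_weights):
            arrays[f"csgnn.att_{h}"] = w
        arrays["node_final"] = self.node_table.final
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "CSGLResults":
        """Load a checkpoint; fails loudly on config/vocabulary mismatch."""
        from .chem import BondType

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = EncoderConfig(**meta["encoder_config"])
            featurizer = AtomFeaturizer(meta["elements"])
            encoder = MoleculeEncoder(cfg, featurizer, np.random.default_rng(0))
            encoder.load_params(
                {k[len("enc::") :]: data[k] for k in data.files if k.startswith("enc::")}
            )
            rel = RelationParams(data["rel.E"])
            vocab = BondTypeVocabulary(
                [BondType(d["elem_a"], d["elem_b"], d["order"]) for d in meta["bond_vocab"]]
            )
            if rel.vocab_size != vocab.size:
                raise ValueError(
                    "checkpoint inconsistent: relation basis does not match "
                    "its bond-type vocabulary"
                )
            csgnn = CSGNNParams(
                [data[f"csgnn.att_{h}"] for h in range(meta["csgnn_layers"])]
            )
            node_final = data["node_final"]
        return cls(
            encoder=encoder,
            bond_vocab=vocab,
            rel_params=rel,
            csgnn_params=csgnn,
            node_keys=meta["node_keys"],
            node_table=NodeEmbeddingTable([node_final]),
        )

    # --------------------------------------------------------------- summary
    def summary(self) -> str:
        cfg = self.encoder.config
        n_params = sum(p.data.size for p in self.encoder.params.values())
        n_params += self.rel_params.matrix.size
        n_params += sum(w.size for w in self.csgnn_params.attention_weights)
        lines = [
            "CSGL model results",
            "=" * 46,
            f"{'molecule encoder':<28}{cfg.gnn_type.upper()} ({cfg.num_layers} layers)",
            f"{'pooling':<28}{cfg.pooling}",
            f"{'embedding dim d':<28}{cfg.hidden_dim}",
            f"{'CSGNN layers H':<28}{self.csgnn_params.num_layers}",
            f"{'bond-type vocabulary':<28}{self.bond_vocab.size}",
            f"{'CSG nodes':<28}{len(self.node_keys)}",
            f"{'trainable parameters':<28}{n_params}",
        ]
        if self.model is not None:
            tc = self.model.train_config
            lines += [
                f"{'reactions (train)':<28}{len(self.model.reactions)}",
                f"{'distinct molecules':<28}{len(self.model.molecules)}",
                f"{'margin γ':<28}{tc.margin}",
                f"{'L2 λ':<28}{tc.l2_lambda}",
                f"{'learning rate':<28}{tc.learning_rate}",
                f"{'epochs × batch':<28}{tc.epochs} × {tc.batch_size}",
            ]
        if self.loss_history is not None and len(self.loss_history):
            last = self.loss_history.iloc[-1]
            lines.append(f"{'final training loss':<28}{last['total_loss']:.4f}")
        if self.fit_seconds is not None:
            lines.append(f"{'fit time (s)':<28}{self.fit_seconds:.1f}")
        lines.append("=" * 46)
        return "\n".join(lines)
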