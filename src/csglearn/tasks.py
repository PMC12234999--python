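"""Downstream evaluation: product ranking, reaction classification, properties.

Product prediction is a ranking problem: for each test reaction the reactant
side is scored against every distinct product set occurring in the test split
(negated translational distance), and the rank of the true product yields MRR
and Hit@K.  Tie-breaking is pessimistic — equal-scoring distractors are
placed ahead of the true product.

Reaction classification follows the transfer protocol: a CSGNN-free model
provides frozen concatenated (reactant ‖ product) READ features and a small
MLP head predicts the class; precision/recall are macro-averaged.  Property
prediction fits a logistic regression on frozen molecule embeddings and
reports ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .chem import Molecule, Reaction
from .graph import member_key
from .model import CSGLModel, CSGLResults

__all__ = [
    "SplitSpec",
    "RankingResult",
    "split_dataset",
    "train_model",
    "rank_products",
    "evaluate_product_prediction",
    "reaction_feature",
    "classify_reactions",
    "predict_properties",
    "evaluate_property_prediction",
]


@dataclass(frozen=True)
class SplitSpec:
    """Random train/valid/test partition (default 80/10/10, seeded)."""

    train_frac: float = 0.8
    valid_frac: float = 0.1
    test_frac: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if abs(self.train_frac + self.valid_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(items: Sequence, spec: SplitSpec = SplitSpec()):
    """Partition items into (train, valid, test); rounding favors train."""
    n = len(items)
    if n < 10:
        raise ValueError(f"need at least 10 items to split, got {n}")
    order = np.random.default_rng(spec.seed).permutation(n)
    n_valid = int(np.floor(n * spec.valid_frac))
    n_test = int(np.floor(n * spec.test_frac))
    n_train = n - n_valid - n_test
    take = lambda idx: [items[i] for i in idx]
    return (
        take(order[:n_train]),
        take(order[n_train : n_train + n_valid]),
        take(order[n_train + n_valid :]),
    )


@dataclass
class RankingResult:
    """Per-query ranks with the aggregate MRR / Hit@K metrics."""

    ranks: list[int]
    mrr: float = field(init=False)
    hits: dict[int, float] = field(init=False)

    def __post_init__(self):
        ranks = np.asarray(self.ranks, dtype=np.float64)
        if len(ranks) == 0 or np.any(ranks < 1):
            raise ValueError("ranks must be a non-empty list of positive integers")
        self.mrr = float(np.mean(1.0 / ranks))
        self.hits = {k: float(np.mean(ranks <= k)) for k in (1, 3, 5)}

    def as_dict(self) -> dict[str, float]:
        out = {"mrr": self.mrr}
        out.update({f"hit@{k}": v for k, v in self.hits.items()})
        return out


def train_model(
    reactions: Sequence[Reaction],
    encoder_config=None,
    train_config=None,
    with_csgnn: bool = True,
    **fit_kwargs,
) -> CSGLResults:
    """Build and fit a CSGL model (CSGNN-free when ``with_csgnn=False``)."""
    model = CSGLModel(
        reactions,
        encoder_config=encoder_config,
        train_config=train_config,
        with_csgnn=with_csgnn,
    )
    return model.fit(**fit_kwargs)


# ------------------------------------------------------------------ ranking
def _candidate_matrix(
    candidates: Sequence[tuple[Molecule, ...]], results: CSGLResults
) -> np.ndarray:
    return np.stack([results.side_embedding(c) for c in candidates])


def rank_products(
    query: Reaction,
    candidates: Sequence[tuple[Molecule, ...]],
    results: CSGLResults,
) -> int:
    """Pessimistic rank of the true product among candidate product sets."""
    keys = [member_key(c) for c in candidates]
    true_key = member_key(query.products)
    if true_key not in keys:
        raise ValueError("true product set is not among the candidates")
    true_pos = keys.index(true_key)
    r_emb, _, t_emb = results.embed_reaction_sides(query)
    p_embs = _candidate_matrix(candidates, results)
    scores = -np.linalg.norm(r_emb + t_emb - p_embs, axis=1)
    true_score = scores[true_pos]
    strictly_higher = int(np.sum(scores > true_score))
    ties = int(np.sum(scores == true_score)) - 1  # excluding the true product
    return 1 + strictly_higher + ties


def evaluate_product_prediction(
    test_reactions: Sequence[Reaction], results: CSGLResults
) -> RankingResult:
    """MRR / Hit@K over a test split.

    The candidate pool is every product set occurring in the test split,
    deduplicated by canonical multiset key (the CSG node-identity rule).
    """
    pool: dict[str, tuple[Molecule, ...]] = {}
    for rxn in test_reactions:
        pool.setdefault(member_key(rxn.products), rxn.products)
    keys = list(pool)
    candidates = [pool[k] for k in keys]
    key_pos = {k: i for i, k in enumerate(keys)}
    p_embs = _candidate_matrix(candidates, results)
    ranks = []
    for rxn in test_reactions:
        r_emb, _, t_emb = results.embed_reaction_sides(rxn)
        scores = -np.linalg.norm(r_emb + t_emb - p_embs, axis=1)
        true_score = scores[key_pos[member_key(rxn.products)]]
        ranks.append(1 + int(np.sum(scores > true_score)) + int(np.sum(scores == true_score)) - 1)
    return RankingResult(ranks)


# ----------------------------------------------------------- classification
def reaction_feature(rxn: Reaction, results: CSGLResults) -> np.ndarray:
    """Frozen 2d-dim reaction feature: (READ reactants ‖ READ products)."""
    return results.reaction_feature(rxn)


def classify_reactions(
    train_reactions: Sequence[Reaction],
    test_reactions: Sequence[Reaction],
    results: CSGLResults,
    seed: int = 0,
    hidden_dim: int | None = None,
    max_iter: int = 2000,
) -> dict[str, float]:
    """MLP decoder on frozen reaction features; accuracy + macro P/R.

    Features are standardized, then a one-hidden-layer (width 2d, ReLU) MLP
    is trained with cross-entropy and early stopping on a held-out
    validation fraction.
    """
    y_train = np.array([r.class_label for r in train_reactions])
    y_test = np.array([r.class_label for r in test_reactions])
    if None in y_train or None in y_test:
        raise ValueError("all reactions need class labels for classification")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    x_train = np.stack([results.reaction_feature(r) for r in train_reactions])
    x_test = np.stack([results.reaction_feature(r) for r in test_reactions])
    width = hidden_dim or 2 * results.encoder.config.hidden_dim
    clf = make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=(width,),
            activation="relu",
            early_stopping=True,
            n_iter_no_change=50,
            max_iter=max_iter,
            random_state=seed,
        ),
    )
    clf.fit(x_train, y_train)
    y_pred = clf.predict(x_test)
    return {
        "accuracy": float(accuracy_score(y_test, y_pred)),
        "precision_macro": float(
            precision_score(y_test, y_pred, average="macro", zero_division=0)
        ),
        "recall_macro": float(
            recall_score(y_test, y_pred, average="macro", zero_division=0)
        ),
    }


# --------------------------------------------------------------- properties
def predict_properties(
    embeddings: np.ndarray, labels: Sequence[int], spec: SplitSpec = SplitSpec()
) -> float:
    """Logistic regression on frozen molecule embeddings; returns test AUC."""
    labels = np.asarray(labels, dtype=int)
    idx_train, _, idx_test = split_dataset(list(range(len(labels))), spec)
    y_test = labels[idx_test]
    if len(np.unique(y_test)) < 2:
        raise ValueError("test split is single-class; AUC undefined")
    clf = make_pipeline(
        StandardScaler(), LogisticRegression(max_iter=2000, random_state=spec.seed)
    )
    clf.fit(embeddings[idx_train], labels[idx_train])
    scores = clf.decision_function(embeddings[idx_test])
    return float(roc_auc_score(y_test, scores))


def evaluate_property_prediction(
    data: Sequence[tuple[Molecule, int]],
    results: CSGLResults,
    spec: SplitSpec = SplitSpec(),
) -> float:
    """Property-prediction AUC from (molecule, binary label) pairs."""
    mols = [m for m, _ in data]
    labels = [l for _, l in data]
    return predict_properties(results.encode_molecules(mols), labels, spec)
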