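"""READ, relation embeddings and CSGNN propagation (incl. nested-loop oracle)."""

import numpy as np
import pytest

from csglearn.chem import parse_reaction
from csglearn.embedding import (
    CSGNNParams,
    RelationParams,
    attention_weights,
    csgnn_propagate,
    read,
    relation_embedding,
)
from csglearn.graph import (
    TransformationFeatures,
    build_csg,
    neighbors,
    transformation_features,
)


def _rel_params(rng, vocab_size=15, d=6):
    return RelationParams(rng.normal(size=(2 + vocab_size, d)))


def test_read_is_sum(rng):
    vecs = [rng.normal(size=5) for _ in range(4)]
    np.testing.assert_allclose(read(vecs), np.sum(vecs, axis=0))
    np.testing.assert_allclose(read(vecs[::-1]), read(vecs))
    np.testing.assert_allclose(read([vecs[0]]), vecs[0])
    np.testing.assert_allclose(read([vecs[0], -vecs[0]]), np.zeros(5))
    with pytest.raises(ValueError):
        read([])


def test_relation_embedding_linearity(rng):
    rp = _rel_params(rng)
    zero = TransformationFeatures(0, 0, (0,) * 15)
    np.testing.assert_array_equal(relation_embedding(zero, rp), np.zeros(6))
    bond_only = TransformationFeatures(1, 0, (0,) * 15)
    np.testing.assert_allclose(relation_embedding(bond_only, rp), rp.e_bond)
    for _ in range(10):
        d1 = rng.integers(-4, 5, size=17)
        d2 = rng.integers(-4, 5, size=17)
        a, b = int(rng.integers(-3, 4)), int(rng.integers(-3, 4))
        t1 = TransformationFeatures(int(d1[0]), int(d1[1]), tuple(d1[2:]))
        t2 = TransformationFeatures(int(d2[0]), int(d2[1]), tuple(d2[2:]))
        combo = a * d1 + b * d2
        tc = TransformationFeatures(int(combo[0]), int(combo[1]), tuple(combo[2:]))
        np.testing.assert_allclose(
            relation_embedding(tc, rp),
            a * relation_embedding(t1, rp) + b * relation_embedding(t2, rp),
            atol=1e-10,
        )
    negated = TransformationFeatures(2, -1, tuple(rng.integers(-2, 3, size=15)))
    np.testing.assert_allclose(
        relation_embedding(-negated, rp), -relation_embedding(negated, rp)
    )


def test_relation_embedding_vocab_mismatch(rng):
    rp = _rel_params(rng, vocab_size=3)
    tf = TransformationFeatures(0, 0, (0,) * 15)
    with pytest.raises(ValueError, match="vocabulary mismatch"):
        relation_embedding(tf, rp)


def test_attention_weights_contract(rng):
    d = 6
    w = rng.normal(size=d)
    center = rng.normal(size=d)
    single = attention_weights(center, [rng.normal(size=d)], [rng.normal(size=d)], w)
    np.testing.assert_allclose(single, [1.0])
    nb = rng.normal(size=d)
    rel = rng.normal(size=d)
    twins = attention_weights(center, [nb, nb], [rel, rel], w)
    np.testing.assert_allclose(twins, [0.5, 0.5])
    many = attention_weights(
        center,
        [rng.normal(size=d) for _ in range(7)],
        [rng.normal(size=d) for _ in range(7)],
        w,
    )
    assert np.all(many >= 0)
    assert abs(many.sum() - 1.0) < 1e-6
    assert attention_weights(center, [], [], w).size == 0


def _toy_csg(vocab):
    rxns = [
        parse_reaction("CCO>>CC=O", reaction_id="r0"),
        parse_reaction("CC=O>>CC(=O)O", reaction_id="r1"),
        parse_reaction("CCCO>>CC=O", reaction_id="r2"),
        parse_reaction("CC(=O)O.OCC>>CC(=O)OCC.O", reaction_id="r3"),
    ]
    return build_csg(rxns, vocab)


def test_h0_propagation_is_read_table(rng, vocab):
    csg = _toy_csg(vocab)
    base = rng.normal(size=(csg.num_nodes, 6))
    table = csgnn_propagate(csg, base, _rel_params(rng), CSGNNParams([]))
    np.testing.assert_array_equal(table.final, base)


def test_isolated_node_keeps_read_embedding(rng, vocab):
    rxns = [
        parse_reaction("CCO>>CC=O", reaction_id="a"),
        parse_reaction("NCCC>>C=CCC", reaction_id="b"),
    ]
    csg = build_csg(rxns, vocab)
    base = rng.normal(size=(csg.num_nodes, 4))
    rp = RelationParams(rng.normal(size=(17, 4)))
    cp = CSGNNParams([rng.normal(size=4), rng.normal(size=4)])
    table = csgnn_propagate(csg, base, rp, cp)
    # every node here has exactly one neighbor, but an artificially isolated
    # node (empty adjacency) must keep its layer-0 embedding
    csg.adjacency[0] = []
    table2 = csgnn_propagate(csg, base, rp, cp)
    np.testing.assert_allclose(table2.final[0], base[0])
    assert table.layers[0] is not table.final


def test_two_node_hand_derivation(rng, vocab):
    """A→B with H=1: final(A) = (A0 + (A0 + 1.0·B0)) / 2."""
    csg = build_csg([parse_reaction("CCO>>CC=O", reaction_id="x")], vocab)
    base = rng.normal(size=(2, 5))
    rp = RelationParams(rng.normal(size=(17, 5)))
    cp = CSGNNParams([rng.normal(size=5)])
    table = csgnn_propagate(csg, base, rp, cp)
    np.testing.assert_allclose(table.final[0], (base[0] + base[0] + base[1]) / 2.0)
    np.testing.assert_allclose(table.final[1], (base[1] + base[1] + base[0]) / 2.0)


def test_nested_loop_oracle_matches_propagation(rng, vocab):
    """Independent nested-loop evaluation of the propagation recurrences."""
    csg = _toy_csg(vocab)
    assert csg.num_nodes <= 6
    d = 5
    base = rng.normal(size=(csg.num_nodes, d))
    rp = RelationParams(rng.normal(size=(17, d)))
    cp = CSGNNParams([rng.normal(size=d), rng.normal(size=d)])

    # --- oracle: literal recurrences, one scalar softmax at a time
    layers = [base.copy()]
    for h in range(cp.num_layers):
        prev, nxt = layers[-1], layers[-1].copy()
        for v in range(csg.num_nodes):
            nbrs = neighbors(csg, v)
            if not nbrs:
                continue
            logits = []
            for u, tf in nbrs:
                t = tf.vector() @ rp.matrix
                logits.append(cp.attention_weights[h] @ (prev[v] * prev[u] * t))
            logits = np.array(logits)
            w = np.exp(logits - logits.max())
            w /= w.sum()
            agg = np.zeros(d)
            for (u, _), wj in zip(nbrs, w):
                agg += wj * prev[u]
            nxt[v] = prev[v] + agg
        layers.append(nxt)
    oracle_final = np.mean(layers, axis=0)

    table = csgnn_propagate(csg, base, rp, cp)
    np.testing.assert_allclose(table.final, oracle_final, atol=1e-5)


def test_attention_rows_sum_to_one_on_fixture(rng, vocab):
    csg = _toy_csg(vocab)
    rp = _rel_params(rng, d=6)
    w = rng.normal(size=6)
    base = rng.normal(size=(csg.num_nodes, 6))
    for v in range(csg.num_nodes):
        nbrs = neighbors(csg, v)
        if not nbrs:
            continue
        rels = [relation_embedding(tf, rp) for _, tf in nbrs]
        weights = attention_weights(base[v], [base[u] for u, _ in nbrs], rels, w)
        assert abs(weights.sum() - 1.0) < 1e-6
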