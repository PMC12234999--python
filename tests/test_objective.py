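"""Translational distance, margin loss and gradient correctness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from csglearn.autodiff import Tensor, finite_difference_grad
from csglearn.objective import (
    TrainConfig,
    batch_loss,
    batch_loss_tensor,
    match_score,
    total_loss,
    translation_distance,
)


def test_translation_distance_examples(rng):
    r, t = rng.normal(size=4), rng.normal(size=4)
    assert translation_distance(r, t, r + t) == pytest.approx(0.0)
    e = np.zeros(4)
    e[0] = 1.0
    assert translation_distance(np.zeros(4), np.zeros(4), e) == pytest.approx(1.0)
    p = rng.normal(size=4)
    assert translation_distance(r, t, p) == pytest.approx(
        translation_distance(-r, -t, -p)
    )
    with pytest.raises(ValueError):
        translation_distance(np.zeros(3), np.zeros(4), np.zeros(4))


def test_match_score_orders_by_distance(rng):
    r, t = rng.normal(size=6), rng.normal(size=6)
    cands = [rng.normal(size=6) for _ in range(12)] + [r + t]
    scores = [match_score(r, t, p) for p in cands]
    dists = [translation_distance(r, t, p) for p in cands]
    assert np.argmax(scores) == len(cands) - 1
    assert scores[-1] == pytest.approx(0.0)
    assert all(s <= 0 for s in scores)
    np.testing.assert_array_equal(np.argsort(scores), np.argsort(dists)[::-1])


def test_batch_loss_zero_embedding_hand_value():
    """Two zero triples with margin 4: positive 0, negative (4+4)/2 = 4."""
    z = np.zeros(8)
    assert batch_loss([(z, z, z), (z, z, z)], margin=4.0) == pytest.approx(4.0)


def test_batch_loss_perfect_and_separated_batch(rng):
    d, margin = 5, 1.0
    triples = []
    for i in range(4):
        r = rng.normal(size=d) + 10.0 * i  # clusters far apart
        t = rng.normal(size=d)
        triples.append((r, t, r + t))
    assert batch_loss(triples, margin) == pytest.approx(0.0)


def test_batch_loss_order_invariant_and_single(rng):
    triples = [
        (rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)) for _ in range(5)
    ]
    v1 = batch_loss(triples, 2.0)
    v2 = batch_loss(triples[::-1], 2.0)
    assert v1 == pytest.approx(v2)
    single = batch_loss(triples[:1], 2.0)
    assert single == pytest.approx(
        translation_distance(*triples[0])
    )  # no negative term
    assert v1 >= 0


def test_batch_loss_translation_invariance(rng):
    triples = [
        (rng.normal(size=4), rng.normal(size=4), rng.normal(size=4)) for _ in range(4)
    ]
    c = rng.normal(size=4)
    shifted = [(r + c, t, p + c) for r, t, p in triples]
    assert batch_loss(shifted, 3.0) == pytest.approx(batch_loss(triples, 3.0))


def test_tensor_batch_loss_matches_reference(rng):
    b, d = 6, 5
    r, t, p = (rng.normal(size=(b, d)) for _ in range(3))
    ref = batch_loss([(r[i], t[i], p[i]) for i in range(b)], margin=4.0)
    vec = batch_loss_tensor(Tensor(r), Tensor(t), Tensor(p), margin=4.0)
    assert vec.item() == pytest.approx(ref, rel=1e-10)


def test_total_loss_regularizer(rng):
    params = [rng.normal(size=(3, 2)), rng.normal(size=4)]
    base = 1.5
    assert total_loss(base, params, 0.0) == pytest.approx(base)
    norm2 = sum(float(np.sum(p**2)) for p in params)
    assert total_loss(base, params, 0.1) == pytest.approx(base + 0.1 * norm2)
    assert total_loss(base, params, 0.2) - base == pytest.approx(
        2 * (total_loss(base, params, 0.1) - base)
    )
    assert total_loss(base, [], 0.5) == pytest.approx(base)


def test_total_loss_gradient_matches_finite_difference(rng):
    """Four-triple toy batch: autodiff vs central differences, rel err < 1e-4."""
    b, d = 4, 3
    r = Tensor(rng.normal(size=(b, d)))
    t = Tensor(rng.normal(size=(b, d)))
    p = Tensor(rng.normal(size=(b, d)))

    def loss():
        return total_loss(batch_loss_tensor(r, t, p, margin=4.0), [r, t, p], 0.01)

    for param in (r, t, p):
        value = loss()
        value.backward()
        ad = param.grad.copy()
        fd = finite_difference_grad(loss, param)
        assert np.abs(ad - fd).max() / max(np.abs(fd).max(), 1e-8) < 1e-4
        for tensor in (r, t, p):
            tensor.grad = None


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(margin=0.0).validate()
    with pytest.raises(ValueError):
        TrainConfig(l2_lambda=-1.0).validate()
    TrainConfig().validate()


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    deltas=hnp.arrays(np.int64, (3, 17), elements=st.integers(-5, 5)),
    coeffs=st.tuples(st.integers(-3, 3), st.integers(-3, 3)),
)
def test_relation_embedding_linear_property(deltas, coeffs):
    """T(a·tf1 + b·tf2) == a·T(tf1) + b·T(tf2) on random integer deltas."""
    from csglearn.embedding import RelationParams, relation_embedding
    from csglearn.graph import TransformationFeatures

    rp = RelationParams(np.random.default_rng(0).normal(size=(17, 4)))
    a, b = coeffs

    def tf(row):
        return TransformationFeatures(int(row[0]), int(row[1]), tuple(int(x) for x in row[2:]))

    combo = a * deltas[0] + b * deltas[1]
    np.testing.assert_allclose(
        relation_embedding(tf(combo), rp),
        a * relation_embedding(tf(deltas[0]), rp) + b * relation_embedding(tf(deltas[1]), rp),
        atol=1e-9,
    )
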