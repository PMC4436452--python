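"""MIMLwel: bag embedding, label relations, and the constrained fit."""

import numpy as np
import pytest

from conftest import make_bag
from weakmiml.bagdist import pairwise_bag_distances
from weakmiml.datamodel import LabelMatrix
from weakmiml.mimlwel import (
    MIMLwel,
    RelationMatrix,
    build_relation_matrix,
    embed,
    embed_many,
    fit_bag_embedding,
    fit_mimlwel,
    group_penalty,
    load_model,
    predict,
    save_model,
)


def _random_bags(m, rng, dim=3):
    return [
        make_bag(f"b{i}", rng.normal(size=(rng.integers(1, 4), dim)))
        for i in range(m)
    ]


# ---------------------------------------------------------------------------
# embedding


def test_cluster_count_follows_fraction():
    rng = np.random.default_rng(0)
    bags = _random_bags(20, rng)
    emb = fit_bag_embedding(bags, alpha=0.1, mu=1.0, seed=1)
    assert emb.K == 2
    assert emb.dim == 3


def test_cluster_count_floor_guard():
    rng = np.random.default_rng(1)
    bags = _random_bags(8, rng)
    emb = fit_bag_embedding(bags, alpha=0.01, mu=1.0, seed=1)
    assert emb.K == 1


def test_fraction_endpoint_at_proteome_scale():
    # 340 training bags at the published fraction 0.1 -> 34 clusters
    assert max(1, int(np.round(0.1 * 340))) == 34


def test_embedding_deterministic_given_seed():
    rng = np.random.default_rng(2)
    bags = _random_bags(15, rng)
    a = fit_bag_embedding(bags, alpha=0.3, mu=1.0, seed=7)
    b = fit_bag_embedding(bags, alpha=0.3, mu=1.0, seed=7)
    assert a.medoid_indices == b.medoid_indices
    assert a.delta == b.delta


def test_embed_coordinates_and_bias():
    rng = np.random.default_rng(3)
    bags = _random_bags(10, rng)
    emb = fit_bag_embedding(bags, alpha=0.2, mu=1.0, seed=0)
    phi = embed(emb, emb.medoids[0])
    assert phi[0] == pytest.approx(1.0)  # identical to medoid 0
    assert phi[-1] == 1.0  # bias
    assert phi.shape == (emb.K + 1,)
    # monotonicity witness: farther bag -> strictly smaller coordinate
    near = make_bag("near", emb.medoids[0].instances + 0.01)
    far = make_bag("far", emb.medoids[0].instances + 10.0)
    assert embed(emb, near)[0] > embed(emb, far)[0]


def test_embed_many_matches_embed():
    rng = np.random.default_rng(4)
    bags = _random_bags(12, rng)
    emb = fit_bag_embedding(bags, alpha=0.25, mu=0.7, seed=3)
    Phi = embed_many(emb, bags)
    for i, bag in enumerate(bags):
        np.testing.assert_allclose(Phi[i], embed(emb, bag))
    # precomputed-distance path agrees
    D = pairwise_bag_distances(bags)
    np.testing.assert_allclose(embed_many(emb, D_to_train=D), Phi)


def test_embedding_rejects_bad_parameters():
    rng = np.random.default_rng(5)
    bags = _random_bags(5, rng)
    with pytest.raises(ValueError):
        fit_bag_embedding(bags, alpha=0.0, mu=1.0)
    with pytest.raises(ValueError):
        fit_bag_embedding(bags, alpha=0.5, mu=-1.0)
    with pytest.raises(ValueError):
        fit_bag_embedding([], alpha=0.5, mu=1.0)


# ---------------------------------------------------------------------------
# relation matrix


def test_relation_matrix_cosine_cases():
    Y = LabelMatrix(
        np.array(
            [
                [1, 1, 0, 1],
                [1, 1, 0, 0],
                [0, 0, 1, 0],
            ]
        ),
        "observed",
    )
    R = build_relation_matrix(Y, tau=0.5)
    assert R.values[0, 1] == 1  # identical columns, cos = 1
    assert R.values[0, 2] == 0  # disjoint supports, cos = 0
    # cos([1,1,0],[1,0,0]) = 1/sqrt(2) ~ 0.707 >= 0.5
    assert R.values[0, 3] == 1
    assert np.array_equal(R.values, R.values.T)
    assert np.all(np.diag(R.values) == 0)


def test_relation_matrix_zero_column_unrelated():
    Y = LabelMatrix(np.array([[1, 0], [1, 0]]), "observed")
    R = build_relation_matrix(Y, tau=0.0)
    assert R.values[0, 1] == 0


def test_relation_matrix_invalid_tau():
    Y = LabelMatrix(np.array([[1]]), "observed")
    with pytest.raises(ValueError):
        build_relation_matrix(Y, tau=1.5)


# ---------------------------------------------------------------------------
# penalty


def test_group_penalty_matches_direct_summation():
    rng = np.random.default_rng(8)
    W = rng.normal(size=(6, 5))
    pairs = [(0, 2), (1, 4), (2, 3)]
    direct = 0.0
    for l, lt in pairs:
        s = sum(np.sqrt(W[r, l] ** 2 + W[r, lt] ** 2) for r in range(6))
        direct += s**2
    assert group_penalty(W, pairs) == pytest.approx(direct, abs=1e-6)


# ---------------------------------------------------------------------------
# fit


def _fit_setup(m=30, L=4, d=6, seed=0, density=0.4):
    rng = np.random.default_rng(seed)
    Phi = np.hstack([rng.random((m, d - 1)), np.ones((m, 1))])
    Yh = (rng.random((m, L)) < density).astype(int)
    Yh[0] = 1  # no empty columns
    return Phi, LabelMatrix(Yh, "observed")


def test_zero_budget_forces_no_correction():
    Phi, Yh = _fit_setup()
    R = build_relation_matrix(Yh, tau=0.5)
    model = fit_mimlwel(Phi, Yh, R, eta=1.0, epsilon=0.0)
    assert np.array_equal(model.Y_bar.values, Yh.values)


def test_decoupled_limit_matches_least_squares():
    # single label, no relations, zero budget: the smooth problem is plain
    # least squares with a closed-form normal-equations solution
    rng = np.random.default_rng(42)
    Phi = rng.normal(size=(20, 5))
    y = (rng.random(20) < 0.5).astype(int)
    y[0] = 1
    Yh = LabelMatrix(y[:, None], "observed")
    R = RelationMatrix(np.zeros((1, 1), dtype=int), 1.0)
    model = fit_mimlwel(Phi, Yh, R, eta=1.0, epsilon=0.0)
    t = 2.0 * y - 1.0
    w_star, *_ = np.linalg.lstsq(Phi, t, rcond=None)
    np.testing.assert_allclose(model.W[:, 0], w_star, atol=1e-4)


def test_decoupling_relations_off_equals_independent_fits():
    Phi, Yh = _fit_setup(m=25, L=3, seed=5)
    R0 = RelationMatrix(np.zeros((3, 3), dtype=int), 1.0)
    joint = fit_mimlwel(Phi, Yh, R0, eta=1.0, epsilon=0.0)
    for l in range(3):
        Yl = LabelMatrix(Yh.values[:, [l]], "observed")
        solo = fit_mimlwel(
            Phi, Yl, RelationMatrix(np.zeros((1, 1), dtype=int), 1.0),
            eta=1.0, epsilon=0.0,
        )
        np.testing.assert_allclose(joint.W[:, l], solo.W[:, 0], atol=1e-5)


def test_constraint_suite_after_fit():
    Phi, Yh = _fit_setup(m=30, L=5, seed=9)
    R = build_relation_matrix(Yh, tau=0.5)
    eps = 0.4
    model = fit_mimlwel(Phi, Yh, R, eta=1.0, epsilon=eps)
    Yb, Yo = model.Y_bar.values, Yh.values
    assert (Yb >= Yo).all()
    F = Phi @ model.W
    for l in range(5):
        flips = int(np.abs(Yb[:, l] - Yo[:, l]).sum())
        assert flips <= int(np.floor(eps * Yo[:, l].sum()))
        flipped = np.flatnonzero((Yb[:, l] == 1) & (Yo[:, l] == 0))
        assert (F[flipped, l] > 0).all()  # no flip where the score is <= 0
    # objective trace non-increasing
    assert all(a >= b - 1e-9 for a, b in zip(model.trace, model.trace[1:]))


def test_trace_non_increasing_with_relations():
    Phi, Yh = _fit_setup(m=30, L=6, seed=13, density=0.5)
    R = build_relation_matrix(Yh, tau=0.3)
    assert len(R.pairs()) > 0
    model = fit_mimlwel(Phi, Yh, R, eta=1.0, epsilon=0.3)
    assert all(a >= b - 1e-9 for a, b in zip(model.trace, model.trace[1:]))


def test_fit_rejects_bad_inputs():
    Phi, Yh = _fit_setup()
    R = build_relation_matrix(Yh, tau=0.5)
    with pytest.raises(ValueError):
        fit_mimlwel(Phi, Yh, R, eta=0.0)
    bad = Phi.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        fit_mimlwel(bad, Yh, R)


def test_scores_invariant_to_training_permutation():
    Phi, Yh = _fit_setup(m=24, L=3, seed=17)
    R = RelationMatrix(np.zeros((3, 3), dtype=int), 1.0)
    model = fit_mimlwel(Phi, Yh, R, eta=1.0, epsilon=0.0)
    perm = np.random.default_rng(1).permutation(24)
    model_p = fit_mimlwel(
        Phi[perm], LabelMatrix(Yh.values[perm], "observed"), R,
        eta=1.0, epsilon=0.0,
    )
    query = np.random.default_rng(2).normal(size=(5, Phi.shape[1]))
    np.testing.assert_allclose(query @ model.W, query @ model_p.W, atol=1e-5)


# ---------------------------------------------------------------------------
# prediction


def test_predict_zero_weights_all_negative():
    Phi, Yh = _fit_setup(m=10, L=2)
    R = RelationMatrix(np.zeros((2, 2), dtype=int), 1.0)
    model = fit_mimlwel(Phi, Yh, R, eta=1.0, epsilon=0.0)
    model.W = np.zeros_like(model.W)
    scores, binary = predict(model, embeddings=Phi)
    assert (scores == 0).all() and (binary == 0).all()
    assert scores.shape == (10, 2)


def test_separable_training_bag_predicted_positive():
    # two bags far apart, one label each; full pipeline via the estimator
    bags = [
        make_bag("a", [[0.0, 0.0]]),
        make_bag("b", [[10.0, 10.0]]),
        make_bag("a2", [[0.1, 0.0]]),
        make_bag("b2", [[10.0, 10.1]]),
    ]
    Y = LabelMatrix(np.array([[1, 0], [0, 1], [1, 0], [0, 1]]), "observed")
    est = MIMLwel(alpha=0.5, mu=1.0, epsilon=0.0, seed=0)
    est.fit(bags, Y)
    scores, binary = est.predict(bags)
    np.testing.assert_array_equal(binary, Y.values)


def test_unfitted_estimator_raises():
    with pytest.raises(ValueError):
        MIMLwel().predict([make_bag("a", [[0.0]])])


def test_model_roundtrip(tmp_path):
    bags = [
        make_bag("a", [[0.0, 0.0]]),
        make_bag("b", [[5.0, 5.0]]),
        make_bag("c", [[0.2, 0.1]]),
    ]
    Y = LabelMatrix(np.array([[1, 0], [0, 1], [1, 0]]), "observed")
    est = MIMLwel(alpha=0.5, seed=1)
    est.fit(bags, Y)
    p = tmp_path / "model.json"
    save_model(est.model_, p)
    again, _ = load_model(p)
    np.testing.assert_allclose(again.W, est.model_.W)
    scores_a, _ = predict(est.model_, bags)
    scores_b, _ = predict(again, bags)
    np.testing.assert_allclose(scores_a, scores_b)
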