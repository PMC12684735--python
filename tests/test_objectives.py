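"""Prediction heads, supervised losses, prototype contrastive losses (with
brute-force oracles), k-means partitioning, and the weighted total."""

import itertools

import numpy as np
import pytest

from molproto.nn import ParameterStore, Tensor
from molproto.objectives import (LossWeights, PredictionHeads,
                                 kmeans_partition, predict, predictive_loss,
                                 proto_contrastive_cls, proto_contrastive_reg,
                                 total_loss)


def make_heads(L, d_g, out_dim, seed=0):
    store = ParameterStore()
    heads = PredictionHeads(L, d_g, out_dim, store, np.random.default_rng(seed))
    return heads, store


def test_predict_is_mean_of_per_layer_heads():
    heads, store = make_heads(L=2, d_g=2, out_dim=2)
    store["heads.layer0.W"].data = np.zeros((2, 2))
    store["heads.layer0.b"].data = np.array([1.0, 3.0])
    store["heads.layer1.W"].data = np.zeros((2, 2))
    store["heads.layer1.b"].data = np.array([3.0, 5.0])
    out = predict([Tensor(np.zeros(2)), Tensor(np.zeros(2))], heads)
    assert np.allclose(out.data, [2.0, 4.0])


def test_predict_zero_heads_and_single_layer_passthrough():
    heads, store = make_heads(L=1, d_g=3, out_dim=2)
    store["heads.layer0.W"].data = np.zeros((3, 2))
    store["heads.layer0.b"].data = np.zeros(2)
    assert np.allclose(predict([Tensor(np.ones(3))], heads).data, 0.0)
    with pytest.raises(ValueError):
        predict([Tensor(np.ones(3))] * 2, heads)


def test_predictive_loss_uniform_softmax_is_ln2():
    for y in (0, 1):
        loss = predictive_loss(Tensor(np.zeros(2)), np.array([y]),
                               "classification")
        assert float(loss.data) == pytest.approx(np.log(2.0), rel=1e-9)


def test_predictive_loss_regression_values():
    exact = predictive_loss(Tensor(np.array([1.5])), np.array([1.5]),
                            "regression")
    assert float(exact.data) == pytest.approx(0.0)
    off = predictive_loss(Tensor(np.array([2.5])), np.array([1.5]),
                          "regression")
    assert float(off.data) == pytest.approx(1.0)


def test_predictive_loss_multitask_masks_missing_labels():
    logits = Tensor(np.array([[0.0, 100.0], [0.0, -100.0]]))
    y = np.array([[1.0, 0.0], [0.0, 1.0]])
    mask = np.array([[True, False], [True, False]])
    # only the first column is observed: BCE(0 logit, y=1) and BCE(0, y=0)
    loss = predictive_loss(logits, y, "multitask", mask)
    assert float(loss.data) == pytest.approx(np.log(2.0), rel=1e-9)
    with pytest.raises(ValueError):
        predictive_loss(logits, y, "multitask",
                        np.zeros_like(mask))


def test_single_task_unobserved_label_is_contract_error():
    with pytest.raises(ValueError):
        predictive_loss(Tensor(np.zeros(2)), np.array([0]),
                        "classification", np.array([False]))


def set_prototypes(values):
    store = ParameterStore()
    P = store.add("P", np.asarray(values, dtype=float))
    return P, store


def test_contrastive_cls_symmetric_hand_value():
    """C=2, N=2, within-class cosine similarity 1, cross-class 0, tau=1:
    per-anchor loss = -ln(e / (2e + 2)) ~ 1.0064."""
    P, _ = set_prototypes([[1.0, 0.0], [2.0, 0.0],
                           [0.0, 1.0], [0.0, 3.0]])
    loss = float(proto_contrastive_cls(P, C=2, N=2, tau=1.0).data)
    e = np.e
    assert loss == pytest.approx(-np.log(e / (2 * e + 2)), rel=1e-9)
    assert abs(loss - 1.0064) < 1e-3


def brute_force_contrastive(P_values, labels, tau):
    """Double-loop oracle over anchors, positives and the unrestricted
    denominator (anchor term included)."""
    Pn = P_values / np.linalg.norm(P_values, axis=1, keepdims=True)
    n = len(P_values)
    losses = []
    for a in range(n):
        pos = [b for b in range(n) if b != a and labels[b] == labels[a]]
        if not pos:
            continue
        num = np.mean([np.exp(Pn[a] @ Pn[b] / tau) for b in pos])
        den = sum(np.exp(Pn[a] @ Pn[b] / tau) for b in range(n))
        losses.append(-np.log(num / den))
    return float(np.mean(losses))


def test_contrastive_cls_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    P_values = rng.standard_normal((12, 5))
    P, _ = set_prototypes(P_values)
    labels = np.repeat(np.arange(3), 4)
    got = float(proto_contrastive_cls(P, C=3, N=4, tau=0.5).data)
    want = brute_force_contrastive(P_values, labels, 0.5)
    assert got == pytest.approx(want, abs=1e-6)


def test_contrastive_cls_invariant_to_within_class_permutation():
    rng = np.random.default_rng(1)
    P_values = rng.standard_normal((6, 4))
    P1, _ = set_prototypes(P_values)
    swapped = P_values.copy()
    swapped[[0, 2]] = swapped[[2, 0]]   # permute within class 0 (N=3)
    P2, _ = set_prototypes(swapped)
    a = float(proto_contrastive_cls(P1, C=2, N=3, tau=0.7).data)
    b = float(proto_contrastive_cls(P2, C=2, N=3, tau=0.7).data)
    assert a == pytest.approx(b, rel=1e-12)


def test_contrastive_cls_contract_errors():
    P, _ = set_prototypes(np.ones((2, 2)))
    with pytest.raises(ValueError):
        proto_contrastive_cls(P, C=1, N=2, tau=1.0)
    with pytest.raises(ValueError):
        proto_contrastive_cls(P, C=2, N=1, tau=1.0)


def brute_force_two_partition(points):
    """Minimum within-cluster SSE over all non-trivial 2-partitions."""
    n = len(points)
    best, best_sse = None, np.inf
    for bits in itertools.product([0, 1], repeat=n):
        if len(set(bits)) < 2:
            continue
        sse = 0.0
        for c in (0, 1):
            members = points[np.array(bits) == c]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        if sse < best_sse - 1e-12:
            best_sse, best = sse, np.array(bits)
    return best


def test_kmeans_partition_matches_brute_force():
    pts = np.array([[0.0], [0.1], [10.0], [10.1]])
    labels = kmeans_partition(pts, seed=0)
    want = brute_force_two_partition(pts)
    # same partition up to label swap
    assert np.array_equal(labels, want) or np.array_equal(labels, 1 - want)
    # duplicated far pairs split identically for any seed
    pts2 = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
    for seed in (0, 1, 2):
        lab = kmeans_partition(pts2, seed=seed)
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]


def test_kmeans_partition_edge_cases():
    two = kmeans_partition(np.array([[0.0], [1.0]]), seed=0)
    assert sorted(two.tolist()) == [0, 1]
    with pytest.raises(ValueError):
        kmeans_partition(np.ones((4, 2)), seed=0)
    with pytest.raises(ValueError):
        kmeans_partition(np.ones((1, 2)), seed=0)


def test_contrastive_reg_mirrors_cls_in_symmetric_config():
    P, _ = set_prototypes([[1.0, 0.0], [2.0, 0.0],
                           [0.0, 1.0], [0.0, 3.0]])
    labels = np.array([0, 0, 1, 1])
    loss = float(proto_contrastive_reg(P, labels, tau=1.0).data)
    e = np.e
    assert loss == pytest.approx(-np.log(e / (2 * e + 2)), rel=1e-9)


def test_contrastive_reg_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    P_values = rng.standard_normal((6, 3))
    labels = kmeans_partition(P_values, seed=0)
    P, _ = set_prototypes(P_values)
    got = float(proto_contrastive_reg(P, labels, tau=0.5).data)
    want = brute_force_contrastive(P_values, labels, 0.5)
    assert got == pytest.approx(want, abs=1e-6)


def test_contrastive_reg_scale_invariance_and_errors():
    rng = np.random.default_rng(3)
    P_values = rng.standard_normal((6, 3))
    labels = np.array([0, 0, 0, 1, 1, 1])
    a = float(proto_contrastive_reg(set_prototypes(P_values)[0],
                                    labels, 0.5).data)
    b = float(proto_contrastive_reg(set_prototypes(5.0 * P_values)[0],
                                    labels, 0.5).data)
    assert a == pytest.approx(b, rel=1e-9)
    with pytest.raises(ValueError):
        proto_contrastive_reg(set_prototypes(P_values[:2])[0],
                              np.array([0, 1]), 0.5)
    with pytest.warns(UserWarning):
        proto_contrastive_reg(set_prototypes(P_values[:3])[0],
                              np.array([0, 0, 1]), 0.5)


def test_total_loss_weighted_combination():
    w = LossWeights(lambda_align=0.9, lambda_pred=0.9, lambda_proto=0.9)
    out = total_loss(0.1308, 0.6931, 1.0064, w)
    assert out.L_total == pytest.approx(0.9 * (0.1308 + 0.6931 + 1.0064),
                                        rel=1e-9)
    assert abs(out.L_total - 1.6473) < 1e-3
    only_pred = total_loss(5.0, 2.0, 7.0,
                           LossWeights(lambda_align=0.0, lambda_pred=1.0,
                                       lambda_proto=0.0))
    assert only_pred.L_total == pytest.approx(2.0)
    zero = total_loss(0.0, 0.0, 0.0, w)
    assert zero.L_total == 0.0
    with pytest.raises(ValueError):
        LossWeights(lambda_align=-0.1)
    with pytest.raises(ValueError):
        total_loss(np.inf, 0.0, 0.0, w)


def test_losses_nonnegative_on_random_configs():
    rng = np.random.default_rng(4)
    for trial in range(50):
        C, N = int(rng.integers(2, 4)), int(rng.integers(2, 5))
        P_values = rng.standard_normal((C * N, 4))
        P, _ = set_prototypes(P_values)
        got = float(proto_contrastive_cls(P, C=C, N=N, tau=0.5).data)
        labels = np.repeat(np.arange(C), N)
        want = brute_force_contrastive(P_values, labels, 0.5)
        assert got >= want - 1e-6
        assert got >= 0.0
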