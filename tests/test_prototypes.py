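"""Prototype space: distances, log-ratio similarities, top-K distributions,
KL alignment, the straight-line oracle, and gradient checks."""

import numpy as np
import pytest

from molproto.nn import ParameterStore, Tensor
from molproto.prototypes import (PrototypeSpace, aggregate_layers,
                                 alignment_loss, log_ratio_similarity,
                                 topk_distribution)

from conftest import numeric_gradient, relative_error


def make_space(C=2, N=2, d_p=3, d_g=3, d_t=3, K=2, eps=1e-6, seed=0):
    store = ParameterStore()
    space = PrototypeSpace(C=C, N=N, d_p=d_p, d_g=d_g, d_t=d_t, store=store,
                           rng=np.random.default_rng(seed), epsilon=eps, K=K)
    return space, store


def test_aggregate_layers_mean_and_edge_cases():
    out = aggregate_layers([Tensor(np.array([1.0, 1.0])),
                            Tensor(np.array([3.0, 3.0]))])
    assert np.allclose(out.data, [2.0, 2.0])
    single = Tensor(np.array([4.0, 5.0]))
    assert np.allclose(aggregate_layers([single]).data, single.data)
    with pytest.raises(ValueError):
        aggregate_layers([])


def test_distances_hand_examples():
    space, store = make_space(C=1, N=2, d_p=2, d_g=2, d_t=2, K=1)
    store["proto.P"].data = np.array([[3.0, 4.0], [0.0, 1.0]])
    D = space.distances(Tensor(np.array([0.0, 0.0])))
    assert np.allclose(D.data, [25.0, 1.0])
    # self-distance is zero
    D2 = space.distances(Tensor(np.array([3.0, 4.0])))
    assert D2.data[0] == pytest.approx(0.0)


def test_distances_nonnegative_for_random_inputs():
    space, _ = make_space(C=3, N=4, d_p=5, d_g=5, d_t=5, K=3, seed=1)
    rng = np.random.default_rng(2)
    for _ in range(10):
        D = space.distances(Tensor(rng.standard_normal(5)))
        assert np.all(D.data >= 0)


def test_log_ratio_similarity_values_and_monotonicity():
    s0 = log_ratio_similarity(np.array([0.0]), 1e-6)
    assert s0.data[0] == pytest.approx(np.log(1e6), rel=1e-9)
    s1 = log_ratio_similarity(np.array([1.0]), 1e-6)
    assert s1.data[0] == pytest.approx(np.log(2.0 / 1.000001), rel=1e-9)
    assert abs(s1.data[0] - 0.693146) < 1e-6
    far = log_ratio_similarity(np.array([1e9]), 1e-6)
    assert far.data[0] <= 1e-8
    # strictly decreasing on a grid, range (0, log(1/eps)]
    grid = np.linspace(0, 50, 200)
    s = log_ratio_similarity(grid, 1e-3).data
    assert np.all(np.diff(s) < 0)
    assert np.all(s > 0) and s[0] == pytest.approx(np.log(1e3))
    with pytest.raises(ValueError):
        log_ratio_similarity(np.array([-0.5]), 1e-6)


def test_topk_distribution_example_and_properties():
    dist = topk_distribution(np.array([3.0, 1.0, 2.0, 5.0, 4.0]), K=2)
    assert sorted(dist.support.tolist()) == [3, 4]
    e5, e4 = np.exp(5.0), np.exp(4.0)
    assert np.allclose(sorted(dist.alpha.data, reverse=True),
                       [e5 / (e5 + e4), e4 / (e5 + e4)], atol=1e-4)
    assert np.count_nonzero(dist.sparse_scores.data) == 2
    assert dist.alpha.data.sum() == pytest.approx(1.0, abs=1e-9)


def test_topk_edge_cases_and_tie_break():
    equal = topk_distribution(np.full(4, 2.0), K=4)
    assert np.allclose(equal.alpha.data, 0.25)
    single = topk_distribution(np.array([1.0, 9.0]), K=1)
    assert np.allclose(single.alpha.data, [1.0])
    # ties resolved toward the lowest flat index
    tied = topk_distribution(np.array([7.0, 7.0, 7.0]), K=2)
    assert tied.support.tolist() == [0, 1]
    with pytest.raises(ValueError):
        topk_distribution(np.ones(3), K=4)


def test_alignment_loss_hand_example_and_identity():
    space, _ = make_space()
    s_same = np.array([4.0, 3.0, 0.5, 0.1])
    d1 = topk_distribution(s_same, K=2, space_id=1)
    d2 = topk_distribution(s_same.copy(), K=2, space_id=1)
    assert float(alignment_loss(d1, d2).data) == pytest.approx(0.0, abs=1e-12)

    # shared support {0,1}: alpha_g = (0.75, 0.25), alpha_t = (0.5, 0.5)
    a = topk_distribution(np.log([0.75, 0.25, 1e-9, 1e-9]), K=2, space_id=1)
    b = topk_distribution(np.log([0.5, 0.5, 1e-9, 1e-9]), K=2, space_id=1)
    expected = 0.75 * np.log(1.5) + 0.25 * np.log(0.5)
    assert float(alignment_loss(a, b).data) == pytest.approx(expected,
                                                             abs=1e-4)
    assert abs(expected - 0.1308) < 1e-4


def test_alignment_loss_nonnegative_on_100_random_pairs():
    rng = np.random.default_rng(3)
    for _ in range(100):
        sa = rng.standard_normal(6)
        sb = rng.standard_normal(6)
        da = topk_distribution(sa, K=3, space_id=9)
        db = topk_distribution(sb, K=3, space_id=9)
        assert float(alignment_loss(da, db).data) >= -1e-12


def test_alignment_loss_space_mismatch_rejected():
    d1 = topk_distribution(np.ones(4), K=2, space_id=1)
    d2 = topk_distribution(np.ones(4), K=2, space_id=2)
    with pytest.raises(ValueError):
        alignment_loss(d1, d2)


def straight_line_prototype_pipeline(hat_g, hat_t, P, Wg, bg, Wt, bt, eps, K,
                                     floor=1e-8):
    """Independent numpy re-implementation of the full prototype stage:
    layer pooling, projection, squared distances, log-ratio, top-K softmax,
    floored full-length KL."""
    zbar_g = np.mean(hat_g, axis=0)
    zbar_t = np.mean(hat_t, axis=0)
    zg = zbar_g @ Wg + bg
    zt = zbar_t @ Wt + bt

    def response(z):
        D = ((z - P) ** 2).sum(axis=1)
        s = np.log((D + 1) / (D + eps))
        order = np.argsort(-s, kind="stable")[:K]
        alpha = np.exp(s[order]) / np.exp(s[order]).sum()
        full = np.full(len(s), floor)
        full[order] = alpha
        return full / full.sum()

    p = response(zg)
    q = response(zt)
    return float((p * np.log(p / q)).sum())


def test_full_pipeline_matches_straight_line_oracle():
    rng = np.random.default_rng(4)
    for trial in range(50):
        C, N = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        d_p = int(rng.integers(2, 6))
        d_g = int(rng.integers(2, 6))
        d_t = int(rng.integers(2, 6))
        K = int(rng.integers(1, C * N + 1))
        L = int(rng.integers(1, 4))
        space, store = make_space(C=C, N=N, d_p=d_p, d_g=d_g, d_t=d_t, K=K,
                                  seed=trial)
        hat_g = [rng.standard_normal(d_g) for _ in range(L)]
        hat_t = [rng.standard_normal(d_t) for _ in range(L)]
        zbar_g = aggregate_layers([Tensor(v) for v in hat_g])
        zbar_t = aggregate_layers([Tensor(v) for v in hat_t])
        dg = space.response(zbar_g, "g")
        dt = space.response(zbar_t, "t")
        got = float(alignment_loss(dg, dt).data)
        want = straight_line_prototype_pipeline(
            hat_g, hat_t, store["proto.P"].data,
            store["proto.proj_g.W"].data, store["proto.proj_g.b"].data,
            store["proto.proj_t.W"].data, store["proto.proj_t.b"].data,
            space.epsilon, K)
        assert got == pytest.approx(want, abs=1e-6), trial


def test_alignment_gradients_match_finite_differences():
    """d L_align / d(P, projections) on C=2, N=2, d_p=3, rel err < 1e-4."""
    space, store = make_space(C=2, N=2, d_p=3, d_g=3, d_t=3, K=2, seed=5)
    rng = np.random.default_rng(6)
    zg = rng.standard_normal(3)
    zt = rng.standard_normal(3)

    def compute_loss():
        dg = space.response(Tensor(zg), "g")
        dt = space.response(Tensor(zt), "t")
        return alignment_loss(dg, dt)

    for pname in ("proto.P", "proto.proj_g.W", "proto.proj_t.W",
                  "proto.proj_g.b"):
        param = store[pname]

        def f(values):
            old = param.data
            param.data = values
            out = float(compute_loss().data)
            param.data = old
            return out

        store.zero_grad()
        compute_loss().backward()
        grad = param.grad if param.grad is not None \
            else np.zeros_like(param.data)
        num = numeric_gradient(f, param.data.copy(), eps=1e-6)
        assert relative_error(grad, num) < 1e-4, pname


def test_space_validates_hyperparameters():
    with pytest.raises(ValueError):
        make_space(K=5)            # K > C*N = 4
    with pytest.raises(ValueError):
        make_space(eps=1.5)
    space, _ = make_space()
    with pytest.raises(ValueError):
        space.project(Tensor(np.ones(7)), "g")
    with pytest.raises(ValueError):
        space.project(Tensor(np.ones(3)), "x")
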