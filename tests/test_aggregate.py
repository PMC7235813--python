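"""Layer-fusion strategies: attention normalization, reduction
identities, the pencil-and-paper fixture, and baseline equivalences."""

import math

import numpy as np
import pytest

import layerfuse as lf
from layerfuse import _autodiff as ad
from layerfuse.aggregate import AggregatorConfigError, resolve_layer_subset

from conftest import random_stack


def _params(d, L, subset="all", heads=1, seed=0, **kw):
    return lf.AggregatorParams.initialize(
        d=d, n_layers=L, layer_subset=subset, n_fusion_heads=heads, seed=seed)


class TestSubsets:
    def test_named_subsets(self):
        assert resolve_layer_subset("all", 4) == (1, 2, 3, 4)
        assert resolve_layer_subset("last2", 12) == (11, 12)
        assert resolve_layer_subset("last4", 12) == (9, 10, 11, 12)
        assert resolve_layer_subset([2, 4], 4) == (2, 4)

    def test_subset_must_fit_and_contain_last(self):
        with pytest.raises(AggregatorConfigError):
            resolve_layer_subset("last6", 4)
        with pytest.raises(AggregatorConfigError):
            resolve_layer_subset([1, 5], 4)
        with pytest.raises(AggregatorConfigError):
            resolve_layer_subset([1, 2], 4)  # missing final layer
        with pytest.raises(AggregatorConfigError):
            resolve_layer_subset([], 4)


def test_attention_weights_normalized_across_geometries():
    for seed, L in enumerate((1, 2, 4)):
        stack = random_stack(L, n=7, d=12, seed=seed)
        p = _params(12, L, heads=3, seed=seed)
        w = lf.multihead_attention_weights(stack, p)
        assert w.shape == (7, 3, L)
        assert (w >= 0).all()
        assert np.abs(w.sum(axis=-1) - 1.0).max() < 1e-6


def test_single_layer_subset_weight_is_exactly_one():
    stack = random_stack(4, n=5, d=8, seed=1)
    p = _params(8, 4, subset=[4], heads=2, seed=1)
    w = lf.multihead_attention_weights(stack, p)
    assert np.array_equal(w, np.ones((5, 2, 1)))


def test_reduction_identities_with_single_layer_subset():
    """With layer_subset={L} and identity projections all four
    strategies return h_L."""
    stack = random_stack(3, n=6, d=10, seed=2)
    ident = lf.AggregatorParams.identity(10, 3, layer_subset=[3])
    h_last = stack.last
    assert np.allclose(lf.aggregate_multihead(stack, ident), h_last, atol=1e-9)
    assert np.allclose(lf.aggregate_concat(stack, ident), h_last, atol=1e-9)
    assert np.allclose(lf.aggregate_sum_average(stack, [3]), h_last)
    assert np.array_equal(lf.aggregate_last_layer(stack), h_last)


def test_forced_uniform_attention_equals_projected_sum_average():
    """Zero query -> equal logits -> the multihead output equals the
    sum-average baseline pushed through the value/mix projections."""
    rng = np.random.default_rng(3)
    for trial in range(100):
        L, d = 3, 8
        stack = random_stack(L, n=4, d=d, seed=100 + trial)
        p = lf.AggregatorParams.identity(d, L, zero_query=True, seed=trial)
        p.w_v = ad.parameter(rng.normal(size=(d, d)))
        p.b_v = ad.parameter(rng.normal(size=d))
        p.w_h = ad.parameter(rng.normal(size=(d, d)))
        p.b_h = ad.parameter(rng.normal(size=d))
        got = lf.aggregate_multihead(stack, p)
        mean = lf.aggregate_sum_average(stack, "all")
        want = (mean @ p.w_v.data + p.b_v.data) @ p.w_h.data + p.b_h.data
        assert np.allclose(got, want, atol=1e-9)


def test_multihead_matches_hand_worked_calculation():
    """L=2, d=2, one head, hand-set parameters: the implementation must
    reproduce a step-by-step hand execution of the fusion equations."""
    h1, h2 = [1.0, -1.0], [0.5, 2.0]
    stack = lf.LayerStack([np.array([h1]), np.array([h2])])
    w_q = np.array([[2.0, 0.0], [0.0, 1.0]])
    b_q = np.array([0.5, -0.5])
    w_k = np.array([[1.0, 1.0], [0.0, 1.0]])
    b_k = np.array([0.0, 0.25])
    w_v = np.array([[1.0, 2.0], [3.0, 4.0]])
    b_v = np.array([0.1, 0.2])
    w_h = np.array([[1.0, 0.5], [-1.0, 2.0]])
    b_h = np.array([0.05, -0.05])
    params = lf.AggregatorParams(
        d=2, n_layers=2, layer_subset=(1, 2), n_fusion_heads=1,
        w_q=ad.parameter(w_q), b_q=ad.parameter(b_q),
        w_k=ad.parameter(w_k), b_k=ad.parameter(b_k),
        w_v=ad.parameter(w_v), b_v=ad.parameter(b_v),
        w_h=ad.parameter(w_h), b_h=ad.parameter(b_h),
        w_c=ad.parameter(np.zeros((4, 2))), b_c=ad.parameter(np.zeros(2)),
    )

    # hand execution, scalar by scalar:
    # Q = h2 w_q + b_q = [0.5*2 + 2*0 + 0.5, 0.5*0 + 2*1 - 0.5]
    Q = [1.5, 1.5]
    # K_l = h_l w_k + b_k
    K1 = [1.0 * 1 + (-1.0) * 0, 1.0 * 1 + (-1.0) * 1 + 0.25]      # [1, 0.25]
    K2 = [0.5 * 1 + 2.0 * 0, 0.5 * 1 + 2.0 * 1 + 0.25]           # [0.5, 2.75]
    # V_l = h_l w_v + b_v
    V1 = [1.0 * 1 + (-1.0) * 3 + 0.1, 1.0 * 2 + (-1.0) * 4 + 0.2]  # [-1.9, -1.8]
    V2 = [0.5 * 1 + 2.0 * 3 + 0.1, 0.5 * 2 + 2.0 * 4 + 0.2]        # [6.6, 9.2]
    # scaled dot-product logits over the two layer items, d_head = 2
    s = 1.0 / math.sqrt(2.0)
    l1 = (Q[0] * K1[0] + Q[1] * K1[1]) * s                         # 1.875/sqrt2
    l2 = (Q[0] * K2[0] + Q[1] * K2[1]) * s                         # 4.875/sqrt2
    z = math.exp(l1) + math.exp(l2)
    a1, a2 = math.exp(l1) / z, math.exp(l2) / z
    head = [a1 * V1[0] + a2 * V2[0], a1 * V1[1] + a2 * V2[1]]
    # E = head w_h + b_h
    expected = [
        head[0] * 1.0 + head[1] * (-1.0) + 0.05,
        head[0] * 0.5 + head[1] * 2.0 - 0.05,
    ]

    got = lf.aggregate_multihead(stack, params)
    assert got.shape == (1, 2)
    assert np.allclose(got[0], expected, atol=1e-9)
    w = lf.multihead_attention_weights(stack, params)
    assert np.allclose(w[0, 0], [a1, a2], atol=1e-9)


class TestConcat:
    def test_preprojection_width_bookkeeping(self):
        stack = random_stack(4, n=3, d=6, seed=5)
        p = _params(6, 4, subset="last2", seed=5)
        assert p.w_c.data.shape == (12, 6)
        out = lf.aggregate_concat(stack, p)
        sel = np.concatenate([stack.layer(3), stack.layer(4)], axis=-1)
        assert np.allclose(out, sel @ p.w_c.data + p.b_c.data)

    def test_ignores_non_selected_layers(self):
        stack = random_stack(4, n=3, d=6, seed=6)
        p = _params(6, 4, subset="last2", seed=6)
        base = lf.aggregate_concat(stack, p)
        permuted = lf.LayerStack([stack.layer(2), stack.layer(1),
                                  stack.layer(3), stack.layer(4)])
        assert np.array_equal(lf.aggregate_concat(permuted, p), base)


def test_multihead_ignores_non_selected_layers():
    stack = random_stack(4, n=3, d=8, seed=7)
    p = _params(8, 4, subset="last2", heads=2, seed=7)
    base = lf.aggregate_multihead(stack, p)
    permuted = lf.LayerStack([stack.layer(2), stack.layer(1),
                              stack.layer(3), stack.layer(4)])
    assert np.array_equal(lf.aggregate_multihead(permuted, p), base)


def test_sum_average_matches_bruteforce_mean():
    stack = random_stack(5, n=4, d=6, seed=8)
    got = lf.aggregate_sum_average(stack, [2, 4, 5])
    want = (stack.layer(2) + stack.layer(4) + stack.layer(5)) / 3.0
    assert np.allclose(got, want, atol=1e-6)
    with pytest.raises(AggregatorConfigError):
        lf.aggregate_sum_average(stack, [])


def test_identical_layers_collapse_to_single_layer():
    h = np.random.default_rng(9).normal(size=(4, 6))
    stack = lf.LayerStack([h, h, h])
    assert np.allclose(lf.aggregate_sum_average(stack, "all"), h)


def test_heads_must_divide_width():
    with pytest.raises(AggregatorConfigError):
        _params(10, 2, heads=3)
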