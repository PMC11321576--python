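"""Equation-level reference operations: worked examples and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcngru.oracle import (GRUState, GRUWeights, categorical_cross_entropy,
                           dilated_causal_conv1d, gru_cell_step, gru_sequence,
                           softmax_probs)


class TestDilatedCausalConv:
    def test_hand_example_dilation_two(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        w = np.ones((2, 1, 1))  # y_t = x_t + x_{t-2}
        y = dilated_causal_conv1d(x, w, dilation=2)
        assert np.allclose(y[:, 0], [1, 2, 4, 6])

    def test_delta_kernel_is_identity(self, rng):
        x = rng.normal(size=(20, 3))
        for d in (1, 2, 5):
            w = np.zeros((3, 3, 3))
            w[-1] = np.eye(3)  # only the current-time tap
            assert np.allclose(dilated_causal_conv1d(x, w, d), x)

    def test_impulse_support_matches_receptive_field(self):
        # k=2 convs at dilations 1,2,4,8, two per level: support = 31 steps
        x = np.zeros((64, 1))
        x[0, 0] = 1.0
        w = np.ones((2, 1, 1))
        for d in (1, 1, 2, 2, 4, 4, 8, 8):
            x = dilated_causal_conv1d(x, w, d)
        support = np.flatnonzero(x[:, 0])
        assert support[0] == 0 and support[-1] == 30
        assert len(support) == 31

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dilated_causal_conv1d(np.zeros((5, 2)), np.zeros((2, 3, 1)), 1)
        with pytest.raises(ValueError):
            dilated_causal_conv1d(np.zeros((5, 2)), np.zeros((2, 2, 1)), 0)

    def test_linearity(self, rng):
        w = rng.normal(size=(3, 2, 4))
        x1, x2 = rng.normal(size=(2, 15, 2))
        lhs = dilated_causal_conv1d(2.5 * x1 - 0.5 * x2, w, 2)
        rhs = 2.5 * dilated_causal_conv1d(x1, w, 2) - 0.5 * dilated_causal_conv1d(x2, w, 2)
        assert np.allclose(lhs, rhs)

    def test_causality_by_perturbation(self, rng):
        w = rng.normal(size=(2, 1, 1))
        x = rng.normal(size=(30, 1))
        x2 = x.copy()
        x2[20:] += rng.normal(size=(10, 1))
        y, y2 = (dilated_causal_conv1d(v, w, 4) for v in (x, x2))
        assert np.allclose(y[:20], y2[:20])


class TestGRUCell:
    def test_zero_weights_halve_the_state(self, rng):
        h = rng.normal(size=6)
        w = GRUWeights.zeros(4, 6)
        out = gru_cell_step(np.zeros(4), GRUState(h), w)
        assert np.allclose(out.h, 0.5 * h)  # sigma(0)=1/2, tanh(0)=0

    def test_scalar_candidate_path(self):
        w = GRUWeights.zeros(1, 1)
        w.W_h[0, 0] = 1.0
        out = gru_cell_step(np.array([1.0]), GRUState(np.array([0.0])), w)
        assert np.allclose(out.h, 0.5 * np.tanh(1.0))

    def test_saturated_update_gate_freezes_state(self, rng):
        h = rng.normal(size=3)
        w = GRUWeights.zeros(2, 3)
        w.b_input_z[:] = 50.0  # z -> 1
        out = gru_cell_step(rng.normal(size=2), GRUState(h), w)
        assert np.allclose(out.h, h, atol=1e-10)

    def test_single_bias_form_ignores_recurrent_biases(self, rng):
        w = GRUWeights.zeros(2, 3)
        w.b_recur_h[:] = 5.0
        h = GRUState(rng.normal(size=3))
        x = rng.normal(size=2)
        single = gru_cell_step(x, h, w, double_bias=False)
        assert np.allclose(single.h, 0.5 * h.h)  # biases dropped -> zero net
        double = gru_cell_step(x, h, w, double_bias=True)
        assert not np.allclose(double.h, single.h)

    def test_non_finite_input_rejected(self):
        w = GRUWeights.zeros(1, 1)
        with pytest.raises(ValueError):
            gru_cell_step(np.array([np.nan]), GRUState(np.array([0.0])), w)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_new_state_is_convex_combination(self, seed):
        rng = np.random.default_rng(seed)
        units, dim = 4, 3
        w = GRUWeights(
            *(rng.normal(size=(dim, units)) for _ in range(3)),
            *(rng.normal(size=(units, units)) for _ in range(3)),
            *(rng.normal(size=units) for _ in range(6)))
        h = rng.normal(size=units)
        x = rng.normal(size=dim)
        out = gru_cell_step(x, GRUState(h), w)
        # recompute the candidate state independently from the equations
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        r = sig(x @ w.W_r + w.b_input_r + h @ w.U_r + w.b_recur_r)
        hh = np.tanh(x @ w.W_h + w.b_input_h + r * (h @ w.U_h + w.b_recur_h))
        # h_new = z h + (1-z) h' lies between h and h' componentwise
        assert np.all(out.h <= np.maximum(h, hh) + 1e-12)
        assert np.all(out.h >= np.minimum(h, hh) - 1e-12)


class TestSoftmaxAndLoss:
    def test_equal_scores_give_uniform(self):
        assert np.allclose(softmax_probs(np.zeros(6)), 1 / 6)

    def test_log_two_ratio(self):
        assert np.allclose(softmax_probs(np.array([0.0, np.log(2.0)])),
                           [1 / 3, 2 / 3])

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_invariance_and_normalisation(self, scores, const):
        p = softmax_probs(np.array(scores))
        assert np.isclose(p.sum(), 1.0)
        assert np.allclose(softmax_probs(np.array(scores) + const), p, atol=1e-9)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            softmax_probs(np.array([]))

    def test_perfect_prediction_zero_loss(self):
        y = np.eye(3)
        assert categorical_cross_entropy(y, y) < 1e-6

    def test_uniform_six_class_loss_is_ln6(self):
        y = np.eye(6)[[0, 3]]
        p = np.full((2, 6), 1 / 6)
        assert np.isclose(categorical_cross_entropy(y, p), np.log(6.0))

    def test_zero_probability_clipped_to_finite_ceiling(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.0, 1.0]])
        assert np.isclose(categorical_cross_entropy(y, p), -np.log(1e-7))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            categorical_cross_entropy(np.eye(3), np.full((2, 3), 1 / 3))


def test_gru_sequence_matches_stepwise(rng):
    w = GRUWeights(
        *(rng.normal(size=(2, 3)) * 0.4 for _ in range(3)),
        *(rng.normal(size=(3, 3)) * 0.4 for _ in range(3)),
        *(rng.normal(size=3) * 0.1 for _ in range(6)))
    x = rng.normal(size=(5, 2))
    seq = gru_sequence(x, w)
    state = GRUState(np.zeros(3))
    for t in range(5):
        state = gru_cell_step(x[t], state, w)
        assert np.allclose(seq[t], state.h)
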