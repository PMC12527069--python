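"""Neural engine: cell equations, gradients, initialization, loss."""

import math

import numpy as np
import pytest

from ecgkit.nn import (
    Adam, AdamW, Conv1d, Dense, LSTM, LSTMCellWeights, MaxPool1d, ReLU,
    Sequential, ToSequence, cell_from_fused, fused_from_cell, kaiming_init,
    lstm_cell_step, softmax, softmax_wce_with_grad, weighted_cross_entropy,
)
from ecgkit._exceptions import ValidationError


def _zero_cell(F=3, H=4):
    z = np.zeros
    return LSTMCellWeights(
        W_i=z((H, F)), W_f=z((H, F)), W_o=z((H, F)), W_c=z((H, F)),
        W_hi=z((H, H)), W_fi=z((H, H)), W_oi=z((H, H)), W_hc=z((H, H)),
        b_i=z(H), b_f=z(H), b_o=z(H), b_c=z(H),
    )


class TestLstmCell:
    def test_zero_weights_closed_form(self):
        # all gates sit at sigmoid(0)=0.5 and the candidate at tanh(0)=0
        w = _zero_cell()
        c_prev = np.array([1.0, -2.0, 0.5, 0.0])
        h, c = lstm_cell_step(np.ones(3), np.zeros(4), c_prev, w)
        np.testing.assert_allclose(c, 0.5 * c_prev)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_saturated_forget_gate_preserves_memory(self):
        w = _zero_cell()
        w.b_f[:] = 50.0  # forget gate pinned at ~1
        c_prev = np.array([0.3, -0.7, 1.2, 0.0])
        _, c = lstm_cell_step(np.zeros(3), np.zeros(4), c_prev, w)
        np.testing.assert_allclose(c, c_prev, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        w = _zero_cell(3, 4)
        with pytest.raises(ValidationError, match="shape"):
            lstm_cell_step(np.zeros(5), np.zeros(4), np.zeros(4), w)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_fused_layer_trajectory(self, seed):
        # dual route: per-equation cell vs the batched fused-gate layer
        rng = np.random.default_rng(seed)
        F, H, T = 4, 6, 5
        cw = LSTMCellWeights.random(F, H, rng)
        W, U, b = fused_from_cell(cw)
        layer = LSTM(F, H, return_sequences=True)
        layer.params["W"][...] = W
        layer.params["U"][...] = U
        layer.params["b"][...] = b
        xs = rng.normal(size=(1, T, F))
        hs = layer.forward(xs)
        h, c = np.zeros(H), np.zeros(H)
        for t in range(T):
            h, c = lstm_cell_step(xs[0, t], h, c, cw)
            np.testing.assert_allclose(hs[0, t], h, atol=1e-5)

    def test_fused_packing_round_trip(self):
        rng = np.random.default_rng(0)
        cw = LSTMCellWeights.random(3, 5, rng)
        back = cell_from_fused(*fused_from_cell(cw))
        for name in ("W_i", "W_f", "W_o", "W_c", "W_hi", "W_fi", "W_oi",
                     "W_hc", "b_i", "b_f", "b_o", "b_c"):
            np.testing.assert_array_equal(getattr(back, name), getattr(cw, name))


class TestGradients:
    """Analytic gradients vs central finite differences on a small net."""

    def _check(self, net, x, y, weights=None, n_probe=6, tol=1e-5):
        rng = np.random.default_rng(99)
        net.zero_grad()
        _, g = softmax_wce_with_grad(net.forward(x), y, weights)
        net.backward(g)
        grads = net.gradients()
        eps = 1e-6
        for key, p in net.parameters().items():
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(n_probe, flat.size),
                                replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = softmax_wce_with_grad(net.forward(x), y, weights)[0]
                flat[i] = old - eps
                lm = softmax_wce_with_grad(net.forward(x), y, weights)[0]
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert abs(num - ana) <= tol * max(1.0, abs(num)), key

    def test_conv_pool_dense_stack(self):
        rng = np.random.default_rng(1)
        net = Sequential([Conv1d(1, 5, 5, stride=2, padding=1), ReLU(),
                          MaxPool1d(2), Conv1d(5, 4, 3, stride=1, padding=1),
                          ReLU(), MaxPool1d(2)], input_shape=(1, 40))
        from ecgkit.nn import Flatten
        flat = int(np.prod(net.output_shape))
        net = Sequential(net.layers + [Flatten(), Dense(flat, 3)],
                         input_shape=(1, 40))
        kaiming_init(net, 2)
        self._check(net, rng.normal(size=(4, 1, 40)), np.array([0, 1, 2, 1]))

    def test_lstm_stack_bptt(self):
        rng = np.random.default_rng(2)
        net = Sequential([LSTM(2, 5, return_sequences=True), LSTM(5, 4),
                          Dense(4, 3)], input_shape=(6, 2))
        kaiming_init(net, 3)
        self._check(net, rng.normal(size=(3, 6, 2)), np.array([2, 0, 1]),
                    weights=np.array([1.0, 2.0, 0.5]))

    def test_hybrid_handoff(self):
        rng = np.random.default_rng(3)
        net = Sequential([Conv1d(1, 4, 5, stride=2, padding=1), ReLU(),
                          MaxPool1d(2), ToSequence(), LSTM(4, 5),
                          Dense(5, 3)], input_shape=(1, 30))
        kaiming_init(net, 4)
        self._check(net, rng.normal(size=(3, 1, 30)), np.array([0, 2, 1]))


class TestLoss:
    def test_perfect_predictions_zero_loss(self):
        p = np.eye(3)[[0, 1, 2]]
        assert weighted_cross_entropy(p, [0, 1, 2]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_weights_reduce_to_plain_ce(self):
        rng = np.random.default_rng(5)
        p = softmax(rng.normal(size=(10, 5)), axis=1)
        y = rng.integers(0, 5, 10)
        plain = float(np.mean(-np.log(p[np.arange(10), y])))
        assert weighted_cross_entropy(p, y, np.ones(5)) == pytest.approx(
            plain, abs=1e-9)
        assert weighted_cross_entropy(p, y) == pytest.approx(plain, abs=1e-9)

    def test_two_class_hand_computation(self):
        # batch: y=(0,1), p_true=(0.8, 0.6), weights (2,1)
        # L = (2*(-ln .8) + 1*(-ln .6)) / (2+1)
        p = np.array([[0.8, 0.2], [0.4, 0.6]])
        expected = (2 * -math.log(0.8) + 1 * -math.log(0.6)) / 3.0
        assert weighted_cross_entropy(p, [0, 1], [2.0, 1.0]) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_probability_clamped_with_warning(self, caplog):
        p = np.array([[1.0, 0.0]])
        with caplog.at_level("WARNING"):
            loss = weighted_cross_entropy(p, [1])
        assert math.isfinite(loss)
        assert "clamped" in caplog.text

    def test_inverse_frequency_weights_penalize_majority_classifier(self):
        # imbalanced set: always-majority must lose to a balanced classifier
        from ecgkit.models import inverse_frequency_weights
        y = np.r_[np.zeros(90, int), np.full(10, 2)]
        w = inverse_frequency_weights(y)
        p_major = np.tile([0.96, 0.01, 0.01, 0.01, 0.01], (100, 1))
        p_balanced = np.full((100, 5), 0.01)
        p_balanced[np.arange(100), y] = 0.96
        assert weighted_cross_entropy(p_major, y, w) > \
            weighted_cross_entropy(p_balanced, y, w)

    def test_grad_matches_probability_residual(self):
        rng = np.random.default_rng(7)
        logits = rng.normal(size=(6, 5))
        y = rng.integers(0, 5, 6)
        _, g = softmax_wce_with_grad(logits, y)
        p = softmax(logits, axis=1)
        onehot = np.eye(5)[y]
        np.testing.assert_allclose(g, (p - onehot) / 6.0, atol=1e-12)


class TestKaimingInit:
    def test_empirical_sd_matches_he_formula(self):
        net = Sequential([Conv1d(50, 40, 5)], input_shape=(50, 20))
        kaiming_init(net, 0)
        w = net.layers[0].params["W"]
        assert w.size >= 10_000
        assert abs(w.std() - math.sqrt(2.0 / 250)) / math.sqrt(2.0 / 250) < 0.05

    def test_same_seed_identical_draws(self):
        def build():
            return Sequential([Dense(30, 20), Dense(20, 5)], input_shape=(30,))
        a = kaiming_init(build(), 7)
        b = kaiming_init(build(), 7)
        for k in a.parameters():
            np.testing.assert_array_equal(a.parameters()[k], b.parameters()[k])

    def test_biases_zero_lstm_scales(self):
        net = Sequential([LSTM(8, 16), Dense(16, 5)], input_shape=(10, 8))
        kaiming_init(net, 1)
        lstm, dense = net.layers
        assert np.all(lstm.params["b"] == 0.0)
        assert np.all(dense.params["b"] == 0.0)
        assert abs(lstm.params["W"].std() - math.sqrt(2 / 8)) < 0.1
        assert abs(lstm.params["U"].std() - math.sqrt(2 / 16)) < 0.05


class TestOptimizers:
    def test_adam_zero_lr_is_identity(self):
        p = {"w": np.ones(4)}
        Adam(lr=0.0).step(p, {"w": np.full(4, 3.0)})
        np.testing.assert_array_equal(p["w"], np.ones(4))

    def test_adamw_decouples_decay(self):
        # with zero gradient, AdamW still shrinks weights; Adam does not
        pa = {"w": np.full(4, 2.0)}
        pw = {"w": np.full(4, 2.0)}
        Adam(lr=0.1).step(pa, {"w": np.zeros(4)})
        AdamW(lr=0.1, weight_decay=0.5).step(pw, {"w": np.zeros(4)})
        np.testing.assert_array_equal(pa["w"], np.full(4, 2.0))
        assert np.all(pw["w"] < 2.0)
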