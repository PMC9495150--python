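"""Classifier components against first-principles oracles."""

import numpy as np
import pytest

from _oracles import ca_reweight_loops, lstm_cell_scalar
from birdcall.autodiff import Tensor, no_grad
from birdcall.model import (
    BirdcallNet,
    CAGates,
    CoordinateAttention,
    LSTMState,
    ModelConfig,
    ca_pool,
    ca_reweight,
    lstm_cell,
    sigmoid,
    silu,
)


class TestSiLU:
    def test_fixed_points(self):
        assert silu(0.0) == 0.0
        assert np.isclose(silu(-1.0), -1.0 * sigmoid(-1.0))
        assert np.isclose(silu(-1.0), -0.2689414, atol=1e-6)

    def test_asymptotically_linear(self):
        assert np.isclose(silu(50.0), 50.0, atol=1e-12)


class TestCAPool:
    def test_hand_example(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])  # 1 x 2 x 2
        pooled_h, pooled_w = ca_pool(x)
        np.testing.assert_allclose(pooled_h, [[1.5, 3.5]])
        np.testing.assert_allclose(pooled_w, [[2.0, 3.0]])

    def test_constant_map(self):
        pooled_h, pooled_w = ca_pool(np.full((2, 3, 5), 7.0))
        assert np.all(pooled_h == 7.0) and np.all(pooled_w == 7.0)

    def test_pooled_means_equal_global_mean(self, rng):
        x = rng.normal(size=(2, 4, 6))
        pooled_h, pooled_w = ca_pool(x)
        for c in range(2):
            assert np.isclose(pooled_h[c].mean(), x[c].mean())
            assert np.isclose(pooled_w[c].mean(), x[c].mean())


class TestCAReweight:
    def test_unit_gates_are_identity(self, rng):
        x = rng.normal(size=(1, 4, 5))
        g = CAGates(np.ones((1, 4)), np.ones((1, 5)))
        np.testing.assert_array_equal(ca_reweight(x, g), x)

    def test_zero_row_gate_zeroes_row(self, rng):
        x = rng.normal(size=(1, 4, 5))
        g_h = np.ones((1, 4))
        g_h[0, 2] = 0.0
        out = ca_reweight(x, CAGates(g_h, np.ones((1, 5))))
        assert np.all(out[0, 2] == 0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=(1, 4, 5))
            g = CAGates(rng.random((1, 4)), rng.random((1, 5)))
            np.testing.assert_array_equal(
                ca_reweight(x, g), ca_reweight_loops(x, g.g_h, g.g_w))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ca_reweight(rng.normal(size=(1, 4, 5)),
                        CAGates(np.ones((1, 3)), np.ones((1, 5))))


class TestCAGatesModule:
    def test_full_size_gate_shapes_and_range(self, rng):
        ca = CoordinateAttention(np.random.default_rng(0), channels=1, mid=8)
        gates = ca.gates_numpy(rng.normal(size=(1, 148, 801)))
        assert gates.g_h.shape == (1, 148)
        assert gates.g_w.shape == (1, 801)
        for g in (gates.g_h, gates.g_w):
            assert (g > 0).all() and (g < 1).all()

    def test_zero_output_transforms_give_half_gates(self, rng):
        ca = CoordinateAttention(np.random.default_rng(1), channels=1, mid=4)
        for p in (ca.Wh, ca.Ww, ca.bh, ca.bw):
            p.data = np.zeros_like(p.data)
        gates = ca.gates_numpy(rng.normal(size=(1, 6, 9)))
        np.testing.assert_allclose(gates.g_h, 0.5)
        np.testing.assert_allclose(gates.g_w, 0.5)

    def test_deterministic(self, rng):
        ca = CoordinateAttention(np.random.default_rng(2), channels=1, mid=4)
        x = rng.normal(size=(1, 6, 9))
        a, b = ca.gates_numpy(x), ca.gates_numpy(x)
        np.testing.assert_array_equal(a.g_h, b.g_h)
        np.testing.assert_array_equal(a.g_w, b.g_w)


class TestLSTMCell:
    @staticmethod
    def random_params(rng, n_in, hidden):
        from birdcall.model import LSTMLayerParams

        fan = n_in + hidden
        return LSTMLayerParams(
            *(rng.normal(size=(fan, hidden)) for _ in range(4)),
            *(rng.normal(size=hidden) for _ in range(4)))

    def test_zero_params_zero_state(self):
        from birdcall.model import LSTMLayerParams

        p = LSTMLayerParams(*(np.zeros((5, 2)) for _ in range(4)),
                            *(np.zeros(2) for _ in range(4)))
        out = lstm_cell(np.ones(3), LSTMState(np.zeros(2), np.zeros(2)), p)
        np.testing.assert_array_equal(out.C, 0.0)
        np.testing.assert_array_equal(out.h, 0.0)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(50):
            p = self.random_params(rng, 3, 2)
            state = LSTMState(rng.normal(size=2), rng.normal(size=2))
            x_t = rng.normal(size=3)
            out = lstm_cell(x_t, state, p)
            h_ref, c_ref = lstm_cell_scalar(
                x_t, state.h, state.C, p.W_f, p.W_i, p.W_C, p.W_o,
                p.b_f, p.b_i, p.b_C, p.b_o)
            np.testing.assert_allclose(out.h, h_ref, atol=1e-10)
            np.testing.assert_allclose(out.C, c_ref, atol=1e-10)

    def test_hidden_state_bounded(self, rng):
        p = self.random_params(rng, 4, 3)
        state = LSTMState(np.zeros(3), np.zeros(3))
        for _ in range(20):
            state = lstm_cell(rng.normal(size=4) * 5, state, p)
            assert np.all(np.abs(state.h) < 1.0)


def brute_force_forward(net, x):
    """Recompute the full eval-mode forward pass with plain numpy from the
    cell equations: CA gates -> re-weight -> per-step LSTM -> FC -> softmax."""
    H, W = x.shape
    if net.ca is not None:
        gates = net.ca.gates_numpy(x[None])
        x = ca_reweight(x[None], gates)[0]
    xs = [x[:, t] for t in range(W)]
    for layer in net.layers:
        params = layer[0].numpy_params()
        state = LSTMState(np.zeros(layer[0].hidden), np.zeros(layer[0].hidden))
        outs = []
        for x_t in xs:
            state = lstm_cell(x_t, state, params)
            outs.append(state.h)
        xs = outs
    last = xs[-1]
    z = silu(last @ net.fc1_W.data + net.fc1_b.data)
    logits = z @ net.fc2_W.data + net.fc2_b.data
    e = np.exp(logits - logits.max())
    return e / e.sum()


class TestForward:
    @pytest.fixture
    def tiny_net(self):
        return BirdcallNet(ModelConfig(n_features=4, n_species=2, hidden=3,
                                       n_layers=2, ca_mid=3, dropout=0.0,
                                       seed=7))

    def test_softmax_normalisation(self, tiny_net, rng):
        probs = tiny_net.predict_proba(rng.normal(size=(5, 4, 6)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs > 0).all()

    def test_eval_mode_deterministic(self, tiny_net, rng):
        x = rng.normal(size=(2, 4, 6))
        np.testing.assert_array_equal(tiny_net.predict_proba(x),
                                      tiny_net.predict_proba(x))

    def test_wrong_input_shape_rejected(self, tiny_net, rng):
        with pytest.raises(ValueError):
            tiny_net.predict_proba(rng.normal(size=(1, 5, 6)))

    def test_matches_equationwise_recomputation(self, tiny_net, rng):
        """End-to-end brute-force oracle on a tiny configuration."""
        for _ in range(5):
            x = rng.normal(size=(4, 6))
            got = tiny_net.predict_proba(x[None])[0]
            ref = brute_force_forward(tiny_net, x)
            np.testing.assert_allclose(got, ref, atol=1e-8)

    def test_unit_gates_equal_ca_ablated_path(self, tiny_net, rng):
        """Forcing both CA gate vectors to 1 must reproduce the CA-off
        network exactly (ablation corresponds to a real code path)."""
        x = rng.normal(size=(1, 4, 6))

        class UnitCA:
            def __call__(self, t):
                return t

        ca = tiny_net.ca
        try:
            tiny_net.ca = UnitCA()
            with_unit_gates = tiny_net.predict_proba(x)
            tiny_net.ca = None
            ablated = tiny_net.predict_proba(x)
        finally:
            tiny_net.ca = ca
        np.testing.assert_array_equal(with_unit_gates, ablated)

    def test_save_load_roundtrip(self, tiny_net, rng, tmp_path):
        x = rng.normal(size=(3, 4, 6))
        tiny_net.save(tmp_path / "ckpt")
        again = BirdcallNet.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(tiny_net.predict_proba(x),
                                      again.predict_proba(x))

    def test_bidirectional_head_width(self, rng):
        net = BirdcallNet(ModelConfig(n_features=4, n_species=3, hidden=3,
                                      n_layers=2, bidirectional=True,
                                      dropout=0.0, seed=1))
        probs = net.predict_proba(rng.normal(size=(2, 4, 6)))
        assert probs.shape == (2, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
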