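"""Recurrent cells, stacks and parameter accounting.

The cell updates are checked against independent scalar-loop oracles that
evaluate the gate equations element by element.
"""

import numpy as np
import pytest

from gaitbalance.rnn import (ARCHITECTURE_PROFILES, BalanceRNN, CellParams,
                             ModelConfig, count_parameters, gru_step,
                             lstm_step)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _zero_params(cell_type, d, H):
    G = 4 if cell_type == "lstm" else 3
    return CellParams(cell_type=cell_type,
                      w_x=np.zeros((G * H, d)), w_h=np.zeros((G * H, H)),
                      b_x=np.zeros(G * H), b_h=np.zeros(G * H))


def _scalar_lstm_sequence(xs, p):
    """Element-wise evaluation of the LSTM gate equations, no vectorization."""
    H = p.hidden_size
    h = np.zeros(H)
    c = np.zeros(H)
    out = []
    for x in xs:
        hx = np.concatenate([h, x])
        W = np.hstack([p.w_h, p.w_x])  # [h, x] concatenation order
        b = p.b_x + p.b_h
        f = np.array([_sigmoid(W[j] @ hx + b[j]) for j in range(H)])
        i = np.array([_sigmoid(W[H + j] @ hx + b[H + j]) for j in range(H)])
        o = np.array([_sigmoid(W[2 * H + j] @ hx + b[2 * H + j])
                      for j in range(H)])
        g = np.array([np.tanh(W[3 * H + j] @ hx + b[3 * H + j])
                      for j in range(H)])
        c = f * c + i * g
        h = o * np.tanh(c)
        out.append(h.copy())
    return np.array(out)


def _scalar_gru_sequence(xs, p):
    H = p.hidden_size
    h = np.zeros(H)
    out = []
    for x in xs:
        hx = np.concatenate([h, x])
        W = np.hstack([p.w_h, p.w_x])
        b = p.b_x + p.b_h
        u = np.array([_sigmoid(W[j] @ hx + b[j]) for j in range(H)])
        r = np.array([_sigmoid(W[H + j] @ hx + b[H + j]) for j in range(H)])
        rhx = np.concatenate([r * h, x])
        n = np.array([np.tanh(W[2 * H + j] @ rhx + b[2 * H + j])
                      for j in range(H)])
        h = (1.0 - u) * h + u * n
        out.append(h.copy())
    return np.array(out)


class TestLstmStep:
    def test_zero_params_zero_cell(self):
        p = _zero_params("lstm", 2, 3)
        y, (h, c) = lstm_step(np.ones(2), (np.zeros(3), np.zeros(3)), p)
        assert np.allclose(c, 0.0)
        assert np.allclose(h, 0.0)

    def test_zero_params_unit_cell_state(self):
        """sigma(0)=0.5 gates halve the carried cell state: h=0.5 tanh(0.5)."""
        p = _zero_params("lstm", 1, 1)
        y, (h, c) = lstm_step(np.zeros(1), (np.zeros(1), np.ones(1)), p)
        assert np.allclose(c, 0.5)
        assert np.allclose(h, 0.5 * np.tanh(0.5))
        assert np.allclose(h, 0.23105857863, atol=1e-10)

    def test_matches_scalar_oracle(self, rng):
        p = CellParams.init("lstm", 3, 4, rng)
        xs = rng.standard_normal((11, 3))
        state = (np.zeros(4), np.zeros(4))
        ys = []
        for x in xs:
            y, state = lstm_step(x, state, p)
            ys.append(y)
        assert np.abs(np.array(ys) - _scalar_lstm_sequence(xs, p)).max() < 1e-12

    def test_shape_mismatch_rejected(self):
        p = _zero_params("lstm", 2, 3)
        with pytest.raises(ValueError):
            lstm_step(np.ones(5), (np.zeros(3), np.zeros(3)), p)


class TestGruStep:
    def test_zero_params_unit_hidden(self):
        """u=r=0.5, candidate tanh(0)=0: h = 0.5*1 + 0.5*0 = 0.5."""
        p = _zero_params("gru", 1, 1)
        y, h = gru_step(np.zeros(1), np.ones(1), p)
        assert np.allclose(h, 0.5)

    def test_zero_params_zero_hidden(self):
        p = _zero_params("gru", 2, 3)
        y, h = gru_step(np.ones(2), np.zeros(3), p)
        assert np.allclose(h, 0.0)

    def test_matches_scalar_oracle(self, rng):
        p = CellParams.init("gru", 3, 4, rng)
        xs = rng.standard_normal((11, 3))
        h = np.zeros(4)
        ys = []
        for x in xs:
            y, h = gru_step(x, h, p)
            ys.append(y)
        assert np.abs(np.array(ys) - _scalar_gru_sequence(xs, p)).max() < 1e-12

    def test_shape_mismatch_rejected(self):
        p = _zero_params("gru", 2, 3)
        with pytest.raises(ValueError):
            gru_step(np.ones(2), np.zeros(4), p)


class TestForward:
    @pytest.mark.parametrize("cell", ["lstm", "gru"])
    @pytest.mark.parametrize("bidirectional", [False, True])
    def test_output_shape(self, cell, bidirectional, rng):
        cfg = ModelConfig(cell_type=cell, bidirectional=bidirectional,
                          hidden_sizes=(5, 4))
        model = BalanceRNN(cfg, seed=0)
        x = rng.standard_normal((3, 6, 101))
        assert model.predict(x).shape == (3, 2, 101)
        assert model.predict(x[0]).shape == (2, 101)

    def test_layer_matches_scalar_oracle_full_sequence(self, rng):
        cfg = ModelConfig(cell_type="lstm", bidirectional=False,
                          hidden_sizes=(4, 3), seq_len=9, input_channels=2)
        model = BalanceRNN(cfg, seed=3)
        x = rng.standard_normal((1, 9, 2))
        y, _ = model.layer1.forward(x)
        oracle = _scalar_lstm_sequence(x[0], model.layer1.directions[0])
        assert np.abs(y[0] - oracle).max() < 1e-12

    def test_unidirectional_layer_is_causal(self, rng):
        """Per-step outputs at step t ignore inputs at steps > t."""
        cfg = ModelConfig(cell_type="gru", bidirectional=False,
                          hidden_sizes=(4, 3))
        model = BalanceRNN(cfg, seed=0)
        x = rng.standard_normal((1, 101, 6))
        y, _ = model.layer1.forward(x)
        x2 = x.copy()
        x2[:, 60:] += 10.0
        y2, _ = model.layer1.forward(x2)
        assert np.allclose(y[:, :60], y2[:, :60])
        assert not np.allclose(y[:, 60:], y2[:, 60:])

    def test_bidirectional_layer_sees_future(self, rng):
        """Perturbing future steps changes earlier bi-directional outputs
        (through the backward pass), unlike the uni-directional case."""
        cfg = ModelConfig(cell_type="gru", bidirectional=True,
                          hidden_sizes=(4, 3))
        model = BalanceRNN(cfg, seed=0)
        x = rng.standard_normal((1, 101, 6))
        y, _ = model.layer1.forward(x)
        x2 = x.copy()
        x2[:, 50:] += 10.0
        y2, _ = model.layer1.forward(x2)
        assert not np.allclose(y[:, 49], y2[:, 49])

    def test_bidirectional_symmetric_weights_palindrome(self, rng):
        """Direction-symmetric weights on a palindromic input give
        step-symmetric concatenated outputs (forward at t = backward at T-1-t)."""
        cfg = ModelConfig(cell_type="gru", bidirectional=True,
                          hidden_sizes=(4, 3), seq_len=11, input_channels=2)
        model = BalanceRNN(cfg, seed=0)
        layer = model.layer1
        for name in ("w_x", "w_h", "b_x", "b_h"):
            setattr(layer.directions[1], name,
                    getattr(layer.directions[0], name).copy())
        half = rng.standard_normal((1, 5, 2))
        mid = rng.standard_normal((1, 1, 2))
        x = np.concatenate([half, mid, half[:, ::-1]], axis=1)  # palindrome
        y, _ = layer.forward(x)
        H = 4
        assert np.allclose(y[0, :, :H], y[0, ::-1, H:], atol=1e-12)

    def test_gate_and_state_bounds(self, rng):
        """All gate activations in (0,1); LSTM hidden state in (-1,1)."""
        p = CellParams.init("lstm", 3, 5, rng)
        state = (np.zeros(5), np.zeros(5))
        for x in rng.standard_normal((50, 3)) * 5:
            y, state = lstm_step(x, state, p)
            assert np.all(np.abs(state[0]) < 1.0)

    def test_wrong_input_shape_rejected(self, rng):
        model = BalanceRNN(ModelConfig(hidden_sizes=(3, 2)), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            model.predict(rng.standard_normal((4, 101)))


class TestCountParameters:
    def test_small_lstm_layer_enumeration(self):
        """d=2, H=3, one direction: 4 gates x (6 + 9 + 6) = 84."""
        cfg = ModelConfig(cell_type="lstm", bidirectional=False,
                          hidden_sizes=(3, 3), input_channels=2)
        _, br = count_parameters(cfg)
        assert br["recurrent_1"] == 84

    def test_small_gru_layer_enumeration(self):
        cfg = ModelConfig(cell_type="gru", bidirectional=False,
                          hidden_sizes=(3, 3), input_channels=2)
        _, br = count_parameters(cfg)
        assert br["recurrent_2"] == 3 * (3 * 3 + 9 + 6)

    def test_gru_lstm_ratio_exactly_three_quarters(self):
        for bi in (False, True):
            lstm = count_parameters(ModelConfig("lstm", bi, "table5"))[0]
            gru = count_parameters(ModelConfig("gru", bi, "table5"))[0]
            assert gru * 4 == lstm * 3

    def test_counts_match_instantiated_model(self):
        for cell in ("lstm", "gru"):
            for bi in (False, True):
                cfg = ModelConfig(cell_type=cell, bidirectional=bi,
                                  hidden_sizes=(5, 4))
                model = BalanceRNN(cfg, seed=0)
                assert (model.n_parameters("recurrent_only")
                        == count_parameters(cfg, "recurrent_only")[0])
                assert (model.n_parameters("full")
                        == count_parameters(cfg, "full")[0])

    def test_profiles_exposed(self):
        assert ARCHITECTURE_PROFILES["table5"] == (512, 512)
        assert ARCHITECTURE_PROFILES["text"] == (256, 64)
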