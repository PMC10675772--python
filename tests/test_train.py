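"""Losses, finite differences, dataset splitting, and the training loop."""

import numpy as np
import pytest

from gaitbalance.imuprep import ChannelScaler
from gaitbalance.rnn import BalanceRNN, ModelConfig
from gaitbalance.train import (Adam, LossConfig, TrainConfig, finite_diff,
                               split_dataset, standard_mse, standard_mse_grad,
                               train_model, weighted_mse, weighted_mse_grad)


class TestStandardMse:
    def test_perfect_prediction_is_zero(self, rng):
        y = rng.standard_normal((2, 101))
        assert standard_mse(y, y) == 0.0

    def test_hand_example(self):
        assert np.isclose(standard_mse([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]),
                          2.0 / 3.0)

    def test_constant_shift_adds_square(self, rng):
        y = rng.standard_normal((2, 101))
        c = 0.7
        assert np.isclose(standard_mse(y + c, y), c ** 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            standard_mse(np.zeros((2, 101)), np.zeros((2, 100)))


class TestFiniteDiff:
    def test_linear_ramp(self):
        y = 2.0 * np.arange(101.0)
        assert np.allclose(finite_diff(y, 1.0), 2.0)

    def test_hand_example(self):
        assert np.allclose(finite_diff(np.array([0.0, 1.0, 2.0]), 1.0),
                           [1.0, 1.0, 1.0])
        assert np.allclose(finite_diff(np.array([1.0, 1.0, 1.0]), 1.0), 0.0)

    def test_quadratic_interior_second_order(self):
        for dt in (0.1, 0.05):
            t = np.arange(0.0, 2.0, dt)
            d = finite_diff(t ** 2, dt)
            err = np.abs(d[1:-1] - 2 * t[1:-1]).max()
            assert err < 1e-10  # central differences are exact on quadratics

    def test_cubic_interior_error_scales_with_dt_squared(self):
        errs = []
        for dt in (0.1, 0.05):
            t = np.arange(0.0, 2.0, dt)
            d = finite_diff(t ** 3, dt)
            errs.append(np.abs(d[1:-1] - 3 * t[1:-1] ** 2).max())
        assert errs[1] < errs[0] / 3.5  # ~ factor 4 for O(dt^2)


class TestWeightedMse:
    def test_zero_when_both_terms_match(self, rng):
        y = rng.standard_normal((2, 101))
        cfg = LossConfig(kind="weighted_mse", lam=5.0)
        assert weighted_mse(y, y, finite_diff(y, 0.011), cfg, 0.011) == 0.0

    def test_lambda_zero_equals_standard_mse(self, rng):
        p = rng.standard_normal((2, 101))
        y = rng.standard_normal((2, 101))
        cfg = LossConfig(kind="weighted_mse", lam=0.0)
        assert np.isclose(weighted_mse(p, y, np.zeros_like(y), cfg, 0.011),
                          standard_mse(p, y))

    def test_hand_example(self):
        truth = np.array([0.0, 1.0, 2.0])
        pred = np.array([1.0, 1.0, 1.0])
        cfg = LossConfig(kind="weighted_mse", lam=5.0)
        loss = weighted_mse(pred, truth, finite_diff(truth, 1.0), cfg, 1.0)
        assert np.isclose(loss, 2.0 / 3.0 + 5.0 * 1.0)

    def test_losses_nonnegative_and_zero_iff_match(self, rng):
        y = rng.standard_normal((2, 101))
        p = y + rng.standard_normal((2, 101)) * 0.1
        cfg = LossConfig(kind="weighted_mse", lam=5.0)
        r = finite_diff(y, 0.011)
        assert weighted_mse(p, y, r, cfg, 0.011) > 0.0
        assert weighted_mse(y, y, r, cfg, 0.011) == 0.0


class TestLossGradients:
    @pytest.mark.parametrize("kind,lam", [("standard_mse", 0.0),
                                          ("weighted_mse", 5.0)])
    def test_analytic_matches_numerical(self, kind, lam, rng):
        p = rng.standard_normal((3, 2, 11))
        y = rng.standard_normal((3, 2, 11))
        r = rng.standard_normal((3, 2, 11))
        dt = rng.uniform(0.009, 0.013, (3, 1, 1))
        cfg = LossConfig(kind="weighted_mse", lam=lam)

        def loss(x):
            if kind == "standard_mse":
                return standard_mse(x, y)
            return weighted_mse(x, y, r, cfg, dt)

        if kind == "standard_mse":
            ana = standard_mse_grad(p, y)
        else:
            ana = weighted_mse_grad(p, y, r, cfg, dt)
        num = np.zeros_like(p)
        eps = 1e-6
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss(p)
            p[idx] = orig - eps
            lm = loss(p)
            p[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        assert (np.linalg.norm(num - ana)
                < 1e-5 * max(np.linalg.norm(num), 1e-8))


class TestModelGradients:
    @pytest.mark.parametrize("cell", ["lstm", "gru"])
    @pytest.mark.parametrize("bidirectional", [False, True])
    def test_backprop_matches_numerical(self, cell, bidirectional, rng):
        """End-to-end gradient check through both recurrent layers and the
        dense stages, per parameter block, norm-wise."""
        cfg = ModelConfig(cell_type=cell, bidirectional=bidirectional,
                          hidden_sizes=(3, 2), seq_len=7, input_channels=2)
        model = BalanceRNN(cfg, seed=1)
        X = rng.standard_normal((2, 2, 7))
        Y = rng.standard_normal((2, 2, 7))
        R = rng.standard_normal((2, 2, 7))
        lcfg = LossConfig(kind="weighted_mse", lam=5.0)
        dt = 0.011
        pred = model.forward(X, keep_cache=True)
        grads = model.backward(weighted_mse_grad(pred, Y, R, lcfg, dt))
        params = model.parameters()
        eps = 1e-6
        for name, p in params.items():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + eps
                lp = weighted_mse(model.predict(X), Y, R, lcfg, dt)
                p[idx] = orig - eps
                lm = weighted_mse(model.predict(X), Y, R, lcfg, dt)
                p[idx] = orig
                num[idx] = (lp - lm) / (2 * eps)
            err = np.linalg.norm(num - grads[name])
            assert err < 1e-5 * max(np.linalg.norm(num), 1e-6), name


class TestSplitDataset:
    def test_published_cohort_size(self):
        tr, va, te = split_dataset(list(range(520)))
        assert (len(tr), len(va), len(te)) == (416, 52, 52)

    def test_ten_trials(self):
        tr, va, te = split_dataset(list(range(10)))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_deterministic_and_disjoint(self):
        items = list(range(37))
        a = split_dataset(items, seed=5)
        b = split_dataset(items, seed=5)
        assert all(x == y for x, y in zip(a[0], b[0]))
        combined = sorted(a[0] + a[1] + a[2])
        assert combined == items

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(3)))


class TestTrainModel:
    def _setup(self, small_cohort, lam, seed=0, epochs=3):
        tr, va, te = split_dataset(small_cohort.trials, seed=seed)
        scaler = ChannelScaler.fit(tr)
        model = BalanceRNN(ModelConfig(cell_type="gru", bidirectional=False,
                                       hidden_sizes=(8, 6)), seed=seed)
        tcfg = TrainConfig(learning_rate=1e-3, epochs=epochs, batch_size=8,
                           seed=seed)
        lcfg = LossConfig(kind="weighted_mse", lam=lam)
        return model, tr, va, scaler, tcfg, lcfg

    def test_zero_epoch_run_leaves_model_unchanged(self, small_cohort):
        model, tr, va, scaler, tcfg, lcfg = self._setup(small_cohort, 5.0)
        before = {k: v.copy() for k, v in model.parameters().items()}
        tcfg = TrainConfig(learning_rate=1e-3, epochs=1, batch_size=8)
        tcfg.epochs = 0
        hist = train_model(model, tr, va, scaler, tcfg, lcfg)
        assert hist.train_loss == []
        after = model.parameters()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_loss_decreases(self, small_cohort):
        model, tr, va, scaler, tcfg, lcfg = self._setup(small_cohort, 5.0,
                                                        epochs=5)
        hist = train_model(model, tr, va, scaler, tcfg, lcfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == len(hist.val_loss) == 5

    def test_history_retains_best_validation_epoch(self, small_cohort):
        model, tr, va, scaler, tcfg, lcfg = self._setup(small_cohort, 5.0,
                                                        epochs=4)
        hist = train_model(model, tr, va, scaler, tcfg, lcfg)
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_divergence_aborts_with_diagnostic(self, small_cohort):
        model, tr, va, scaler, tcfg, lcfg = self._setup(small_cohort, 5.0)
        model.dense_w[0, 0] = np.nan  # poisoned state -> non-finite loss
        with pytest.raises(FloatingPointError, match="diverged"):
            train_model(model, tr, va, scaler, tcfg, lcfg)

    def test_evaluation_loss_invariant_to_trial_order(self, small_cohort, rng):
        from gaitbalance.train import evaluate_loss
        model, tr, va, scaler, _, lcfg = self._setup(small_cohort, 5.0)
        shuffled = list(tr)
        rng.shuffle(shuffled)
        assert np.isclose(evaluate_loss(model, tr, scaler, lcfg),
                          evaluate_loss(model, shuffled, scaler, lcfg))


class TestAdam:
    def test_quadratic_convergence(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = Adam(params, lr=0.1)
        for _ in range(500):
            opt.step(params, {"w": 2 * params["w"]})
        assert np.abs(params["w"]).max() < 1e-3
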