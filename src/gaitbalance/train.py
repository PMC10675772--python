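"""Loss functions, dataset splitting, and the Adam training loop.

Two losses are available for curve regression over the N = 101 steps of the
normalized gait cycle:

* standard MSE: mean squared IA error;
* weighted MSE: the IA term plus ``lambda`` times the mean squared error of
  the finite-difference rate of change of the predicted IA against the
  ground-truth RCIA.

The loss operates on scaled model outputs; the RCIA term divides the
per-step difference by ``dt = cycle_duration / 100`` of each trial so the
weighting keeps rate-of-change (per-second) semantics across trials of
different durations.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .imuprep import ChannelScaler, NormalizedTrial
from .rnn import BalanceRNN

__all__ = [
    "LossConfig",
    "TrainConfig",
    "TrainingHistory",
    "standard_mse",
    "weighted_mse",
    "finite_diff",
    "split_dataset",
    "train_model",
    "Adam",
]


@dataclass
class LossConfig:
    """kind: 'standard_mse' or 'weighted_mse'; lam: RCIA weight (default 5)."""

    kind: str = "weighted_mse"
    lam: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("standard_mse", "weighted_mse"):
            raise ValueError("kind must be 'standard_mse' or 'weighted_mse'")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class TrainConfig:
    """Optimizer protocol; defaults follow the published training setup."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 100
    batch_size: int = 32
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.learning_rate, self.beta1, self.beta2,
               self.epochs, self.batch_size) <= 0:
            raise ValueError("all training parameters must be positive")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def standard_mse(pred_ia: np.ndarray, true_ia: np.ndarray) -> float:
    """Mean squared IA error over the cycle, averaged over planes and batch."""
    pred_ia = np.asarray(pred_ia, float)
    true_ia = np.asarray(true_ia, float)
    if pred_ia.shape != true_ia.shape:
        raise ValueError("prediction and target shapes differ")
    return float(np.mean((pred_ia - true_ia) ** 2))


def standard_mse_grad(pred_ia: np.ndarray, true_ia: np.ndarray) -> np.ndarray:
    d = np.asarray(pred_ia, float) - np.asarray(true_ia, float)
    return 2.0 * d / d.size


def finite_diff(curve: np.ndarray, dt: float | np.ndarray = 1.0) -> np.ndarray:
    """Finite-difference derivative along the last axis.

    Central differences at interior points, one-sided at both ends.
    ``dt`` may be a scalar or broadcast per-sample (e.g. one cycle duration
    per batch element).
    """
    y = np.asarray(curve, float)
    if y.shape[-1] < 2:
        raise ValueError("need at least two samples")
    d = np.empty_like(y)
    d[..., 0] = y[..., 1] - y[..., 0]
    d[..., -1] = y[..., -1] - y[..., -2]
    d[..., 1:-1] = (y[..., 2:] - y[..., :-2]) / 2.0
    return d / dt


def _finite_diff_adjoint(g: np.ndarray, dt: float | np.ndarray) -> np.ndarray:
    """Adjoint (transpose) of the finite-difference operator."""
    g = np.asarray(g, float) / dt
    out = np.zeros_like(g)
    out[..., 0] -= g[..., 0]
    out[..., 1] += g[..., 0]
    out[..., -1] += g[..., -1]
    out[..., -2] -= g[..., -1]
    out[..., 2:] += g[..., 1:-1] / 2.0
    out[..., :-2] -= g[..., 1:-1] / 2.0
    return out


def weighted_mse(
    pred_ia: np.ndarray,
    true_ia: np.ndarray,
    true_rcia: np.ndarray,
    config: LossConfig,
    dt: float | np.ndarray = 1.0,
) -> float:
    """IA MSE + lambda * MSE of finite-difference RCIA against ground truth.

    All three curve arrays share a shape (..., N); ``true_rcia`` must be
    expressed in the same units as ``finite_diff(pred_ia, dt)``.
    With ``lam = 0`` this equals ``standard_mse`` exactly.
    """
    pred_ia = np.asarray(pred_ia, float)
    if pred_ia.shape != np.shape(true_ia) or pred_ia.shape != np.shape(true_rcia):
        raise ValueError("prediction/target shapes differ")
    ia_term = np.mean((pred_ia - true_ia) ** 2)
    rcia_term = np.mean((finite_diff(pred_ia, dt) - true_rcia) ** 2)
    return float(ia_term + config.lam * rcia_term)


def weighted_mse_grad(
    pred_ia: np.ndarray,
    true_ia: np.ndarray,
    true_rcia: np.ndarray,
    config: LossConfig,
    dt: float | np.ndarray = 1.0,
) -> np.ndarray:
    pred_ia = np.asarray(pred_ia, float)
    n = pred_ia.size
    g = 2.0 * (pred_ia - np.asarray(true_ia, float)) / n
    resid = finite_diff(pred_ia, dt) - np.asarray(true_rcia, float)
    g = g + config.lam * _finite_diff_adjoint(2.0 * resid / n, dt)
    return g


# ---------------------------------------------------------------------------
# dataset handling
# ---------------------------------------------------------------------------

def split_dataset(
    trials: list,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Disjoint, exhaustive, seed-deterministic trial-level split.

    Counts are ``round(f * n)`` for the train and validation fractions with
    the remainder in the test set (520 trials at 80/10/10 -> 416/52/52).
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n = len(trials)
    n_train = round(split[0] * n)
    n_val = round(split[1] * n)
    if n_train == 0 or n_val == 0 or n - n_train - n_val == 0:
        raise ValueError(f"{n} trials cannot fill a {split} split")
    order = np.random.default_rng(seed).permutation(n)
    sets = (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])
    return tuple([trials[i] for i in idx] for idx in sets)


def _stack(trials: list[NormalizedTrial], scaler: ChannelScaler):
    """Scaled arrays for a trial list: X (B,6,101), Y (B,2,101), rates, dt."""
    X = np.stack([scaler.scale_inputs(t.imu) for t in trials])
    Y = np.stack([scaler.scale_outputs(t.target_ia) for t in trials])
    # ground-truth RCIA in scaled units per second
    gain = scaler.output_gain[:, None]
    R = np.stack([t.target_rcia / gain for t in trials])
    dt = np.array([t.cycle_duration_s / 100.0 for t in trials])
    return X, Y, R, dt[:, None, None]


class Adam:
    """Adaptive moment estimation on a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _batch_loss_and_grad(model, X, Y, R, dt, loss_cfg):
    pred = model.forward(X, keep_cache=True)
    if loss_cfg.kind == "standard_mse":
        loss = standard_mse(pred, Y)
        dpred = standard_mse_grad(pred, Y)
    else:
        loss = weighted_mse(pred, Y, R, loss_cfg, dt)
        dpred = weighted_mse_grad(pred, Y, R, loss_cfg, dt)
    return loss, model.backward(dpred)


def evaluate_loss(model: BalanceRNN, trials, scaler, loss_cfg: LossConfig) -> float:
    X, Y, R, dt = _stack(trials, scaler)
    pred = model.predict(X)
    if loss_cfg.kind == "standard_mse":
        return standard_mse(pred, Y)
    return weighted_mse(pred, Y, R, loss_cfg, dt)


def train_model(
    model: BalanceRNN,
    train_trials: list[NormalizedTrial],
    val_trials: list[NormalizedTrial],
    scaler: ChannelScaler,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> TrainingHistory:
    """Minimize the configured loss with Adam; retain the best-validation
    parameters in ``model``.

    The scaler must have been fitted on the training split only.  The
    history records the running mean training loss and the validation loss
    of each epoch.  A zero-epoch config returns the model unchanged.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(train_cfg.seed)
    X, Y, R, dt = _stack(train_trials, scaler)
    n = len(train_trials)
    opt = Adam(model.parameters(), train_cfg.learning_rate,
               train_cfg.beta1, train_cfg.beta2)
    history = TrainingHistory()
    best_val = np.inf
    best_params = copy.deepcopy(model.parameters())
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            loss, grads = _batch_loss_and_grad(
                model, X[idx], Y[idx], R[idx], dt[idx], loss_cfg)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            params = model.parameters()
            opt.step(params, grads)
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        val = evaluate_loss(model, val_trials, scaler, loss_cfg)
        history.val_loss.append(float(val))
        if val < best_val:
            best_val = val
            best_epoch = epoch
            best_params = copy.deepcopy(model.parameters())
            history.best_epoch = best_epoch
    if history.train_loss:
        model.set_parameters(best_params)
    return history
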