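"""Recurrent regressors mapping IMU cycles to inclination-angle curves.

Implemented from the gate equations directly in NumPy (forward and
backward), so the cell math is inspectable and exactly matches the
published formulation:

LSTM (gate order f, i, o, candidate)::

    f_t = sigma(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigma(W_i [h_{t-1}, x_t] + b_i)
    o_t = sigma(W_o [h_{t-1}, x_t] + b_o)
    c_t = f_t o c_{t-1} + i_t o tanh(W_c [h_{t-1}, x_t] + b_c)
    h_t = o_t o tanh(c_t);   y_t = h_t

GRU (gate order u, r, candidate), with the update gate weighting the new
candidate::

    u_t = sigma(W_u [h_{t-1}, x_t] + b_u)
    r_t = sigma(W_r [h_{t-1}, x_t] + b_r)
    h_t = (1 - u_t) o h_{t-1} + u_t o tanh(W_h [r_t o h_{t-1}, x_t] + b_h)
    y_t = h_t

Each gate carries dual bias vectors (an input-side and a recurrent-side
one), so a recurrent layer with input width d, hidden size H and G gate
blocks holds G (dH + H^2 + 2H) parameters per direction.

The full model stacks two recurrent layers (uni- or bi-directional; a
bi-directional layer concatenates the forward and backward hidden state at
every step), flattens the per-step outputs of layer 2, and applies a
202-unit tanh dense stage followed by a 202-unit linear output stage,
reshaped to the 2 x 101 sagittal/frontal IA curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellParams",
    "ModelConfig",
    "BalanceRNN",
    "lstm_step",
    "gru_step",
    "count_parameters",
    "ARCHITECTURE_PROFILES",
]

# hidden sizes (H1, H2) of the two recurrent layers
ARCHITECTURE_PROFILES: dict[str, tuple[int, int]] = {
    "table5": (512, 512),  # reproduces the published parameter counts
    "text": (256, 64),     # the written 256/64-cell description
}

GATE_BLOCKS = {"lstm": 4, "gru": 3}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class CellParams:
    """Weights of one recurrent direction.

    ``w_x``: (G*H, d) input weights, ``w_h``: (G*H, H) recurrent weights,
    ``b_x``/``b_h``: (G*H,) dual bias vectors; gate blocks are stacked in
    order (f, i, o, c) for LSTM and (u, r, h) for GRU.
    """

    cell_type: str
    w_x: np.ndarray
    w_h: np.ndarray
    b_x: np.ndarray
    b_h: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_type not in GATE_BLOCKS:
            raise ValueError("cell_type must be 'lstm' or 'gru'")
        G = GATE_BLOCKS[self.cell_type]
        H = self.hidden_size
        if self.w_h.shape != (G * H, H) or self.w_x.shape[0] != G * H:
            raise ValueError("inconsistent gate-block shapes")
        if self.b_x.shape != (G * H,) or self.b_h.shape != (G * H,):
            raise ValueError("bias vectors must be (gates*hidden,)")

    @property
    def hidden_size(self) -> int:
        return self.w_h.shape[1]

    @property
    def input_size(self) -> int:
        return self.w_x.shape[1]

    @classmethod
    def init(cls, cell_type: str, input_size: int, hidden_size: int,
             rng: np.random.Generator) -> "CellParams":
        """Uniform init in +/- 1/sqrt(H), seed-controlled."""
        G = GATE_BLOCKS[cell_type]
        s = 1.0 / np.sqrt(hidden_size)
        return cls(
            cell_type=cell_type,
            w_x=rng.uniform(-s, s, (G * hidden_size, input_size)),
            w_h=rng.uniform(-s, s, (G * hidden_size, hidden_size)),
            b_x=rng.uniform(-s, s, G * hidden_size),
            b_h=rng.uniform(-s, s, G * hidden_size),
        )

    def n_params(self) -> int:
        return self.w_x.size + self.w_h.size + self.b_x.size + self.b_h.size


# ---------------------------------------------------------------------------
# single-step cell updates (reference API; the layer loop inlines the math)
# ---------------------------------------------------------------------------

def lstm_step(
    x_t: np.ndarray,
    state: tuple[np.ndarray, np.ndarray],
    params: CellParams,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """One LSTM update; ``state`` is (h_prev, c_prev). Returns (y_t, state)."""
    if params.cell_type != "lstm":
        raise ValueError("params are not LSTM parameters")
    h_prev, c_prev = state
    x_t = np.atleast_1d(np.asarray(x_t, float))
    if x_t.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError("input/state shape mismatch with parameters")
    H = params.hidden_size
    a = x_t @ params.w_x.T + h_prev @ params.w_h.T + params.b_x + params.b_h
    f = _sigmoid(a[..., 0:H])
    i = _sigmoid(a[..., H:2 * H])
    o = _sigmoid(a[..., 2 * H:3 * H])
    g = np.tanh(a[..., 3 * H:4 * H])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, (h, c)


def gru_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    params: CellParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One GRU update. Returns (y_t, h_t)."""
    if params.cell_type != "gru":
        raise ValueError("params are not GRU parameters")
    x_t = np.atleast_1d(np.asarray(x_t, float))
    if x_t.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ValueError("input/state shape mismatch with parameters")
    H = params.hidden_size
    wx, wh = params.w_x, params.w_h
    a_ur = (x_t @ wx[:2 * H].T + h_prev @ wh[:2 * H].T
            + params.b_x[:2 * H] + params.b_h[:2 * H])
    u = _sigmoid(a_ur[..., :H])
    r = _sigmoid(a_ur[..., H:])
    a_n = (x_t @ wx[2 * H:].T + (r * h_prev) @ wh[2 * H:].T
           + params.b_x[2 * H:] + params.b_h[2 * H:])
    n = np.tanh(a_n)
    h = (1.0 - u) * h_prev + u * n
    return h, h


# ---------------------------------------------------------------------------
# batched layer forward/backward
# ---------------------------------------------------------------------------

class _DirectionCache:
    __slots__ = ("x", "h_prev", "c_prev", "gates", "extra")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _lstm_forward(x: np.ndarray, p: CellParams):
    """x: (B, T, d) -> h-sequence (B, T, H) + cache."""
    B, T, _ = x.shape
    H = p.hidden_size
    xw = x @ p.w_x.T + (p.b_x + p.b_h)          # (B, T, 4H)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, T, H))
    h_prev = np.empty((B, T, H))
    c_prev = np.empty((B, T, H))
    gates = np.empty((B, T, 4 * H))             # f, i, o, g post-activation
    tanh_c = np.empty((B, T, H))
    for t in range(T):
        a = xw[:, t] + h @ p.w_h.T
        f = _sigmoid(a[:, :H])
        i = _sigmoid(a[:, H:2 * H])
        o = _sigmoid(a[:, 2 * H:3 * H])
        g = np.tanh(a[:, 3 * H:])
        h_prev[:, t] = h
        c_prev[:, t] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        gates[:, t, :H] = f
        gates[:, t, H:2 * H] = i
        gates[:, t, 2 * H:3 * H] = o
        gates[:, t, 3 * H:] = g
        tanh_c[:, t] = tc
    cache = _DirectionCache(x=x, h_prev=h_prev, c_prev=c_prev, gates=gates,
                            extra=tanh_c)
    return hs, cache


def _lstm_backward(dh_seq: np.ndarray, p: CellParams, cache: _DirectionCache):
    B, T, H = dh_seq.shape
    gates, tanh_c = cache.gates, cache.extra
    dA = np.empty((B, T, 4 * H))
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + dh_seq[:, t]
        f = gates[:, t, :H]
        i = gates[:, t, H:2 * H]
        o = gates[:, t, 2 * H:3 * H]
        g = gates[:, t, 3 * H:]
        tc = tanh_c[:, t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        df = dc * cache.c_prev[:, t]
        di = dc * g
        dg = dc * i
        dA[:, t, :H] = df * f * (1.0 - f)
        dA[:, t, H:2 * H] = di * i * (1.0 - i)
        dA[:, t, 2 * H:3 * H] = do * o * (1.0 - o)
        dA[:, t, 3 * H:] = dg * (1.0 - g * g)
        dh = dA[:, t] @ p.w_h
        dc = dc * f
    dx = dA @ p.w_x
    grads = {
        "w_x": np.einsum("btg,btd->gd", dA, cache.x),
        "w_h": np.einsum("btg,bth->gh", dA, cache.h_prev),
    }
    db = dA.sum(axis=(0, 1))
    grads["b_x"] = db
    grads["b_h"] = db.copy()
    return dx, grads


def _gru_forward(x: np.ndarray, p: CellParams):
    B, T, _ = x.shape
    H = p.hidden_size
    wx_ur, wx_n = p.w_x[:2 * H], p.w_x[2 * H:]
    wh_ur, wh_n = p.w_h[:2 * H], p.w_h[2 * H:]
    b_ur = p.b_x[:2 * H] + p.b_h[:2 * H]
    b_n = p.b_x[2 * H:] + p.b_h[2 * H:]
    xw_ur = x @ wx_ur.T + b_ur
    xw_n = x @ wx_n.T + b_n
    h = np.zeros((B, H))
    hs = np.empty((B, T, H))
    h_prev = np.empty((B, T, H))
    gates = np.empty((B, T, 3 * H))             # u, r, n post-activation
    rh = np.empty((B, T, H))
    for t in range(T):
        a_ur = xw_ur[:, t] + h @ wh_ur.T
        u = _sigmoid(a_ur[:, :H])
        r = _sigmoid(a_ur[:, H:])
        rh_t = r * h
        n = np.tanh(xw_n[:, t] + rh_t @ wh_n.T)
        h_prev[:, t] = h
        h = (1.0 - u) * h + u * n
        hs[:, t] = h
        gates[:, t, :H] = u
        gates[:, t, H:2 * H] = r
        gates[:, t, 2 * H:] = n
        rh[:, t] = rh_t
    cache = _DirectionCache(x=x, h_prev=h_prev, c_prev=None, gates=gates,
                            extra=rh)
    return hs, cache


def _gru_backward(dh_seq: np.ndarray, p: CellParams, cache: _DirectionCache):
    B, T, H = dh_seq.shape
    gates, rh = cache.gates, cache.extra
    wh_ur, wh_n = p.w_h[:2 * H], p.w_h[2 * H:]
    dA_ur = np.empty((B, T, 2 * H))
    dA_n = np.empty((B, T, H))
    dh = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        dh = dh + dh_seq[:, t]
        u = gates[:, t, :H]
        r = gates[:, t, H:2 * H]
        n = gates[:, t, 2 * H:]
        h_prev = cache.h_prev[:, t]
        du = dh * (n - h_prev)
        dn = dh * u
        dh_next = dh * (1.0 - u)
        da_n = dn * (1.0 - n * n)
        drh = da_n @ wh_n
        dr = drh * h_prev
        dh_next = dh_next + drh * r
        dA_n[:, t] = da_n
        dA_ur[:, t, :H] = du * u * (1.0 - u)
        dA_ur[:, t, H:] = dr * r * (1.0 - r)
        dh = dh_next + dA_ur[:, t] @ wh_ur
    dx = dA_ur @ p.w_x[:2 * H] + dA_n @ p.w_x[2 * H:]
    gw_x = np.vstack([np.einsum("btg,btd->gd", dA_ur, cache.x),
                      np.einsum("btg,btd->gd", dA_n, cache.x)])
    gw_h = np.vstack([np.einsum("btg,bth->gh", dA_ur, cache.h_prev),
                      np.einsum("btg,bth->gh", dA_n, rh)])
    db = np.concatenate([dA_ur.sum(axis=(0, 1)), dA_n.sum(axis=(0, 1))])
    return dx, {"w_x": gw_x, "w_h": gw_h, "b_x": db, "b_h": db.copy()}


_FORWARD = {"lstm": _lstm_forward, "gru": _gru_forward}
_BACKWARD = {"lstm": _lstm_backward, "gru": _gru_backward}


class RecurrentLayer:
    """One uni- or bi-directional recurrent layer (batch-first)."""

    def __init__(self, cell_type: str, input_size: int, hidden_size: int,
                 bidirectional: bool, rng: np.random.Generator):
        self.cell_type = cell_type
        self.bidirectional = bidirectional
        self.directions = [CellParams.init(cell_type, input_size, hidden_size, rng)]
        if bidirectional:
            self.directions.append(
                CellParams.init(cell_type, input_size, hidden_size, rng))

    @property
    def output_size(self) -> int:
        return self.directions[0].hidden_size * len(self.directions)

    def forward(self, x: np.ndarray):
        """x: (B, T, d) -> (B, T, H * n_directions), caches."""
        fwd, cache_f = _FORWARD[self.cell_type](x, self.directions[0])
        if not self.bidirectional:
            return fwd, (cache_f, None)
        bwd, cache_b = _FORWARD[self.cell_type](x[:, ::-1], self.directions[1])
        return np.concatenate([fwd, bwd[:, ::-1]], axis=2), (cache_f, cache_b)

    def backward(self, dy: np.ndarray, caches):
        cache_f, cache_b = caches
        H = self.directions[0].hidden_size
        dx, grads_f = _BACKWARD[self.cell_type](
            np.ascontiguousarray(dy[:, :, :H]), self.directions[0], cache_f)
        grads = [grads_f]
        if self.bidirectional:
            dx_b, grads_b = _BACKWARD[self.cell_type](
                np.ascontiguousarray(dy[:, ::-1, H:]), self.directions[1], cache_b)
            dx = dx + dx_b[:, ::-1]
            grads.append(grads_b)
        return dx, grads


@dataclass
class ModelConfig:
    """Architecture of a balance-curve regressor.

    ``profile`` selects the published hidden sizes: "table5" (512, 512)
    matches the reported total parameter counts exactly; "text" (256, 64)
    matches the written layer-size description and is cheap enough for
    CPU training.  ``hidden_sizes`` overrides the profile when given.
    """

    cell_type: str = "gru"
    bidirectional: bool = True
    profile: str = "table5"
    hidden_sizes: tuple[int, int] | None = None
    input_channels: int = 6
    seq_len: int = 101
    output_planes: int = 2

    def __post_init__(self) -> None:
        if self.cell_type not in GATE_BLOCKS:
            raise ValueError("cell_type must be 'lstm' or 'gru'")
        if self.hidden_sizes is None:
            if self.profile not in ARCHITECTURE_PROFILES:
                raise ValueError(f"unknown profile {self.profile!r}")
            self.hidden_sizes = ARCHITECTURE_PROFILES[self.profile]
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)

    @property
    def output_units(self) -> int:
        # one neuron per plane per percent of the gait cycle
        return self.output_planes * self.seq_len

    @property
    def dense_units(self) -> int:
        return self.output_units


def count_parameters(config: ModelConfig, scope: str = "recurrent_only"):
    """Exact parameter count with a per-layer breakdown.

    A recurrent layer with input width d, hidden H and G gate blocks has
    ``G (dH + H^2 + 2H)`` parameters per direction (dual bias vectors); a
    bi-directional layer doubles this and doubles the next layer's input
    width.  ``scope="full"`` adds the dense and output stages.
    Returns ``(total, breakdown)``.
    """
    if scope not in ("recurrent_only", "full"):
        raise ValueError("scope must be 'recurrent_only' or 'full'")
    G = GATE_BLOCKS[config.cell_type]
    ndir = 2 if config.bidirectional else 1
    H1, H2 = config.hidden_sizes
    breakdown: dict[str, int] = {}
    d = config.input_channels
    for name, H in (("recurrent_1", H1), ("recurrent_2", H2)):
        per_dir = G * (d * H + H * H + 2 * H)
        breakdown[name] = ndir * per_dir
        d = ndir * H
    total = sum(breakdown.values())
    if scope == "full":
        flat = config.seq_len * ndir * H2
        breakdown["dense"] = flat * config.dense_units + config.dense_units
        breakdown["output"] = (config.dense_units * config.output_units
                               + config.output_units)
        total += breakdown["dense"] + breakdown["output"]
    return total, breakdown


class BalanceRNN:
    """Two recurrent layers + flattened 202-unit dense and output stages.

    ``forward`` maps a scaled IMU batch (B, 6, 101) to scaled IA curves
    (B, 2, 101); ``backward`` returns gradients for every parameter given
    the loss gradient with respect to the output.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        H1, H2 = config.hidden_sizes
        self.layer1 = RecurrentLayer(config.cell_type, config.input_channels,
                                     H1, config.bidirectional, rng)
        self.layer2 = RecurrentLayer(config.cell_type, self.layer1.output_size,
                                     H2, config.bidirectional, rng)
        flat = config.seq_len * self.layer2.output_size
        s1 = 1.0 / np.sqrt(flat)
        s2 = 1.0 / np.sqrt(config.dense_units)
        self.dense_w = rng.uniform(-s1, s1, (config.dense_units, flat))
        self.dense_b = rng.uniform(-s1, s1, config.dense_units)
        self.out_w = rng.uniform(-s2, s2, (config.output_units, config.dense_units))
        self.out_b = rng.uniform(-s2, s2, config.output_units)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        params = {}
        for li, layer in ((1, self.layer1), (2, self.layer2)):
            for di, p in enumerate(layer.directions):
                for n in ("w_x", "w_h", "b_x", "b_h"):
                    params[f"layer{li}.dir{di}.{n}"] = getattr(p, n)
        params["dense.w"] = self.dense_w
        params["dense.b"] = self.dense_b
        params["out.w"] = self.out_w
        params["out.b"] = self.out_b
        return params

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for li, layer in ((1, self.layer1), (2, self.layer2)):
            for di, p in enumerate(layer.directions):
                for n in ("w_x", "w_h", "b_x", "b_h"):
                    setattr(p, n, params[f"layer{li}.dir{di}.{n}"].copy())
        self.dense_w = params["dense.w"].copy()
        self.dense_b = params["dense.b"].copy()
        self.out_w = params["out.w"].copy()
        self.out_b = params["out.b"].copy()

    def n_parameters(self, scope: str = "full") -> int:
        total = sum(p.n_params() for layer in (self.layer1, self.layer2)
                    for p in layer.directions)
        if scope == "full":
            total += (self.dense_w.size + self.dense_b.size
                      + self.out_w.size + self.out_b.size)
        return total

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        x = np.asarray(x, float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        B, C, T = x.shape
        if C != self.config.input_channels or T != self.config.seq_len:
            raise ValueError(
                f"expected input ({self.config.input_channels}, "
                f"{self.config.seq_len}), got ({C}, {T})")
        seq = np.transpose(x, (0, 2, 1))              # (B, T, C)
        y1, c1 = self.layer1.forward(seq)
        y2, c2 = self.layer2.forward(y1)
        flat = y2.reshape(B, -1)
        z1 = flat @ self.dense_w.T + self.dense_b
        a1 = np.tanh(z1)
        out = a1 @ self.out_w.T + self.out_b
        pred = out.reshape(B, self.config.output_planes, self.config.seq_len)
        if keep_cache:
            self._cache = (c1, c2, y2.shape, flat, a1)
        return pred[0] if squeeze else pred

    def backward(self, dpred: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients for all parameters; requires forward(keep_cache=True)."""
        if self._cache is None:
            raise RuntimeError("call forward(..., keep_cache=True) first")
        c1, c2, y2_shape, flat, a1 = self._cache
        B = flat.shape[0]
        dout = np.asarray(dpred, float).reshape(B, -1)
        grads: dict[str, np.ndarray] = {}
        grads["out.w"] = dout.T @ a1
        grads["out.b"] = dout.sum(axis=0)
        da1 = dout @ self.out_w
        dz1 = da1 * (1.0 - a1 * a1)
        grads["dense.w"] = dz1.T @ flat
        grads["dense.b"] = dz1.sum(axis=0)
        dy2 = (dz1 @ self.dense_w).reshape(y2_shape)
        dy1, g2 = self.layer2.backward(dy2, c2)
        _, g1 = self.layer1.backward(dy1, c1)
        for li, gl in ((1, g1), (2, g2)):
            for di, g in enumerate(gl):
                for n, v in g.items():
                    grads[f"layer{li}.dir{di}.{n}"] = v
        return grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, keep_cache=False)
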