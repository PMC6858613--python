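"""LSTM next-day glucose forecaster, implemented directly in NumPy.

The recurrent cell follows the gated formulation with sigmoid activations
throughout (including the candidate/"external input" nonlinearity):

    f_t = sigma(b_f + U_f x_t + W_f h_{t-1})        forget gate
    g_t = sigma(b_g + U_g x_t + W_g h_{t-1})        external input gate
    c_t = sigma(b_c + U_c x_t + W_c h_{t-1})        candidate unit
    s_t = f_t * s_{t-1} + g_t * c_t                 cell state
    q_t = sigma(b_o + U_o x_t + W_o h_{t-1})        output gate
    h_t = tanh(s_t) * q_t                           hidden output

Note the candidate uses a sigmoid (both conventions exist in the literature;
tanh candidates are the Keras default).  Because |tanh| <= 1 and 0 < q < 1,
hidden activations always satisfy |h| <= 1.

The cell is unrolled over a lookback window of six daily features, dropout
is applied to the final hidden vector during training only, and a one-hidden-
layer ReLU feed-forward head produces the scalar scaled-glucose prediction.
Training minimizes mean squared error on scaled targets with full-batch Adam
and analytic backpropagation through time; the parameters with the best
validation RMSE over epochs are retained.  Everything is seeded and
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glucoforecast.preprocess import (
    ScalingParams,
    SplitSpec,
    WindowedDataset,
    inverse_scale_glucose,
    make_windows,
    split_series,
)

GATES = ("f", "g", "c", "o")  # forget, external input, candidate, output


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class LSTMConfig:
    """Architecture and training settings.

    dropout_rate, n_lstm_units and n_dense_units are the three tunable
    hyperparameters (search bounds (0.10, 5, 5)-(0.45, 60, 40)); the rest are
    fixed training choices.
    """

    dropout_rate: float = 0.2
    n_lstm_units: int = 20
    n_dense_units: int = 10
    lookback: int = 1
    epochs: int = 200
    learning_rate: float = 1e-3
    seed: int = 0
    n_features: int = 6
    n_lstm_layers: int = 1
    init_scale: float | None = None  # None -> 1/sqrt(fan_in)

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        for name in ("n_lstm_units", "n_dense_units", "lookback", "epochs",
                     "n_features", "n_lstm_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LSTMState:
    """Hidden and cell state of one LSTM layer."""

    h: np.ndarray
    s: np.ndarray


@dataclass
class LSTMParams:
    """All trainable tensors, keyed ``l<layer>/U_f`` ... ``head/W1`` etc."""

    tensors: dict[str, np.ndarray]
    config: LSTMConfig

    def layer(self, i: int = 0) -> dict[str, np.ndarray]:
        prefix = f"l{i}/"
        return {k[len(prefix):]: v for k, v in self.tensors.items() if k.startswith(prefix)}

    def copy(self) -> "LSTMParams":
        return LSTMParams({k: v.copy() for k, v in self.tensors.items()}, self.config)

    # -- flat-vector view (used by optimizers and finite-difference checks) --
    def flatten(self) -> np.ndarray:
        return np.concatenate([self.tensors[k].ravel() for k in sorted(self.tensors)])

    def from_flat(self, vec: np.ndarray) -> "LSTMParams":
        out, i = {}, 0
        for k in sorted(self.tensors):
            size = self.tensors[k].size
            out[k] = vec[i : i + size].reshape(self.tensors[k].shape).copy()
            i += size
        return LSTMParams(out, self.config)


def init_params(config: LSTMConfig) -> LSTMParams:
    """Seeded initialization: small uniform weights, zero biases except the
    forget-gate bias, which starts at 1 (standard trick so early training
    does not wipe the cell state)."""
    rng = np.random.default_rng(config.seed)
    H, K = config.n_lstm_units, config.n_dense_units
    tensors: dict[str, np.ndarray] = {}
    for layer in range(config.n_lstm_layers):
        D = config.n_features if layer == 0 else H
        a_u = config.init_scale or 1.0 / np.sqrt(D)
        a_w = config.init_scale or 1.0 / np.sqrt(H)
        for gate in GATES:
            tensors[f"l{layer}/U_{gate}"] = rng.uniform(-a_u, a_u, size=(H, D))
            tensors[f"l{layer}/W_{gate}"] = rng.uniform(-a_w, a_w, size=(H, H))
            tensors[f"l{layer}/b_{gate}"] = (
                np.ones(H) if gate == "f" else np.zeros(H)
            )
    a_h = config.init_scale or 1.0 / np.sqrt(H)
    a_k = config.init_scale or 1.0 / np.sqrt(K)
    tensors["head/W1"] = rng.uniform(-a_h, a_h, size=(K, H))
    tensors["head/b1"] = np.zeros(K)
    tensors["head/w2"] = rng.uniform(-a_k, a_k, size=K)
    tensors["head/b2"] = np.zeros(1)
    return LSTMParams(tensors, config)


def cell_step(x: np.ndarray, state: LSTMState, params: LSTMParams,
              layer: int = 0) -> LSTMState:
    """One step of the gated recurrence; works on single vectors or batches."""
    p = params.layer(layer)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    h = np.atleast_2d(state.h)
    s = np.atleast_2d(state.s)
    if x.shape[1] != p["U_f"].shape[1]:
        raise ValueError(f"input dim {x.shape[1]} != expected {p['U_f'].shape[1]}")
    f = _sigmoid(x @ p["U_f"].T + h @ p["W_f"].T + p["b_f"])
    g = _sigmoid(x @ p["U_g"].T + h @ p["W_g"].T + p["b_g"])
    c = _sigmoid(x @ p["U_c"].T + h @ p["W_c"].T + p["b_c"])
    q = _sigmoid(x @ p["U_o"].T + h @ p["W_o"].T + p["b_o"])
    s_new = f * s + g * c
    h_new = np.tanh(s_new) * q
    if state.h.ndim == 1:
        return LSTMState(h_new[0], s_new[0])
    return LSTMState(h_new, s_new)


def _forward_full(X: np.ndarray, params: LSTMParams, training: bool,
                  rng: np.random.Generator | None):
    """Unrolled forward pass over windows X (N, T, D) with caches."""
    cfg = params.config
    N, T, _ = X.shape
    H = cfg.n_lstm_units
    caches = []
    inp = X
    for layer in range(cfg.n_lstm_layers):
        p = params.layer(layer)
        h = np.zeros((N, H))
        s = np.zeros((N, H))
        steps = []
        h_seq = np.empty((N, T, H))
        for t in range(T):
            x = inp[:, t, :]
            f = _sigmoid(x @ p["U_f"].T + h @ p["W_f"].T + p["b_f"])
            g = _sigmoid(x @ p["U_g"].T + h @ p["W_g"].T + p["b_g"])
            c = _sigmoid(x @ p["U_c"].T + h @ p["W_c"].T + p["b_c"])
            q = _sigmoid(x @ p["U_o"].T + h @ p["W_o"].T + p["b_o"])
            s_new = f * s + g * c
            tanh_s = np.tanh(s_new)
            h_new = tanh_s * q
            steps.append((x, h, s, f, g, c, q, tanh_s))
            h, s = h_new, s_new
            h_seq[:, t, :] = h
        caches.append(steps)
        inp = h_seq
    h_final = h
    if training and cfg.dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        mask = (rng.random(h_final.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
    else:
        mask = np.ones_like(h_final)
    h_drop = h_final * mask
    W1, b1 = params.tensors["head/W1"], params.tensors["head/b1"]
    w2, b2 = params.tensors["head/w2"], params.tensors["head/b2"]
    z1 = h_drop @ W1.T + b1
    r1 = np.maximum(z1, 0.0)
    yhat = r1 @ w2 + b2[0]
    head_cache = (h_drop, mask, z1, r1)
    return yhat, caches, head_cache


def forward(window: np.ndarray, params: LSTMParams, training: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Predict scaled glucose for one window (T, D) or a batch (N, T, D)."""
    X = np.asarray(window, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[2] != params.config.n_features:
        raise ValueError(
            f"expected {params.config.n_features} features, got {X.shape[2]}"
        )
    yhat, _, _ = _forward_full(X, params, training, rng)
    return yhat[0] if single else yhat


def loss_and_gradients(
    data: WindowedDataset,
    params: LSTMParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean-squared-error loss and its analytic gradient (BPTT)."""
    cfg = params.config
    X, y = data.inputs, data.targets
    N, T, _ = X.shape
    yhat, caches, (h_drop, mask, z1, r1) = _forward_full(X, params, training, rng)
    resid = yhat - y
    loss = float(np.mean(resid**2))

    grads = {k: np.zeros_like(v) for k, v in params.tensors.items()}
    dyhat = 2.0 * resid / N
    w2 = params.tensors["head/w2"]
    grads["head/b2"][0] = dyhat.sum()
    grads["head/w2"][:] = r1.T @ dyhat
    dz1 = (dyhat[:, None] * w2) * (z1 > 0)
    grads["head/W1"][:] = dz1.T @ h_drop
    grads["head/b1"][:] = dz1.sum(axis=0)
    dh_top = (dz1 @ params.tensors["head/W1"]) * mask

    # gradient w.r.t. each layer's hidden sequence; top layer only sees a
    # gradient at the final step
    H = cfg.n_lstm_units
    dH_seq = np.zeros((N, T, H))
    dH_seq[:, T - 1, :] = dh_top
    for layer in reversed(range(cfg.n_lstm_layers)):
        p = params.layer(layer)
        steps = caches[layer]
        D_in = steps[0][0].shape[1]
        dX = np.zeros((N, T, D_in))
        dh_next = np.zeros((N, H))
        ds_next = np.zeros((N, H))
        for t in reversed(range(T)):
            x, h_prev, s_prev, f, g, c, q, tanh_s = steps[t]
            dh = dH_seq[:, t, :] + dh_next
            ds = ds_next + dh * q * (1.0 - tanh_s**2)
            da_o = (dh * tanh_s) * q * (1.0 - q)
            da_f = (ds * s_prev) * f * (1.0 - f)
            da_g = (ds * c) * g * (1.0 - g)
            da_c = (ds * g) * c * (1.0 - c)
            ds_next = ds * f
            for gate, da in zip(GATES, (da_f, da_g, da_c, da_o)):
                grads[f"l{layer}/U_{gate}"] += da.T @ x
                grads[f"l{layer}/W_{gate}"] += da.T @ h_prev
                grads[f"l{layer}/b_{gate}"] += da.sum(axis=0)
            dh_next = da_f @ p["W_f"] + da_g @ p["W_g"] + da_c @ p["W_c"] + da_o @ p["W_o"]
            dX[:, t, :] = da_f @ p["U_f"] + da_g @ p["U_g"] + da_c @ p["U_c"] + da_o @ p["U_o"]
        if layer > 0:
            dH_seq = dX
    return loss, grads


@dataclass
class TrainResult:
    """Trained parameters plus the per-epoch loss log."""

    params: LSTMParams
    history: pd.DataFrame
    best_epoch: int
    best_val_rmse: float


def train(
    data: WindowedDataset,
    val: WindowedDataset,
    config: LSTMConfig,
    init: LSTMParams | None = None,
    scaler: ScalingParams | None = None,
) -> TrainResult:
    """Full-batch Adam on MSE; keeps the epoch with the best validation RMSE.

    ``init`` allows warm-starting from pretrained parameters (transfer
    learning).  If ``scaler`` is given, logged validation RMSE is converted
    to mg/dL (an affine rescaling, so the selected epoch is unchanged).
    """
    if len(data) == 0:
        raise ValueError("empty training dataset")
    if init is not None:
        for f in ("n_lstm_units", "n_dense_units", "n_features", "n_lstm_layers"):
            if getattr(init.config, f) != getattr(config, f):
                raise ValueError(
                    f"architecture mismatch between init params and config: {f}"
                )
        params = LSTMParams(init.copy().tensors, config)
    else:
        params = init_params(config)
    rng = np.random.default_rng(config.seed)
    span = scaler.glucose_span() if scaler is not None else 1.0

    keys = sorted(params.tensors)
    m = {k: np.zeros_like(params.tensors[k]) for k in keys}
    v = {k: np.zeros_like(params.tensors[k]) for k in keys}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best = params.copy()
    best_val = np.inf
    best_epoch = -1
    rows = []
    for epoch in range(config.epochs):
        loss, grads = loss_and_gradients(data, params, training=True, rng=rng)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
        t = epoch + 1
        for k in keys:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            mh = m[k] / (1 - beta1**t)
            vh = v[k] / (1 - beta2**t)
            params.tensors[k] -= config.learning_rate * mh / (np.sqrt(vh) + eps)

        if len(val) > 0:
            val_pred = forward(val.inputs, params)
            val_rmse = float(np.sqrt(np.mean((val_pred - val.targets) ** 2))) * span
        else:  # fall back to training loss when no validation data exists
            val_rmse = float(np.sqrt(loss)) * span
        rows.append({"epoch": epoch, "train_mse": loss, "val_rmse": val_rmse})
        if val_rmse < best_val:
            best_val = val_rmse
            best = params.copy()
            best_epoch = epoch
    return TrainResult(best, pd.DataFrame(rows), best_epoch, best_val)


def predict_series(
    series,
    params: LSTMParams,
    scaler: ScalingParams,
    split: SplitSpec | None = None,
) -> pd.DataFrame:
    """Per-test-day predictions in mg/dL, aligned to target dates.

    The prediction for day t uses only days <= t-1 (the window ends the day
    before the target).  Returns columns date, actual_mgdl, predicted_mgdl.
    """
    if scaler.x_min.shape[0] != params.config.n_features:
        raise ValueError("scaler feature count does not match model input size")
    if split is None:
        split = split_series(series.n_days)
    _, _, test = make_windows(series, scaler, split, lookback=params.config.lookback)
    if len(test) == 0:
        return pd.DataFrame(columns=["date", "actual_mgdl", "predicted_mgdl"])
    pred_scaled = forward(test.inputs, params)
    return pd.DataFrame(
        {
            "date": series.dates[test.day_indices],
            "actual_mgdl": inverse_scale_glucose(test.targets, scaler),
            "predicted_mgdl": inverse_scale_glucose(pred_scaled, scaler),
        }
    )


# ---------------------------------------------------------------------------
# Serialization: portable .npz with config and scaler embedded.
# ---------------------------------------------------------------------------

def save_params(path: str | Path, params: LSTMParams,
                scaler: ScalingParams | None = None) -> None:
    payload = {f"tensor:{k}": v for k, v in params.tensors.items()}
    payload["config_json"] = np.array(json.dumps(dataclasses.asdict(params.config)))
    if scaler is not None:
        payload["scaler_x_min"] = scaler.x_min
        payload["scaler_x_max"] = scaler.x_max
        payload["scaler_range"] = np.array([scaler.range_lo, scaler.range_hi])
    np.savez(path, **payload)


def load_params(path: str | Path) -> tuple[LSTMParams, ScalingParams | None]:
    with np.load(path, allow_pickle=False) as data:
        cfg = LSTMConfig(**json.loads(str(data["config_json"])))
        tensors = {k[len("tensor:"):]: data[k] for k in data.files if k.startswith("tensor:")}
        scaler = None
        if "scaler_x_min" in data.files:
            lo, hi = data["scaler_range"]
            scaler = ScalingParams(data["scaler_x_min"], data["scaler_x_max"],
                                   float(lo), float(hi))
    return LSTMParams(tensors, cfg), scaler
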