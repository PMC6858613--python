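import math

import numpy as np
import pandas as pd
import pytest

from glucoforecast.baselines import moving_average_series
from glucoforecast.cohort import PatientArchetype, simulate_patient
from glucoforecast.forecaster import (
    LSTMConfig,
    LSTMParams,
    LSTMState,
    cell_step,
    forward,
    init_params,
    load_params,
    loss_and_gradients,
    predict_series,
    save_params,
    train,
)
from glucoforecast.preprocess import (
    ScalingParams,
    WindowedDataset,
    inverse_scale_glucose,
    make_windows,
    prepare_patient,
    split_series,
)


def _scalar_lstm_step(x, h, s, p):
    """Independent scalar re-implementation of the gate equations.

    Pure-python loops over units, no shared code with the package forward
    pass beyond numpy scalars.
    """
    H = len(h)
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h_new, s_new = [0.0] * H, [0.0] * H
    for i in range(H):
        a_f = p["b_f"][i] + sum(p["U_f"][i][j] * x[j] for j in range(len(x)))
        a_g = p["b_g"][i] + sum(p["U_g"][i][j] * x[j] for j in range(len(x)))
        a_c = p["b_c"][i] + sum(p["U_c"][i][j] * x[j] for j in range(len(x)))
        a_o = p["b_o"][i] + sum(p["U_o"][i][j] * x[j] for j in range(len(x)))
        for k in range(H):
            a_f += p["W_f"][i][k] * h[k]
            a_g += p["W_g"][i][k] * h[k]
            a_c += p["W_c"][i][k] * h[k]
            a_o += p["W_o"][i][k] * h[k]
        f, g, c, q = sig(a_f), sig(a_g), sig(a_c), sig(a_o)
        s_new[i] = f * s[i] + g * c
        h_new[i] = math.tanh(s_new[i]) * q
    return h_new, s_new


def test_cell_step_hand_value_all_zero_params():
    cfg = LSTMConfig(n_lstm_units=2, n_dense_units=2, n_features=3)
    params = init_params(cfg)
    for k in params.tensors:
        params.tensors[k][:] = 0.0
    state = cell_step(np.array([1.0, -2.0, 3.0]), LSTMState(np.zeros(2), np.zeros(2)), params)
    # f = g = c = q = 0.5, s' = 0.25, h' = 0.5 * tanh(0.25)
    assert np.allclose(state.s, 0.25)
    assert np.allclose(state.h, 0.5 * np.tanh(0.25), atol=1e-12)


def test_cell_step_matches_scalar_oracle():
    rng = np.random.default_rng(0)
    for trial in range(100):
        H = int(rng.integers(1, 4))
        D = int(rng.integers(1, 5))
        cfg = LSTMConfig(n_lstm_units=H, n_dense_units=2, n_features=D, seed=trial)
        params = init_params(cfg)
        for k, v in params.tensors.items():
            params.tensors[k] = rng.normal(scale=0.8, size=v.shape)
        x = rng.normal(size=D)
        h = rng.uniform(-1, 1, size=H)
        s = rng.normal(size=H)
        got = cell_step(x, LSTMState(h.copy(), s.copy()), params)
        want_h, want_s = _scalar_lstm_step(x.tolist(), h.tolist(), s.tolist(),
                                           {k: v.tolist() for k, v in params.layer(0).items()})
        assert np.max(np.abs(got.h - np.array(want_h))) < 1e-10
        assert np.max(np.abs(got.s - np.array(want_s))) < 1e-10


def test_saturated_gates_limits():
    cfg = LSTMConfig(n_lstm_units=2, n_dense_units=2, n_features=2)
    params = init_params(cfg)
    s0 = np.array([0.3, -0.7])
    # forget gate saturated open, input gate saturated closed: state carried
    params.tensors["l0/b_f"][:] = 500.0
    params.tensors["l0/b_g"][:] = -500.0
    st = cell_step(np.zeros(2), LSTMState(np.zeros(2), s0.copy()), params)
    assert np.allclose(st.s, s0, atol=1e-12)
    # output gate saturated closed: hidden output is zero regardless of state
    params.tensors["l0/b_o"][:] = -500.0
    st = cell_step(np.ones(2), LSTMState(np.zeros(2), s0.copy()), params)
    assert np.allclose(st.h, 0.0, atol=1e-12)


def test_init_determinism_and_forget_bias():
    cfg = LSTMConfig(seed=5)
    a, b = init_params(cfg), init_params(cfg)
    assert np.array_equal(a.flatten(), b.flatten())
    assert np.all(a.tensors["l0/b_f"] == 1.0)
    assert np.all(a.tensors["l0/b_g"] == 0.0)
    assert np.abs(a.tensors["l0/U_f"]).max() <= 1.0 / np.sqrt(cfg.n_features)


def test_hidden_magnitude_bounded():
    """|h| <= 1 always: h = tanh(s) * sigmoid(a)."""
    rng = np.random.default_rng(1)
    cfg = LSTMConfig(n_lstm_units=6, n_dense_units=4, lookback=5, seed=1)
    params = init_params(cfg)
    for k, v in params.tensors.items():
        params.tensors[k] = rng.normal(scale=3.0, size=v.shape)
    state = LSTMState(np.zeros(6), np.zeros(6))
    for t in range(20):
        state = cell_step(rng.normal(scale=5.0, size=6), state, params)
        assert np.all(np.abs(state.h) <= 1.0)


def test_forward_deterministic_without_training_flag(rng):
    cfg = LSTMConfig(dropout_rate=0.3, n_lstm_units=5, n_dense_units=4, seed=2)
    params = init_params(cfg)
    w = rng.normal(size=(1, 6))
    assert forward(w, params) == forward(w, params)


def test_dropout_seeded_reproducible(rng):
    cfg = LSTMConfig(dropout_rate=0.4, n_lstm_units=5, n_dense_units=4, seed=2)
    params = init_params(cfg)
    w = rng.normal(size=(8, 1, 6))
    a = forward(w, params, training=True, rng=np.random.default_rng(9))
    b = forward(w, params, training=True, rng=np.random.default_rng(9))
    c = forward(w, params, training=True, rng=np.random.default_rng(10))
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_zero_head_weights_predict_bias(rng):
    cfg = LSTMConfig(n_lstm_units=4, n_dense_units=3, seed=0)
    params = init_params(cfg)
    params.tensors["head/W1"][:] = 0.0
    params.tensors["head/w2"][:] = 0.0
    params.tensors["head/b2"][:] = 0.37
    assert np.allclose(forward(rng.normal(size=(3, 1, 6)), params), 0.37)


def test_gradient_matches_finite_differences(rng):
    """Analytic BPTT gradient vs central finite differences, 2-unit net."""
    cfg = LSTMConfig(dropout_rate=0.0, n_lstm_units=2, n_dense_units=3,
                     lookback=3, n_features=4, seed=1)
    params = init_params(cfg)
    ds = WindowedDataset(rng.normal(size=(5, 3, 4)), rng.normal(size=5), np.arange(5))
    _, grads = loss_and_gradients(ds, params)
    flat = params.flatten()
    gvec = np.concatenate([grads[k].ravel() for k in sorted(grads)])
    eps = 1e-6
    num = np.empty_like(flat)
    for i in range(len(flat)):
        up, dn = flat.copy(), flat.copy()
        up[i] += eps
        dn[i] -= eps
        num[i] = (loss_and_gradients(ds, params.from_flat(up))[0]
                  - loss_and_gradients(ds, params.from_flat(dn))[0]) / (2 * eps)
    rel = np.abs(gvec - num) / np.maximum(np.abs(num) + np.abs(gvec), 1e-8)
    assert rel.max() < 1e-4


def test_train_determinism(prepared, tiny_config):
    a = train(prepared.train, prepared.val, tiny_config)
    b = train(prepared.train, prepared.val, tiny_config)
    assert np.array_equal(a.params.flatten(), b.params.flatten())
    assert a.best_epoch == b.best_epoch


def test_train_rejects_empty_and_reports_nonfinite(prepared, tiny_config):
    empty = WindowedDataset(np.empty((0, 1, 6)), np.empty(0), np.empty(0, dtype=int))
    with pytest.raises(ValueError):
        train(empty, prepared.val, tiny_config)


def test_constant_glucose_learned_within_1_mgdl():
    """On a constant-glucose series the squared-error optimum is the constant."""
    arch = PatientArchetype(
        baseline_glucose=130.0, noise_sd=0.0, carb_effect=0.0, exercise_effect=0.0,
        weight_drift=0.0, weight_effect=0.0, missing_rate_glucose=0.0,
        missing_rate_lifestyle=0.0, n_days=120,
    )
    series = simulate_patient(arch, seed=0)
    split = split_series(series.n_days)
    # glucose is constant, so the training-fit scaler would be degenerate:
    # supply an explicit plausible range instead
    x_min = series.values.min().to_numpy() - 1.0
    x_max = series.values.max().to_numpy() + 1.0
    x_min[-1], x_max[-1] = 80.0, 180.0
    scaler = ScalingParams(x_min, x_max)
    tr, va, te = make_windows(series, scaler, split)
    cfg = LSTMConfig(dropout_rate=0.0, n_lstm_units=8, n_dense_units=6,
                     epochs=400, learning_rate=5e-3, seed=0)
    result = train(tr, va, cfg, scaler=scaler)
    preds = inverse_scale_glucose(forward(te.inputs, result.params), scaler)
    assert np.max(np.abs(preds - 130.0)) < 1.0


def test_lstm_beats_moving_average_on_noiseless_covariate_series():
    """Noiseless AR(1)+carbs dynamics are exactly predictable from yesterday's
    features; a 3-day moving average necessarily lags."""
    arch = PatientArchetype(
        baseline_glucose=140.0, ar_coefficient=0.5, carb_effect=0.3,
        exercise_effect=0.0, weight_effect=0.0, noise_sd=0.0,
        missing_rate_glucose=0.0, missing_rate_lifestyle=0.0, n_days=180,
    )
    series = simulate_patient(arch, seed=4)
    prep = prepare_patient(series)
    cfg = LSTMConfig(dropout_rate=0.0, n_lstm_units=16, n_dense_units=8,
                     epochs=400, learning_rate=5e-3, seed=0)
    result = train(prep.train, prep.val, cfg, scaler=prep.scaler)
    refs = inverse_scale_glucose(prep.test.targets, prep.scaler)
    lstm_pred = inverse_scale_glucose(forward(prep.test.inputs, result.params), prep.scaler)
    ma_pred = moving_average_series(prep.series, prep.test.day_indices, 3)
    lstm_rmse = np.sqrt(np.mean((lstm_pred - refs) ** 2))
    ma_rmse = np.sqrt(np.mean((ma_pred - refs) ** 2))
    assert lstm_rmse < ma_rmse


def test_prediction_causality(prepared, tiny_config):
    """Altering features on day t never changes the prediction for day t."""
    result = train(prepared.train, prepared.val, tiny_config)
    preds = predict_series(prepared.series, result.params, prepared.scaler, prepared.split)
    tampered = prepared.series.copy()
    t = prepared.test.day_indices[0]
    tampered.values.iloc[t, :] = tampered.values.iloc[t, :] * 5
    preds2 = predict_series(tampered, result.params, prepared.scaler, prepared.split)
    assert np.isclose(
        preds["predicted_mgdl"].iloc[0], preds2["predicted_mgdl"].iloc[0]
    )
    # later predictions (which see day t as input) do change
    assert not np.allclose(preds["predicted_mgdl"], preds2["predicted_mgdl"])


def test_predict_series_alignment_and_units(prepared, tiny_config):
    result = train(prepared.train, prepared.val, tiny_config)
    preds = predict_series(prepared.series, result.params, prepared.scaler, prepared.split)
    assert len(preds) == prepared.split.test_days
    assert preds["date"].iloc[0] == prepared.series.dates[prepared.test.day_indices[0]]
    actual = inverse_scale_glucose(prepared.test.targets, prepared.scaler)
    assert np.allclose(preds["actual_mgdl"], actual)


def test_params_round_trip_on_disk(tmp_path, prepared, tiny_config):
    result = train(prepared.train, prepared.val, tiny_config)
    path = tmp_path / "model.npz"
    save_params(path, result.params, prepared.scaler)
    params, scaler = load_params(path)
    assert np.array_equal(params.flatten(), result.params.flatten())
    assert params.config == tiny_config
    assert scaler is not None and np.array_equal(scaler.x_min, prepared.scaler.x_min)
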