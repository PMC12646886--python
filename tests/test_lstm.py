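import numpy as np
import pytest

from epicast.lstm import (
    COUNTS_PRESET,
    RESIDUAL_PRESET,
    LstmConfig,
    _backward,
    _forward,
    _init_params,
    forecast_recursive,
    train,
)
from epicast.preprocess import minmax_inverse, minmax_transform


def test_backprop_matches_finite_differences():
    """BPTT gradients agree with central finite differences for a small
    two-layer network (the analytic backward pass is the oracle target)."""
    cfg = LstmConfig(window=5, hidden_units=4, lstm_layers=2, dropout=0.0,
                     batch_size=3, max_epochs=1, seed=1)
    rng = np.random.default_rng(0)
    params = _init_params(cfg, rng)
    x, y = rng.random((3, 5)), rng.random(3)
    _, grads = _backward(params, x, y, cfg, None)
    eps = 1e-6
    worst = 0.0
    for li, layer in enumerate(params):
        for key, w in layer.items():
            flat = w.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):  # spot-check
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = _backward(params, x, y, cfg, None)
                flat[idx] = orig - eps
                lm, _ = _backward(params, x, y, cfg, None)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[li][key].reshape(-1)[idx]
                worst = max(worst, abs(num - ana) / max(1e-8, abs(num) + abs(ana)))
    assert worst < 1e-3


def test_training_is_bitwise_reproducible():
    series = 50 + 10 * np.sin(2 * np.pi * np.arange(60) / 12)
    cfg = LstmConfig(window=12, hidden_units=8, batch_size=4, max_epochs=5,
                     early_stop_patience=None, seed=3)
    a, b = train(series, cfg), train(series, cfg)
    np.testing.assert_array_equal(a.loss_history, b.loss_history)
    for la, lb in zip(a.params, b.params):
        for k in la:
            np.testing.assert_array_equal(la[k], lb[k])


def test_loss_decreases_on_easy_series():
    rng = np.random.default_rng(0)
    series = 100.0 + rng.normal(0, 0.5, 80)
    cfg = LstmConfig(window=6, hidden_units=8, batch_size=8, max_epochs=30,
                     early_stop_patience=None, seed=0)
    f = train(series, cfg)
    assert f.loss_history[-1] < f.loss_history[0]


def test_learns_noiseless_seasonal_cycle():
    """COUNTS preset reaches one-step MAPE < 10% on a pure 12-month sine."""
    t = np.arange(240)
    series = 2.0 + np.sin(2 * np.pi * t / 12)
    f = train(series, COUNTS_PRESET)
    fc = forecast_recursive(f, series, 12)
    truth = 2.0 + np.sin(2 * np.pi * np.arange(240, 252) / 12)
    assert 100 * np.mean(np.abs(fc - truth) / truth) < 10.0


def test_early_stopping_returns_best_epoch():
    series = 50 + 10 * np.sin(2 * np.pi * np.arange(120) / 12) \
        + np.random.default_rng(2).normal(0, 1, 120)
    cfg = LstmConfig(window=12, hidden_units=8, batch_size=8, max_epochs=40,
                     early_stop_patience=5, seed=1)
    f = train(series, cfg)
    assert f.holdout_history is not None
    # restored weights achieve the minimum observed holdout loss
    from epicast.lstm import _holdout_loss
    from epicast.preprocess import make_windows
    scaled = minmax_transform(series, f.scaler)
    ws = make_windows(scaled, 12)
    hold = np.arange(len(ws)) + 12 >= len(series) - 12
    final = _holdout_loss(f.params, ws.inputs[hold], ws.targets[hold], cfg)
    assert final == pytest.approx(np.min(f.holdout_history), abs=1e-12)


def test_recursive_forecast_definition():
    series = 10 + np.sin(np.arange(60.0))
    cfg = LstmConfig(window=12, hidden_units=6, batch_size=8, max_epochs=5,
                     early_stop_patience=None, seed=0)
    f = train(series, cfg)
    one = forecast_recursive(f, series, 1)
    # h=1 equals the plain one-step prediction through the scaler
    window = minmax_transform(series[-12:], f.scaler)
    direct = minmax_inverse(f.predict_scaled(window[None, :]), f.scaler)
    np.testing.assert_allclose(one, direct)
    with pytest.raises(ValueError):
        forecast_recursive(f, series, 0)
    with pytest.raises(ValueError, match="shorter"):
        forecast_recursive(f, series[:5], 1)


def test_too_short_series_errors():
    with pytest.raises(ValueError, match="too short"):
        train(np.arange(10.0), LstmConfig(window=12, hidden_units=4))


def test_presets_match_protocol():
    assert (COUNTS_PRESET.window, COUNTS_PRESET.hidden_units,
            COUNTS_PRESET.batch_size, COUNTS_PRESET.max_epochs) == (12, 50, 12, 200)
    assert (RESIDUAL_PRESET.window, RESIDUAL_PRESET.hidden_units,
            RESIDUAL_PRESET.batch_size, RESIDUAL_PRESET.max_epochs) == (12, 64, 8, 100)
    assert COUNTS_PRESET.learning_rate == RESIDUAL_PRESET.learning_rate == 1e-3
    assert COUNTS_PRESET.dropout == RESIDUAL_PRESET.dropout == 0.2
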