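import math

import numpy as np
import pytest

from twotk.forecaster import (
    DivergenceError,
    RNNParams,
    TrainConfig,
    VergenceForecaster,
    counterfactual_forecast,
    rnn_step,
    rolling_forecast,
    train,
    windowed_vergence,
)


def _random_params(rng, H, n_in=2):
    return RNNParams(
        W_xh=rng.normal(size=(H, n_in)),
        W_hh=rng.normal(size=(H, H)),
        b_h=rng.normal(size=H),
        W_hy=rng.normal(size=H),
        b_y=float(rng.normal()),
        eps_scale=1.0,
    )


def _brute_force_step(params, x, h_prev):
    """Independent plain-Python evaluation of the two update formulas."""
    H = len(h_prev)
    x = list(np.atleast_1d(x))
    h = []
    for i in range(H):
        a = params.b_h[i]
        for j, xj in enumerate(x):
            a += params.W_xh[i][j] * xj
        for j in range(H):
            a += params.W_hh[i][j] * h_prev[j]
        h.append(math.tanh(a))
    o = params.b_y
    for i in range(H):
        o += params.W_hy[i] * h[i]
    return 1.0 / (1.0 + math.exp(-o)), h


class TestRnnStep:
    def test_zero_parameters_output_half(self):
        p = RNNParams(W_xh=np.zeros((4, 1)), W_hh=np.zeros((4, 4)),
                      b_h=np.zeros(4), W_hy=np.zeros(4), b_y=0.0)
        v, h = rnn_step(p, 0.7, np.zeros(4))
        assert v == 0.5
        assert np.all(h == 0)

    def test_scalar_hand_example(self):
        # H=1, W_xh=1, W_hh=0, b=0: zero input keeps hidden at 0, output 0.5
        p = RNNParams(W_xh=np.array([[1.0]]), W_hh=np.zeros((1, 1)),
                      b_h=np.zeros(1), W_hy=np.ones(1), b_y=0.0)
        v, h = rnn_step(p, 0.0, np.zeros(1))
        assert v == 0.5 and h[0] == 0.0
        v2, h2 = rnn_step(p, 1.0, np.zeros(1))
        assert h2[0] == pytest.approx(math.tanh(1.0))
        assert v2 == pytest.approx(1.0 / (1.0 + math.exp(-math.tanh(1.0))))

    @pytest.mark.parametrize("H", [1, 3, 5])
    def test_matches_brute_force_evaluation(self, H):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = _random_params(rng, H)
            x = rng.normal(size=2)
            h_prev = rng.normal(size=H)
            v, h = rnn_step(p, x, h_prev)
            v_bf, h_bf = _brute_force_step(p, x, h_prev)
            assert v == pytest.approx(v_bf, abs=1e-12)
            assert np.allclose(h, h_bf, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        p = RNNParams(W_xh=np.zeros((2, 2)), W_hh=np.zeros((2, 2)),
                      b_h=np.zeros(2), W_hy=np.zeros(2), b_y=0.0)
        with pytest.raises(ValueError):
            rnn_step(p, [0.1], np.zeros(2))
        with pytest.raises(ValueError):
            rnn_step(p, [0.1, 0.2], np.zeros(3))


class TestTraining:
    def test_constant_series_is_an_attractor(self):
        est = VergenceForecaster().fit(np.full(100, 0.8))
        fitted = est.predict()
        assert np.all(np.abs(fitted[50:] - 0.8) < 0.05)

    def test_loss_improves_over_training(self):
        rng = np.random.default_rng(5)
        y = np.clip(0.7 + 0.1 * rng.normal(size=80), 0, 1)
        est = VergenceForecaster(epochs=300).fit(y)
        assert est.loss_curve_[-1] <= est.loss_curve_[0]

    def test_same_seed_gives_identical_parameters(self):
        y = np.linspace(0.2, 0.9, 60)
        p1 = train(y, TrainConfig(epochs=40, seed=9))
        p2 = train(y, TrainConfig(epochs=40, seed=9))
        assert np.array_equal(p1.W_xh, p2.W_xh)
        assert np.array_equal(p1.W_hh, p2.W_hh)
        assert p1.b_y == p2.b_y

    def test_divergent_training_reports_epoch_and_rate(self):
        y = np.linspace(0.1, 0.9, 50)
        with pytest.raises(DivergenceError, match="epoch"):
            VergenceForecaster(learning_rate=float("inf"), epochs=50).fit(y)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            VergenceForecaster(hidden_size=8).fit(np.full(5, 0.5))

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            VergenceForecaster().fit(np.array([0.2, 1.4] * 20))

    def test_params_json_round_trip(self, tmp_path):
        p = train(np.linspace(0.3, 0.8, 40), TrainConfig(epochs=20, hidden_size=4))
        path = tmp_path / "params.json"
        p.to_json(path)
        q = RNNParams.from_json(path)
        assert np.array_equal(p.W_xh, q.W_xh)
        assert np.array_equal(p.W_hh, q.W_hh)
        assert p.eps_scale == q.eps_scale


@pytest.fixture(scope="module")
def trend_model():
    y = np.linspace(0.9, 0.3, 120)
    est = VergenceForecaster(epochs=1500).fit(y[:90])
    return est, y


class TestRollingForecast:
    def test_forecasts_stay_in_unit_interval(self, trend_model):
        est, y = trend_model
        res = est.rolling_forecast(y, start_epsilon=91)
        assert np.all(res.forecast >= 0) and np.all(res.forecast <= 1)

    def test_trend_following(self, trend_model):
        est, y = trend_model
        res = est.rolling_forecast(y, start_epsilon=91, stride=3)
        slope = np.polyfit(np.arange(len(res.forecast)), res.forecast, 1)[0]
        assert slope < 0

    def test_stride_equal_to_remainder_is_pure_free_run(self, trend_model):
        est, y = trend_model
        res = est.rolling_forecast(y, start_epsilon=91, stride=30)
        assert res.refit_boundaries == [91]
        assert len(res.forecast) == 30

    def test_stride_one_is_one_step_ahead(self, trend_model):
        est, y = trend_model
        res = est.rolling_forecast(y, start_epsilon=91, stride=1)
        assert res.refit_boundaries == list(range(91, 121))
        # every step is conditioned on observations: block of length 1
        single = est.rolling_forecast(y, start_epsilon=91, stride=1).forecast
        assert np.array_equal(res.forecast, single)

    def test_invalid_stride_rejected(self, trend_model):
        est, y = trend_model
        with pytest.raises(ValueError, match="stride"):
            est.rolling_forecast(y, start_epsilon=91, stride=0)

    def test_start_outside_series_rejected(self, trend_model):
        est, y = trend_model
        with pytest.raises(ValueError, match="start_epsilon"):
            est.rolling_forecast(y, start_epsilon=500)


class TestCounterfactual:
    def test_windowed_vergence_matches_brute_force(self):
        rng = np.random.default_rng(3)
        deltas = rng.integers(0, 2, size=60)
        out = windowed_vergence(deltas, window=7)
        for i in range(60):
            lo = max(0, i - 6)
            assert out[i] == pytest.approx(deltas[lo : i + 1].mean())

    def test_intervention_on_all_positive_stream_is_noop(self):
        deltas = np.ones(80, dtype=int)
        p = train(windowed_vergence(deltas, 20), TrainConfig(epochs=60, hidden_size=4))
        fact, cf = counterfactual_forecast(p, deltas, 40, window=20)
        assert np.allclose(fact.forecast, cf.forecast)

    def test_intervention_raises_conditioning_series(self):
        rng = np.random.default_rng(11)
        deltas = rng.integers(0, 2, size=100)
        idx = int(np.flatnonzero(deltas[40:] == 0)[0]) + 40  # null-polarity act
        w = 20
        fact = windowed_vergence(deltas, w)
        cf = windowed_vergence(np.insert(deltas, idx, 1), w)[:100]
        # while the inserted positive act stays inside the trailing window,
        # every conditioning value is at least the factual one
        assert np.all(cf[idx : idx + w] >= fact[idx : idx + w] - 1e-12)
        assert cf[idx] > fact[idx]
        # once the insert leaves the window, the series is the factual one
        # shifted by a single act
        assert np.allclose(cf[idx + w :], fact[idx + w - 1 : -1])

    def test_regime_drop_orders_factual_below_counterfactual(self):
        # one replicate of the divergence scenario (full sweep in acceptance)
        from twotk.metrics import MetricSeries, running_vergence
        from twotk.synthetic_data import GeneratorConfig, generate_dialogue

        cfg = GeneratorConfig(n_concatenations=15, acts_per_concatenation=20,
                              p_delta_task=0.9, change_point=150,
                              p_delta_task_post=0.2, seed=0)
        d = generate_dialogue(cfg)
        deltas = [a.delta("task") for a in d.acts()]
        series = running_vergence(d, window=20)
        tr = MetricSeries(series.granularity, series.object_id,
                          [pt for pt in series if pt.index <= 150])
        est = VergenceForecaster(epochs=800, seed=1000).fit(tr)
        fact, cf = est.counterfactual_forecast(deltas, 150, window=20)
        assert fact.forecast[:30].mean() < cf.forecast[:30].mean()

    def test_invalid_deltas_rejected(self):
        p = train(np.full(40, 0.5), TrainConfig(epochs=20, hidden_size=4))
        with pytest.raises(ValueError, match="0/1"):
            counterfactual_forecast(p, [0, 2, 1] * 10, 10)
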