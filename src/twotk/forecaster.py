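"""Recurrent vergence forecaster (single-layer Elman network).

The model predicts the vergence trajectory of a dialogue from its own past
dynamics.  At each dialogical time step the hidden state is updated as

    h_e = sigma_h(W_xh x_e + W_hh h_{e-1} + b_h)

and the predicted vergence is read out as

    V_e = sigma_y(W_hy h_e + b_y)

with sigma_h = tanh (bounded, non-linear) and sigma_y = logistic so that
every prediction is a valid vergence value in [0, 1].

The per-step input x_e is a two-component vector: the normalized dialogical
time e and the vergence observed (or, when free-running, predicted) at the
previous step.  Feeding the previous vergence back in is what makes
teacher-forced re-conditioning and counterfactual interventions on the
conditioning series act on the forecast; time alone would make the forecast
blind to what actually happened.

Training is full-sequence backpropagation through time on a mean-squared
error loss, plain full-batch gradient descent, deterministic given a seed.

Forecasting follows a rolling protocol: free-run for ``stride`` steps
(default 3), then re-condition the hidden state on the observed values of
those steps, and repeat.  A counterfactual forecast inserts a positively
polarized act into the underlying polarity stream at the intervention
point, recomputes the running-vergence conditioning series, and re-runs the
same protocol, so factual and counterfactual trajectories are directly
comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .metrics import MetricSeries

__all__ = [
    "RNNParams",
    "TrainConfig",
    "ForecastResult",
    "DivergenceError",
    "VergenceForecaster",
    "rnn_step",
    "train",
    "rolling_forecast",
    "counterfactual_forecast",
    "DEFAULT_SEED",
]

#: Default initialization seed (any value works; fixed for reproducibility).
DEFAULT_SEED = 1459549


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; reports epoch and learning rate."""


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


_ACTIVATIONS = {
    "tanh": (np.tanh, lambda h: 1.0 - h * h),  # derivative in terms of output
    "logistic": (_logistic, lambda y: y * (1.0 - y)),
    "identity": (lambda z: z, lambda y: np.ones_like(y)),
}


@dataclass
class RNNParams:
    """Weights, biases and activations of the vergence forecaster.

    ``W_xh`` has one column per input component (normalized time, previous
    vergence); ``eps_scale`` is the constant the raw time index is divided
    by before entering the network.
    """

    W_xh: np.ndarray  # (H, n_inputs)
    W_hh: np.ndarray  # (H, H)
    b_h: np.ndarray  # (H,)
    W_hy: np.ndarray  # (H,)
    b_y: float
    hidden_activation: str = "tanh"
    output_activation: str = "logistic"
    eps_scale: float = 1.0

    @property
    def hidden_size(self) -> int:
        return self.W_hh.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_xh.shape[1]

    def validate(self) -> None:
        H = self.hidden_size
        if self.W_xh.shape[0] != H or self.W_hh.shape != (H, H) or self.b_h.shape != (H,) \
                or self.W_hy.shape != (H,):
            raise ValueError("parameter dimension mismatch")
        for arr in (self.W_xh, self.W_hh, self.b_h, self.W_hy):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite parameter entries")
        if not np.isfinite(self.b_y):
            raise ValueError("non-finite output bias")
        if self.hidden_activation not in _ACTIVATIONS or self.output_activation not in _ACTIVATIONS:
            raise ValueError("unknown activation")

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        obj = {
            "W_xh": self.W_xh.tolist(),
            "W_hh": self.W_hh.tolist(),
            "b_h": self.b_h.tolist(),
            "W_hy": self.W_hy.tolist(),
            "b_y": float(self.b_y),
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
            "eps_scale": float(self.eps_scale),
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "RNNParams":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        obj = json.loads(text)
        return cls(
            W_xh=np.asarray(obj["W_xh"], dtype=float),
            W_hh=np.asarray(obj["W_hh"], dtype=float),
            b_h=np.asarray(obj["b_h"], dtype=float),
            W_hy=np.asarray(obj["W_hy"], dtype=float),
            b_y=float(obj["b_y"]),
            hidden_activation=obj["hidden_activation"],
            output_activation=obj["output_activation"],
            eps_scale=float(obj["eps_scale"]),
        )


@dataclass
class TrainConfig:
    epochs: int = 2000
    learning_rate: float = 0.01
    seed: int = DEFAULT_SEED
    loss: str = "mse"
    stride: int = 3
    hidden_size: int = 8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class ForecastResult:
    """Observed, fitted and forecast values with refit boundaries marked."""

    observed_epsilons: np.ndarray
    observed: np.ndarray
    fitted_epsilons: np.ndarray
    fitted: np.ndarray
    forecast_epsilons: np.ndarray
    forecast: np.ndarray
    refit_boundaries: list
    train_end_epsilon: int


def rnn_step(params: RNNParams, x, h_prev: np.ndarray):
    """One recurrence step: returns (predicted vergence, new hidden state).

    ``x`` is the per-step input (scalar or vector of length ``n_inputs``),
    already normalized per ``params``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    h_prev = np.asarray(h_prev, dtype=float)
    if x.shape[0] != params.n_inputs:
        raise ValueError(f"input length {x.shape[0]} != expected {params.n_inputs}")
    if h_prev.shape != (params.hidden_size,):
        raise ValueError(f"hidden state shape {h_prev.shape} != ({params.hidden_size},)")
    f_h = _ACTIVATIONS[params.hidden_activation][0]
    f_y = _ACTIVATIONS[params.output_activation][0]
    h = f_h(params.W_xh @ x + params.W_hh @ h_prev + params.b_h)
    v = float(f_y(params.W_hy @ h + params.b_y))
    return v, h


def _series_values(series) -> tuple:
    """Accept a MetricSeries or a plain value array; return (epsilons, values)."""
    if isinstance(series, MetricSeries):
        return series.indices.astype(int), series.vergences
    values = np.asarray(series, dtype=float)
    return np.arange(1, len(values) + 1), values


class VergenceForecaster(RegressorMixin, BaseEstimator):
    """Elman-network forecaster for running-vergence trajectories.

    Parameters
    ----------
    hidden_size : int, default 8
        Number of hidden units H.
    learning_rate : float, default 0.01
        Step size of full-batch gradient descent.
    epochs : int, default 2000
        Gradient-descent iterations over the full sequence.
    seed : int, default 1459549
        Seed of the weight initialization (uniform in [-0.5, 0.5] scaled by
        1/sqrt(H)); the same seed gives bit-identical parameters.
    stride : int, default 3
        Rolling-forecast block length: free-run this many steps, then
        re-condition the hidden state on the observed values.
    clip_norm : float, default 5.0
        Global gradient-norm clip, guarding BPTT against exploding
        gradients on long sequences.

    Attributes
    ----------
    params_ : RNNParams
        Learned weights (set by :meth:`fit`).
    loss_curve_ : ndarray
        Mean-squared training error per epoch.
    """

    def __init__(
        self,
        hidden_size: int = 8,
        learning_rate: float = 0.01,
        epochs: int = 2000,
        seed: int = DEFAULT_SEED,
        stride: int = 3,
        clip_norm: float = 5.0,
    ):
        self.hidden_size = hidden_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed
        self.stride = stride
        self.clip_norm = clip_norm

    # -- training ---------------------------------------------------------

    def _inputs(self, eps: np.ndarray, prev_values: np.ndarray, eps_scale: float) -> np.ndarray:
        return np.column_stack([eps / eps_scale, prev_values])

    def fit(self, series, y=None) -> "VergenceForecaster":
        """Fit on one running-vergence series (values in [0, 1]).

        ``series`` is a :class:`~twotk.metrics.MetricSeries` or a 1-d array
        of vergence values; ``y`` is ignored (the series is its own
        target), kept for estimator-API compatibility.
        """
        eps, values = _series_values(series)
        T = len(values)
        H = int(self.hidden_size)
        if T < H + 2:
            raise ValueError(f"series length {T} too short for hidden size {H}")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("vergence values must lie in [0, 1]")

        eps_scale = float(eps[-1])
        rng = np.random.default_rng(self.seed)
        scale = 1.0 / np.sqrt(H)
        W_xh = rng.uniform(-0.5, 0.5, size=(H, 2)) * scale
        W_hh = rng.uniform(-0.5, 0.5, size=(H, H)) * scale
        b_h = np.zeros(H)
        W_hy = rng.uniform(-0.5, 0.5, size=H) * scale
        b_y = 0.0

        # teacher-forced inputs: previous observed vergence (first step
        # bootstraps on its own value) and normalized time
        prev = np.concatenate([[values[0]], values[:-1]])
        X = self._inputs(eps.astype(float), prev, eps_scale)

        lr = float(self.learning_rate)
        losses = np.empty(self.epochs)
        for epoch in range(self.epochs):
            # forward
            h = np.zeros((T + 1, H))
            out = np.empty(T)
            for t in range(T):
                h[t + 1] = np.tanh(W_xh @ X[t] + W_hh @ h[t] + b_h)
                out[t] = W_hy @ h[t + 1] + b_y
            pred = _logistic(out)
            err = pred - values
            loss = float(np.mean(err * err))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch} (learning rate {lr}); "
                    "lower the learning rate"
                )
            losses[epoch] = loss

            # backward (BPTT)
            d_out = (2.0 / T) * err * pred * (1.0 - pred)
            gW_xh = np.zeros_like(W_xh)
            gW_hh = np.zeros_like(W_hh)
            gb_h = np.zeros_like(b_h)
            gW_hy = np.zeros_like(W_hy)
            gb_y = 0.0
            dh_next = np.zeros(H)
            for t in range(T - 1, -1, -1):
                gW_hy += d_out[t] * h[t + 1]
                gb_y += d_out[t]
                dh = d_out[t] * W_hy + dh_next
                da = dh * (1.0 - h[t + 1] * h[t + 1])
                gW_xh += np.outer(da, X[t])
                gW_hh += np.outer(da, h[t])
                gb_h += da
                dh_next = W_hh.T @ da
            gnorm = np.sqrt(
                sum(float(np.sum(g * g)) for g in (gW_xh, gW_hh, gb_h, gW_hy)) + gb_y**2
            )
            if gnorm > self.clip_norm:
                f = self.clip_norm / gnorm
                gW_xh *= f
                gW_hh *= f
                gb_h *= f
                gW_hy *= f
                gb_y *= f
            W_xh -= lr * gW_xh
            W_hh -= lr * gW_hh
            b_h -= lr * gb_h
            W_hy -= lr * gW_hy
            b_y -= lr * gb_y

        self.params_ = RNNParams(
            W_xh=W_xh, W_hh=W_hh, b_h=b_h, W_hy=W_hy, b_y=float(b_y),
            eps_scale=eps_scale,
        )
        self.loss_curve_ = losses
        self.train_epsilons_ = eps
        self.train_values_ = values
        return self

    # -- prediction -------------------------------------------------------

    def predict(self, series=None) -> np.ndarray:
        """Teacher-forced one-step-ahead predictions over a series.

        With no argument, predicts over the training series (fitted
        values).
        """
        self._check_fitted()
        if series is None:
            eps, values = self.train_epsilons_, self.train_values_
        else:
            eps, values = _series_values(series)
        p = self.params_
        prev = np.concatenate([[values[0]], values[:-1]])
        h = np.zeros(p.hidden_size)
        out = np.empty(len(values))
        for t in range(len(values)):
            out[t], h = rnn_step(p, [eps[t] / p.eps_scale, prev[t]], h)
        return out

    def rolling_forecast(self, series, start_epsilon: int, stride: Optional[int] = None) -> ForecastResult:
        self._check_fitted()
        return rolling_forecast(self.params_, series, start_epsilon,
                                stride=self.stride if stride is None else stride)

    def counterfactual_forecast(self, deltas, intervention_epsilon: int,
                                window: int = 20, stride: Optional[int] = None):
        self._check_fitted()
        return counterfactual_forecast(
            self.params_, deltas, intervention_epsilon, window=window,
            stride=self.stride if stride is None else stride,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("forecaster is not fitted; call fit() first")


def train(series, config: Optional[TrainConfig] = None) -> RNNParams:
    """Fit a forecaster on a running-vergence series; return its parameters."""
    config = config or TrainConfig()
    if config.loss != "mse":
        raise ValueError(f"unsupported loss {config.loss!r}")
    est = VergenceForecaster(
        hidden_size=config.hidden_size,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        seed=config.seed,
        stride=config.stride,
    )
    est.fit(series)
    return est.params_


def rolling_forecast(
    params: RNNParams,
    series,
    start_epsilon: int,
    stride: int = 3,
) -> ForecastResult:
    """Forecast from ``start_epsilon`` to the end of the series.

    The hidden state is first conditioned (teacher-forced) on the observed
    values before ``start_epsilon``.  Then, repeatedly: free-run ``stride``
    steps feeding the model its own predictions, record them as the
    forecast, and re-condition the hidden state on the observed values of
    those steps before the next block.  ``stride`` equal to the remaining
    length gives a single pure free-run; ``stride=1`` gives one-step-ahead
    predictions.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    params.validate()
    eps, values = _series_values(series)
    pos = np.searchsorted(eps, start_epsilon)
    if pos <= 0 or pos >= len(values):
        raise ValueError(
            f"start_epsilon {start_epsilon} must be inside the series "
            f"(after {eps[0]}, at or before {eps[-1]})"
        )

    prev = np.concatenate([[values[0]], values[:-1]])
    h = np.zeros(params.hidden_size)
    fitted = np.empty(pos)
    for t in range(pos):
        fitted[t], h = rnn_step(params, [eps[t] / params.eps_scale, prev[t]], h)

    forecast = np.empty(len(values) - pos)
    boundaries = []
    t = pos
    while t < len(values):
        boundaries.append(int(eps[t]))
        block = range(t, min(t + stride, len(values)))
        # free-run: feed predictions back in
        h_free = h.copy()
        prev_v = values[t - 1]
        for j in block:
            v_hat, h_free = rnn_step(params, [eps[j] / params.eps_scale, prev_v], h_free)
            forecast[j - pos] = v_hat
            prev_v = v_hat
        # re-condition on what was actually observed in the block
        for j in block:
            _, h = rnn_step(params, [eps[j] / params.eps_scale, prev[j]], h)
        t += stride

    return ForecastResult(
        observed_epsilons=eps,
        observed=values,
        fitted_epsilons=eps[:pos],
        fitted=fitted,
        forecast_epsilons=eps[pos:],
        forecast=forecast,
        refit_boundaries=boundaries,
        train_end_epsilon=int(eps[pos - 1]),
    )


def windowed_vergence(deltas: Sequence[int], window: int = 20) -> np.ndarray:
    """Trailing-window mean of a 0/1 polarity stream (prefix-shortened)."""
    deltas = np.asarray(deltas, dtype=float)
    out = np.empty(len(deltas))
    c = np.concatenate([[0.0], np.cumsum(deltas)])
    for i in range(len(deltas)):
        lo = max(0, i + 1 - window)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out


def counterfactual_forecast(
    params: RNNParams,
    deltas: Sequence[int],
    intervention_epsilon: int,
    *,
    window: int = 20,
    stride: int = 3,
):
    """Compare factual and counterfactual rolling forecasts.

    The factual conditioning series is the trailing-window vergence of the
    polarity stream ``deltas`` (act at dialogical time e sits at index
    e - 1).  The counterfactual inserts one positively polarized act at the
    intervention point, recomputes the conditioning series, and truncates
    it to the original length so both forecasts share their time axis.

    Returns ``(factual, counterfactual)`` :class:`ForecastResult` pairs,
    both forecasting from ``intervention_epsilon`` onward.
    """
    deltas = np.asarray(deltas, dtype=int)
    if np.any((deltas != 0) & (deltas != 1)):
        raise ValueError("deltas must be 0/1")
    idx = intervention_epsilon - 1
    if not (0 < idx < len(deltas)):
        raise ValueError("intervention_epsilon must be inside the series")

    factual_series = windowed_vergence(deltas, window)
    cf_deltas = np.insert(deltas, idx, 1)
    cf_series = windowed_vergence(cf_deltas, window)[: len(deltas)]

    factual = rolling_forecast(params, factual_series, intervention_epsilon, stride=stride)
    counterfactual = rolling_forecast(params, cf_series, intervention_epsilon, stride=stride)
    return factual, counterfactual
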