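"""Lagged input designs and the multilayer-perceptron phase model.

The perceptron has one hidden layer (tanh) and a logistic output bounded to
the [0, 1] target range. Light enters with lags 0-24 h in 30-minute steps
(49 columns) and each temperature variable with lags 0-5 h (11 columns).
Training is full-batch resilient backpropagation (Rprop) minimising MSE,
restarted from many seeded random initialisations; the restart with the
lowest training error is kept.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .config import RunConfig
from .datatypes import BinnedMatrix
from .preprocess import in_intervals
from .reference import ReferenceWaveform

logger = logging.getLogger("circaphase")


class DesignError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


def n_lags(lag_hours: float, bin_minutes: int) -> int:
    """Number of lag columns for a 0..lag_hours grid in bin-width steps."""
    return int(round(lag_hours * 60.0 / bin_minutes)) + 1


def count_weights(n_inputs: int, hidden: int = 5) -> int:
    """Trainable weights of the perceptron: (I+1)*H hidden + (H+1) output."""
    if n_inputs < 1:
        raise ValueError("need at least one input")
    return (n_inputs + 1) * hidden + (hidden + 1)


@dataclass
class LaggedDesign:
    """Design matrix of lagged inputs aligned to target values."""

    X: np.ndarray  # (n_rows, n_inputs)
    y: np.ndarray  # (n_rows,) reference waveform value at the row time
    columns: list
    times: np.ndarray  # bin centres (minutes)
    participant_id: str
    in_lab_mask: np.ndarray  # boolean per row

    def __post_init__(self) -> None:
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise DesignError("lagged design must not contain missing entries")


def build_lagged_design(
    binned: BinnedMatrix,
    reference: ReferenceWaveform,
    config: RunConfig,
    participant_id: str = "",
    light_column: str = "light",
    temp_columns: Optional[Sequence[str]] = None,
    inlab_intervals: Sequence[tuple[float, float]] = (),
) -> LaggedDesign:
    """One row per 30-min bin with a complete lag history.

    Rows lacking the full 24 h of prior light history are excluded; the
    target is the reference-waveform value at the row's bin centre.
    """
    frame = binned.frame
    if light_column not in frame.columns:
        raise DesignError(f"binned matrix lacks light column {light_column!r}")
    if temp_columns is None:
        temp_columns = [c for c in frame.columns if c.startswith("temp")]
    centers = binned.bin_centers
    nl = n_lags(config.light_lag_hours, config.bin_minutes)
    nt = n_lags(config.temp_lag_hours, config.bin_minutes)
    max_lag = max(nl, nt) - 1
    n_rows = len(frame) - max_lag
    if n_rows <= 0:
        raise DesignError("no rows with a complete lag history")

    cols, blocks = [], []
    light = frame[light_column].to_numpy(dtype=float)
    for k in range(nl):
        cols.append(f"{light_column}_lag{k * config.bin_minutes}")
        blocks.append(light[max_lag - k: max_lag - k + n_rows])
    for name in temp_columns:
        tv = frame[name].to_numpy(dtype=float)
        for k in range(nt):
            cols.append(f"{name}_lag{k * config.bin_minutes}")
            blocks.append(tv[max_lag - k: max_lag - k + n_rows])
    X = np.column_stack(blocks)
    times = centers[max_lag:]
    y = reference.value_at(times)
    in_lab = in_intervals(times, inlab_intervals)
    return LaggedDesign(X, y, cols, times, participant_id, in_lab)


@dataclass
class ScalingParams:
    """Per-column mean/SD from the training participants; zero-SD columns
    are dropped (with a warning) rather than divided by zero."""

    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # boolean column mask
    columns: list

    @classmethod
    def fit(cls, designs: Sequence[LaggedDesign]) -> "ScalingParams":
        X = np.vstack([d.X for d in designs])
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d zero-variance design columns", int((~keep).sum()))
        return cls(mean, sd, keep, list(designs[0].columns))

    def apply(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.mean.size:
            raise ValueError("design column count does not match scaling parameters")
        return (X[:, self.keep] - self.mean[self.keep]) / self.sd[self.keep]


@dataclass
class NetworkWeights:
    """Weights of the two-layer perceptron (hidden bias in the last row of
    ``w1``; output bias in the last entry of ``w2``)."""

    w1: np.ndarray  # (I+1, H)
    w2: np.ndarray  # (H+1,)
    rng_seed: Optional[int] = None
    training_error: float = np.nan

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[0] - 1

    @property
    def hidden(self) -> int:
        return self.w1.shape[1]

    @property
    def n_weights(self) -> int:
        return self.w1.size + self.w2.size


@dataclass
class TrainingResult:
    best: NetworkWeights
    restart_errors: list
    selected_restart: int


def _forward(X: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    A = np.tanh(X @ w1[:-1] + w1[-1])
    return expit(A @ w2[:-1] + w2[-1])


def predict(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Forward pass: one predicted target value per design row."""
    if X.shape[1] != weights.n_inputs:
        raise ValueError(
            f"design has {X.shape[1]} columns, network expects {weights.n_inputs}"
        )
    return _forward(X, weights.w1, weights.w2)


def _loss_grad(w: np.ndarray, X: np.ndarray, y: np.ndarray, I: int, H: int):
    w1 = w[: (I + 1) * H].reshape(I + 1, H)
    w2 = w[(I + 1) * H:]
    A = np.tanh(X @ w1[:-1] + w1[-1])
    out = expit(A @ w2[:-1] + w2[-1])
    e = out - y
    n = y.size
    loss = float(np.mean(e ** 2))
    ds = (2.0 / n) * e * out * (1.0 - out)
    g2 = np.empty(H + 1)
    g2[:-1] = A.T @ ds
    g2[-1] = ds.sum()
    dA = np.outer(ds, w2[:-1]) * (1.0 - A ** 2)
    g1 = np.empty((I + 1, H))
    g1[:-1] = X.T @ dA
    g1[-1] = dA.sum(axis=0)
    return loss, np.concatenate([g1.ravel(), g2])


def _rprop(
    w0: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    I: int,
    H: int,
    max_epochs: int,
    step_tol: float,
    eta_plus: float = 1.2,
    eta_minus: float = 0.5,
    delta0: float = 0.07,
    delta_max: float = 50.0,
    delta_min: float = 1e-12,
):
    """Full-batch Rprop; returns (best weights, best loss, loss curve)."""
    w = w0.copy()
    delta = np.full(w.shape, delta0)
    prev_g = np.zeros_like(w)
    best_w, best_loss = w.copy(), np.inf
    curve = []
    for _ in range(max_epochs):
        loss, g = _loss_grad(w, X, y, I, H)
        if not np.isfinite(loss):
            raise TrainingError("non-finite loss")
        curve.append(loss)
        if loss < best_loss:
            best_loss, best_w = loss, w.copy()
        sign_change = g * prev_g
        delta = np.where(sign_change > 0, np.minimum(delta * eta_plus, delta_max), delta)
        delta = np.where(sign_change < 0, np.maximum(delta * eta_minus, delta_min), delta)
        g_eff = np.where(sign_change < 0, 0.0, g)
        step = -np.sign(g_eff) * delta
        w = w + step
        prev_g = g_eff
        if np.max(np.abs(step)) < step_tol:
            break
    final_loss, _ = _loss_grad(w, X, y, I, H)
    if np.isfinite(final_loss) and final_loss < best_loss:
        best_loss, best_w = final_loss, w
    return best_w, best_loss, curve


def train_rprop(
    X: np.ndarray,
    y: np.ndarray,
    config: RunConfig,
    rng: np.random.Generator,
) -> TrainingResult:
    """Train with ``config.restarts`` seeded random initialisations.

    Each restart draws uniform(-0.5, 0.5) weights from a child stream of
    ``rng``; the restart with the lowest training MSE wins (ties by index).
    Restarts that diverge to non-finite loss are discarded with a warning.
    """
    I, H = X.shape[1], config.hidden_neurons
    n_w = (I + 1) * H + H + 1
    children = rng.spawn(config.restarts)
    errors, results = [], []
    for k, child in enumerate(children):
        w0 = child.uniform(-0.5, 0.5, size=n_w)
        try:
            w, loss, _ = _rprop(w0, X, y, I, H, config.max_epochs, config.step_tol)
        except TrainingError:
            logger.warning("restart %d diverged; discarded", k)
            errors.append(np.inf)
            continue
        errors.append(loss)
        results.append((loss, k, w))
    if not results:
        raise TrainingError("every training restart diverged")
    loss, k, w = min(results, key=lambda r: (r[0], r[1]))
    w1 = w[: (I + 1) * H].reshape(I + 1, H)
    w2 = w[(I + 1) * H:]
    best = NetworkWeights(w1, w2, training_error=loss)
    return TrainingResult(best, errors, k)


@dataclass
class TrainedModel:
    """A trained network plus the scaling needed to apply it."""

    weights: NetworkWeights
    scaling: ScalingParams
    hidden_neurons: int = 5

    def predict_design(self, design: LaggedDesign) -> np.ndarray:
        return predict(self.weights, self.scaling.apply(design.X))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "w1": self.weights.w1.tolist(),
            "w2": self.weights.w2.tolist(),
            "training_error": self.weights.training_error,
            "scaling_mean": self.scaling.mean.tolist(),
            "scaling_sd": self.scaling.sd.tolist(),
            "scaling_keep": self.scaling.keep.astype(int).tolist(),
            "columns": self.scaling.columns,
            "hidden_neurons": self.hidden_neurons,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        raw = json.loads(Path(path).read_text())
        weights = NetworkWeights(
            np.asarray(raw["w1"], dtype=float),
            np.asarray(raw["w2"], dtype=float),
            training_error=raw["training_error"],
        )
        scaling = ScalingParams(
            np.asarray(raw["scaling_mean"], dtype=float),
            np.asarray(raw["scaling_sd"], dtype=float),
            np.asarray(raw["scaling_keep"], dtype=bool),
            list(raw["columns"]),
        )
        return cls(weights, scaling, raw["hidden_neurons"])


def _stack(designs: Sequence[LaggedDesign], scaling: ScalingParams):
    X = np.vstack([scaling.apply(d.X) for d in designs])
    y = np.concatenate([d.y for d in designs])
    return X, y


def train_final(designs: Sequence[LaggedDesign], config: RunConfig,
                rng: Optional[np.random.Generator] = None) -> TrainedModel:
    """Train a single model on the full cohort for use on unseen cohorts."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    scaling = ScalingParams.fit(designs)
    X, y = _stack(designs, scaling)
    result = train_rprop(X, y, config, rng)
    return TrainedModel(result.best, scaling, config.hidden_neurons)


@dataclass
class FoldPrediction:
    participant_id: str
    times: np.ndarray  # out-of-lab bin centres
    predicted: np.ndarray
    model: TrainedModel


def loocv(designs: Sequence[LaggedDesign], config: RunConfig,
          rng: Optional[np.random.Generator] = None) -> list[FoldPrediction]:
    """Leave-one-participant-out cross-validation.

    For each participant the model is trained on all the others (including
    their in-lab rows); predictions are emitted only for the held-out
    participant's out-of-lab rows. Participants with no out-of-lab rows are
    skipped with a warning.
    """
    if len(designs) < 3:
        raise ValueError("leave-one-out validation needs at least 3 participants")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    folds = []
    children = rng.spawn(len(designs))
    for i, held in enumerate(designs):
        out_rows = ~held.in_lab_mask
        if not out_rows.any():
            logger.warning("participant %s has no out-of-lab rows; skipped",
                           held.participant_id)
            continue
        train = [d for j, d in enumerate(designs) if j != i]
        scaling = ScalingParams.fit(train)
        X, y = _stack(train, scaling)
        result = train_rprop(X, y, config, children[i])
        model = TrainedModel(result.best, scaling, config.hidden_neurons)
        pred = model.predict_design(held)
        folds.append(FoldPrediction(held.participant_id, held.times[out_rows],
                                    pred[out_rows], model))
    return folds
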