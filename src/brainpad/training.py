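"""Predictor-agnostic training-control rules: learning-rate decay, dual
early stopping, inverse-age-frequency observation weights, and a generic
grid-search driver over pluggable predictors.

These utilities reproduce the training-control protocol around a slice-level
regressor without any commitment to a particular model family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "LrSchedule",
    "learning_rate",
    "EarlyStopState",
    "early_stopping_update",
    "age_frequency_weights",
    "grid_search",
]


@dataclass(frozen=True)
class LrSchedule:
    """Per-batch inverse-time decay: rate(b) = initial / (1 + b * decay)."""

    initial_rate: float
    decay: float = 3e-7

    def __post_init__(self) -> None:
        if self.initial_rate <= 0:
            raise ValueError("initial_rate must be > 0")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")


def learning_rate(schedule: LrSchedule, batch_index: int) -> float:
    if batch_index < 0:
        raise ValueError("batch_index must be >= 0")
    return schedule.initial_rate / (1.0 + batch_index * schedule.decay)


@dataclass(frozen=True)
class EarlyStopState:
    """Dual early-stopping rule.

    Stops when (a) the validation loss has not strictly improved for
    ``patience`` consecutive epochs, or (b) the training MAE drops below the
    validation MAE (immediate overfitting signal, patience 0).
    """

    best_loss: float = math.inf
    epochs_without_improvement: int = 0
    stop_flag: bool = False
    patience: int = 3


def early_stopping_update(state: EarlyStopState, epoch_train_mae: float,
                          epoch_val_loss: float,
                          epoch_val_mae: float) -> EarlyStopState:
    for v in (epoch_train_mae, epoch_val_loss, epoch_val_mae):
        if not math.isfinite(v):
            raise ValueError("early-stopping inputs must be finite")
    if epoch_val_loss < state.best_loss:
        best, misses = epoch_val_loss, 0
    else:
        best, misses = state.best_loss, state.epochs_without_improvement + 1
    stop = misses >= state.patience or epoch_train_mae < epoch_val_mae
    return replace(state, best_loss=best, epochs_without_improvement=misses,
                   stop_flag=stop)


def age_frequency_weights(ages, n_bins: int = 16) -> np.ndarray:
    """Observation weights inversely proportional to the frequency of the
    observation's chronological-age histogram bin, normalised to mean 1
    (so weighted and unweighted losses share a scale)."""
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("ages must be non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    counts, edges = np.histogram(ages, bins=n_bins)
    idx = np.clip(np.digitize(ages, edges[1:-1]), 0, n_bins - 1)
    w = 1.0 / counts[idx]
    return w * (ages.size / w.sum())


def grid_search(param_grid: Mapping[str, Sequence],
                evaluate: Callable[..., float]) -> tuple[dict, float, list]:
    """Exhaustive search over the Cartesian product of ``param_grid``.

    ``evaluate(**params)`` returns a loss (e.g. fold-averaged MAE); the
    configuration with the minimal loss wins, ties broken toward the earlier
    grid position (deterministic). Returns (best_params, best_loss, history).
    """
    if not param_grid:
        raise ValueError("param_grid must be non-empty")
    names = list(param_grid)
    best_params, best_loss = None, math.inf
    history = []
    for combo in itertools.product(*(param_grid[n] for n in names)):
        params = dict(zip(names, combo))
        loss = float(evaluate(**params))
        history.append((params, loss))
        if loss < best_loss:
            best_params, best_loss = params, loss
    return best_params, best_loss, history
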