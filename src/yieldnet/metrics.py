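"""Losses and evaluation metrics for multi-crop yield regression.

The training objective for the dual-head network is the *normalized
max-loss*: each crop's mean squared residual is scaled by the square of that
crop's average yield (so corn at ~147 bu/acre and soybean at ~45 bu/acre
contribute on the same scale), and the loss is the larger of the two terms —
the optimizer always works on whichever crop is currently predicted worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "YieldBatch",
    "LossConfig",
    "yieldnet_loss",
    "euclidean_loss",
    "rmse",
    "mae",
    "mae_percent",
    "pearson_r",
    "error_percent_per_record",
]


@dataclass(frozen=True)
class LossConfig:
    """Fixed normalization constants: the training-set average yields."""

    corn_mean: float
    soy_mean: float

    def __post_init__(self) -> None:
        if not (self.corn_mean > 0 and self.soy_mean > 0):
            raise ValueError("average yields must be strictly positive")


@dataclass
class YieldBatch:
    """Paired truths/predictions for the crops present in a mini-batch.

    A crop may be absent (empty arrays); at least one crop must be present.
    """

    corn_truth: np.ndarray
    corn_pred: np.ndarray
    soy_truth: np.ndarray
    soy_pred: np.ndarray

    def __post_init__(self) -> None:
        for name in ("corn_truth", "corn_pred", "soy_truth", "soy_pred"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=np.float64)))
        if self.corn_truth.shape != self.corn_pred.shape:
            raise ValueError("corn truth/pred lengths disagree")
        if self.soy_truth.shape != self.soy_pred.shape:
            raise ValueError("soy truth/pred lengths disagree")
        if self.corn_truth.size + self.soy_truth.size == 0:
            raise ValueError("batch contains neither crop")


def _normalized_term(truth: np.ndarray, pred: np.ndarray, mean: float) -> float:
    return float(np.mean(((truth - pred) / mean) ** 2))


def yieldnet_loss(batch: YieldBatch, cfg: LossConfig) -> float:
    """max( mean((Yc - Ŷc)/Ȳc)² , mean((Ys - Ŷs)/Ȳs)² ).

    With a single-crop batch the present crop's term is returned alone.
    """
    terms = []
    if batch.corn_truth.size:
        terms.append(_normalized_term(batch.corn_truth, batch.corn_pred, cfg.corn_mean))
    if batch.soy_truth.size:
        terms.append(_normalized_term(batch.soy_truth, batch.soy_pred, cfg.soy_mean))
    return max(terms)


def _paired(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.atleast_1d(np.asarray(truth, dtype=np.float64))
    pred = np.atleast_1d(np.asarray(pred, dtype=np.float64))
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size == 0:
        raise ValueError("empty input")
    return truth, pred


def euclidean_loss(truth, pred) -> float:
    """Mean squared error (the baselines' training objective)."""
    truth, pred = _paired(truth, pred)
    return float(np.mean((truth - pred) ** 2))


def rmse(truth, pred) -> float:
    """Root-mean-square error."""
    return float(np.sqrt(euclidean_loss(truth, pred)))


def mae(truth, pred) -> float:
    """Mean absolute error."""
    truth, pred = _paired(truth, pred)
    return float(np.mean(np.abs(truth - pred)))


def mae_percent(truth, pred) -> float:
    """MAE as a percentage of the average true yield."""
    truth, pred = _paired(truth, pred)
    m = truth.mean()
    if not m > 0:
        raise ValueError("mean of truth must be positive for mae_percent")
    return float(100.0 * np.mean(np.abs(truth - pred)) / m)


def pearson_r(truth, pred) -> float:
    """Product-moment correlation between truth and prediction."""
    truth, pred = _paired(truth, pred)
    if truth.size < 2:
        raise ValueError("pearson_r needs at least two pairs")
    if np.std(truth) == 0 or np.std(pred) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(np.corrcoef(truth, pred)[0, 1])


def error_percent_per_record(truth, pred) -> np.ndarray:
    """Per-record absolute error as a percentage of that record's truth."""
    truth, pred = _paired(truth, pred)
    if np.any(truth == 0):
        raise ValueError("error percentage undefined where truth is zero")
    return 100.0 * np.abs(truth - pred) / np.abs(truth)
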