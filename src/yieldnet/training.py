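"""Training loops and the in-season forecasting / ablation experiments.

The dual-head network is trained end-to-end with Adam (learning rate 0.0005,
mini-batch 32, 4000 iterations by default, Xavier initialization, no
dropout) on the normalized max-loss: each mini-batch contributes the larger
of the two crops' normalized mean squared errors, so the optimizer always
pushes on the currently-worse crop. Gradients follow the subgradient of the
attained maximum (ties broken toward corn).

Evaluation follows the held-out-year protocol: for each test year and each
in-season forecast date, histograms are truncated at that date, models are
fit on earlier years only, and RMSE / MAE / correlation are reported per
crop. Nothing derived from test years (bin edges, loss normalization means,
model fits) ever enters training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.tree import DecisionTreeRegressor

from . import nn
from .architectures import CORN, SOY, ModelHandle, build_dfnn, build_yieldnet
from .data import Entry, PairedDataset
from .histograms import FORECAST_DATES, month_day_to_doy, truncate_season
from .metrics import LossConfig, mae, mae_percent, pearson_r, rmse

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "SplitSpec",
    "ClassicalSpec",
    "PairedDataset",
    "Entry",
    "train_yieldnet",
    "predict",
    "fit_classical",
    "run_forecast_experiment",
    "run_ablation",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.0005  # the published "0.05%"
    batch_size: int = 32
    iterations: int = 4000
    optimizer: Literal["adam"] = "adam"
    init: Literal["xavier"] = "xavier"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    test_years: tuple[int, ...] = (2016, 2017, 2018)
    forecast_dates: tuple[tuple[int, int], ...] = FORECAST_DATES
    train_year_rule: Literal["all_before_test_year", "fixed_pool"] = (
        "all_before_test_year"
    )

    def train_years_for(self, test_year: int, available: Sequence[int]) -> list[int]:
        if self.train_year_rule == "all_before_test_year":
            years = [y for y in available if y < test_year]
        else:  # fixed_pool: everything that is not a test year
            years = [y for y in available if y not in self.test_years]
        if test_year in years:
            raise AssertionError("test year leaked into training pool")
        return years


@dataclass(frozen=True)
class ClassicalSpec:
    """A single-crop classical baseline with the published hyperparameters."""

    kind: Literal["ridge", "lasso", "rf", "rt"]
    alpha: float = 0.05  # ridge/lasso penalty
    n_trees: int = 150  # rf
    max_depth: int | None = None  # rf default 20, rt default 12

    def depth(self) -> int:
        if self.max_depth is not None:
            return self.max_depth
        return {"rf": 20, "rt": 12}.get(self.kind, 0)


def _flatten_features(dataset: PairedDataset) -> np.ndarray:
    # row-major (time, bin, band) flattening, documented for reproducibility
    X, _, _ = dataset.to_arrays()
    return X.reshape(len(dataset), -1).astype(np.float64)


def _output_dense(head: nn.Sequential) -> nn.Dense:
    for layer in reversed(head.layers):
        if isinstance(layer, nn.Dense):
            return layer
    raise ValueError("head has no dense output layer")


def loss_config_from(train: PairedDataset) -> LossConfig:
    means = train.crop_means()
    return LossConfig(
        corn_mean=means.get(CORN, 1.0), soy_mean=means.get(SOY, 1.0)
    )


def train_yieldnet(
    train: PairedDataset,
    cfg: TrainingConfig,
    loss_cfg: LossConfig | None = None,
    variant: str = "dual",
) -> tuple[ModelHandle, list[float]]:
    """Train the (dual- or single-head) histogram network; returns the model
    and the per-iteration loss history.

    Mini-batches are sampled with replacement over location-years; each
    batch's loss uses whichever crop labels are present. Each head's output
    bias starts at that crop's training-mean yield so early iterations model
    deviations rather than the absolute yield scale. Same seed, same data ->
    identical loss history.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    if loss_cfg is None:
        loss_cfg = loss_config_from(train)
    X, yc, ys = train.to_arrays()
    labels = {CORN: yc, SOY: ys}
    means = {CORN: loss_cfg.corn_mean, SOY: loss_cfg.soy_mean}
    model = build_yieldnet(tuple(X.shape[1:]), variant, seed=cfg.seed)
    for crop, head in model.heads.items():
        _output_dense(head).b.value[:] = means[crop]
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng([cfg.seed, 100])
    n = len(train)
    crops = model.crops
    history: list[float] = []
    for it in range(cfg.iterations):
        idx = rng.integers(0, n, size=cfg.batch_size)
        preds = model.forward_full(X[idx], train=True)
        terms: dict[str, float] = {}
        for crop in crops:
            y = labels[crop][idx]
            ok = np.isfinite(y)
            if ok.any():
                r = (y[ok] - preds[crop][ok]) / means[crop]
                terms[crop] = float(np.mean(r**2))
        if not terms:
            history.append(history[-1] if history else 0.0)
            continue
        # subgradient of the max: the attained crop only; ties -> corn
        attained = max(terms, key=lambda c: (terms[c], c == CORN))
        loss = terms[attained]
        head_grads = {c: np.zeros(cfg.batch_size, dtype=np.float32) for c in crops}
        y = labels[attained][idx]
        ok = np.isfinite(y)
        g = np.zeros(cfg.batch_size)
        g[ok] = -2.0 * (y[ok] - preds[attained][ok]) / (means[attained] ** 2 * ok.sum())
        head_grads[attained] = g.astype(np.float32)
        opt.zero_grad()
        model.backward(head_grads)
        opt.step()
        history.append(loss)
        if (it + 1) % 100 == 0:
            logger.info("iter %d/%d loss %.5f", it + 1, cfg.iterations, loss)
    return model, history


def predict(
    model: ModelHandle, dataset: PairedDataset, batch_size: int = 128
) -> dict[str, np.ndarray]:
    """Inference-mode predictions per crop over a dataset."""
    X, _, _ = dataset.to_arrays()
    chunks: dict[str, list[np.ndarray]] = {c: [] for c in model.crops}
    for i in range(0, len(dataset), batch_size):
        out = model.forward_full(X[i : i + batch_size], train=False)
        for c in model.crops:
            chunks[c].append(out[c])
    return {c: np.concatenate(v) for c, v in chunks.items()}


class ClassicalPredictor:
    """Fitted single-crop baseline over flattened histogram features."""

    def __init__(self, estimator, crop: str):
        self.estimator = estimator
        self.crop = crop

    def predict(self, dataset: PairedDataset) -> dict[str, np.ndarray]:
        return {self.crop: self.estimator.predict(_flatten_features(dataset))}

    @property
    def crops(self) -> tuple[str, ...]:
        return (self.crop,)


def fit_classical(
    train: PairedDataset, spec: ClassicalSpec, crop: str, seed: int = 0
) -> ClassicalPredictor:
    """Fit ridge / lasso / random forest / regression tree for one crop."""
    X = _flatten_features(train)
    _, yc, ys = train.to_arrays()
    y = {CORN: yc, SOY: ys}[crop]
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError(f"no {crop} labels in the training set")
    est = {
        "ridge": lambda: Ridge(alpha=spec.alpha),
        "lasso": lambda: Lasso(alpha=spec.alpha, max_iter=5000),
        "rf": lambda: RandomForestRegressor(
            n_estimators=spec.n_trees, max_depth=spec.depth(), random_state=seed
        ),
        "rt": lambda: DecisionTreeRegressor(max_depth=spec.depth(), random_state=seed),
    }[spec.kind]()
    est.fit(X[ok], y[ok])
    return ClassicalPredictor(est, crop)


# ---------------------------------------------------------------------------
# experiment protocol
# ---------------------------------------------------------------------------

NEURAL_MODELS = ("yieldnet_dual", "yieldnet_corn_only", "yieldnet_soy_only", "dfnn")


def _fit_model(
    name, train: PairedDataset, cfg: TrainingConfig
) -> list:
    """Fit one model spec; returns predictor objects with .crops/.predict."""
    if isinstance(name, ClassicalSpec):
        fitted = []
        means = train.crop_means()
        for crop in (CORN, SOY):
            if crop in means:
                fitted.append(fit_classical(train, name, crop, seed=cfg.seed))
        return fitted
    if name.startswith("yieldnet"):
        variant = name.removeprefix("yieldnet_") if "_" in name else "dual"
        loss_cfg = loss_config_from(train)
        crop_of = {"corn_only": CORN, "soy_only": SOY}
        if variant in crop_of:
            sub = PairedDataset(
                Entry(
                    e.location_id, e.year, e.histogram,
                    e.corn_yield if variant == "corn_only" else None,
                    e.soy_yield if variant == "soy_only" else None,
                )
                for e in train
                if (e.corn_yield if variant == "corn_only" else e.soy_yield)
                is not None
            )
        else:
            sub = train
        model, _ = train_yieldnet(sub, cfg, loss_cfg, variant=variant)
        return [_NeuralPredictor(model)]
    if name == "dfnn":
        fitted = []
        means = train.crop_means()
        for crop in (CORN, SOY):
            if crop not in means:
                continue
            fitted.append(_fit_dfnn(train, cfg, crop))
        return fitted
    raise ValueError(f"unknown model spec {name!r}")


class _NeuralPredictor:
    def __init__(self, model: ModelHandle):
        self.model = model
        self.crops = model.crops

    def predict(self, dataset: PairedDataset) -> dict[str, np.ndarray]:
        return predict(self.model, dataset)


def _fit_dfnn(train: PairedDataset, cfg: TrainingConfig, crop: str):
    """Single-crop deep feed-forward baseline on flattened histograms,
    trained with Adam on the plain Euclidean (mean-squared-error) loss."""
    X, yc, ys = train.to_arrays()
    y = {CORN: yc, SOY: ys}[crop]
    ok = np.isfinite(y)
    Xf = X.reshape(len(train), -1)[ok]
    yk = y[ok]
    model = build_dfnn(Xf.shape[1], seed=cfg.seed, crop=crop)
    _output_dense(model.backbone).b.value[:] = yk.mean()
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng([cfg.seed, 101])
    for _ in range(cfg.iterations):
        idx = rng.integers(0, len(yk), size=cfg.batch_size)
        pred = model.forward_full(Xf[idx], train=True)[crop]
        g = (-2.0 * (yk[idx] - pred) / cfg.batch_size).astype(np.float32)
        opt.zero_grad()
        model.backward({crop: g})
        opt.step()
    return _NeuralPredictor(model)


def _model_label(name) -> str:
    return name.kind if isinstance(name, ClassicalSpec) else str(name)


def run_forecast_experiment(
    data: PairedDataset,
    split: SplitSpec,
    models: Sequence,
    cfg: TrainingConfig,
    composite_calendar=None,
) -> pd.DataFrame:
    """Progressive in-season forecasting with year-held-out splits.

    For every (test year, forecast date): truncate all histograms at the
    date, train every model on the training years, evaluate per crop on the
    held-out year. One model is trained per forecast date so each model sees
    a fixed input shape. Returns a tidy report with columns
    model/test_year/forecast_date/crop/rmse/mae/mae_percent/pearson_r/n.
    """
    rows = []
    available = data.years()
    for test_year in split.test_years:
        train_years = split.train_years_for(test_year, available)
        if not train_years:
            logger.warning("no training years before %d; skipped", test_year)
            continue
        test_full = data.filter_years([test_year])
        if len(test_full) == 0:
            logger.warning("test year %d has no entries; skipped", test_year)
            continue
        train_full = data.filter_years(train_years)
        assert not set(train_full.years()) & set(split.test_years)
        for month, day in split.forecast_dates:
            doy = month_day_to_doy(month, day)
            trunc = lambda h: truncate_season(h, doy, composite_calendar)
            train_t = train_full.map_histograms(trunc)
            test_t = test_full.map_histograms(trunc)
            _, yc_t, ys_t = test_t.to_arrays()
            truths = {CORN: yc_t, SOY: ys_t}
            for name in models:
                for predictor in _fit_model(name, train_t, cfg):
                    preds = predictor.predict(test_t)
                    for crop in predictor.crops:
                        y = truths[crop]
                        ok = np.isfinite(y)
                        if not ok.any():
                            continue
                        p = preds[crop][ok]
                        rows.append(
                            {
                                "model": _model_label(name),
                                "test_year": test_year,
                                "forecast_date": f"{month:02d}-{day:02d}",
                                "crop": crop,
                                "rmse": rmse(y[ok], p),
                                "mae": mae(y[ok], p),
                                "mae_percent": mae_percent(y[ok], p),
                                "pearson_r": pearson_r(y[ok], p)
                                if ok.sum() >= 2 and np.std(y[ok]) > 0
                                else np.nan,
                                "n": int(ok.sum()),
                            }
                        )
    return pd.DataFrame(rows)


def run_ablation(
    data: PairedDataset,
    split: SplitSpec,
    cfg: TrainingConfig,
    composite_calendar=None,
) -> pd.DataFrame:
    """Dual-head network vs the two single-head variants, same protocol."""
    return run_forecast_experiment(
        data,
        split,
        ["yieldnet_dual", "yieldnet_corn_only", "yieldnet_soy_only"],
        cfg,
        composite_calendar,
    )
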