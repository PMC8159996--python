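"""Reference synthetic studies: signal recovery, ablation, in-season forecasting.

These are the package's standing experiments on generated data with known
ground truth. Their configurations are fixed study conditions, shared by the
test suite and the reproduction script, and are sized for a single CPU:

* **Signal recovery** — an easy, low-noise configuration with 2,000
  location-years. The trained dual-head network's held-out-year RMSE is
  compared per crop with the linear oracle's floor (least squares on
  per-composite, per-band histogram means). The floor contains everything
  the imagery cannot see: the crop-specific latent share and the label
  noise.
* **Ablation** — dual-head versus the two single-head variants, trained
  identically on shared-latent data, scored on a held-out year across
  seeds. The regime mirrors the full-scale protocol's ~10 training epochs;
  label noise is set so the two crops' normalized error floors match and
  the max-loss keeps optimizing both heads.
* **Progressive forecast** — the same dual model trained on July-truncated
  histograms versus full-season ones; with signal accumulating late in the
  season (grain filling), the July forecast should not beat October.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CORN, SOY, PairedDataset
from .histograms import month_day_to_doy, truncate_season
from .metrics import rmse
from .synth import (
    DEFAULT_PIXEL_NOISE_SD,
    GeneratorConfig,
    generate_histogram_dataset,
    oracle_predictor,
)
from .training import TrainingConfig, predict, train_yieldnet

JULY_DOY = month_day_to_doy(7, 23)  # 204
OCTOBER_DOY = month_day_to_doy(10, 23)  # 296


def cubic_ramp(n_composites: int = 30) -> np.ndarray:
    """Late-season signal ramp g(t) = (t/T)^3.

    Grain filling concentrates yield formation late in the season, so the
    imagery acquired by late July carries only a fraction of the final
    signal — the condition under which early forecasts are genuinely
    harder.
    """
    return (np.arange(1, n_composites + 1) / n_composites) ** 3


def recovery_config(seed: int = 11) -> GeneratorConfig:
    """Easy low-noise study: strong signal, 125 locations x 16 years."""
    return GeneratorConfig(
        n_locations=125,
        n_years=16,
        grid=(16, 16),
        pixel_noise_sd=DEFAULT_PIXEL_NOISE_SD * 0.3,
        corn_noise_sd=5.0,
        soy_noise_sd=1.5,
        shared_latent_weight=0.9,
        seed=seed,
    )


def ablation_config(seed: int = 0) -> GeneratorConfig:
    """Shared-latent study: 50 locations x 13 years, late-season ramp.

    Label noise 12.0 / 4.2 bu/acre makes the two crops' normalized error
    floors equal, so at the max-loss equilibrium neither head is starved.
    """
    return GeneratorConfig(
        n_locations=50,
        n_years=13,
        grid=(16, 16),
        n_bins=16,
        pixel_noise_sd=DEFAULT_PIXEL_NOISE_SD * 0.5,
        corn_noise_sd=12.0,
        soy_noise_sd=4.2,
        shared_latent_weight=0.9,
        season_ramp=cubic_ramp(),
        seed=seed,
    )


def _holdout(cfg: GeneratorConfig) -> tuple[PairedDataset, PairedDataset, object]:
    """Last-year-held-out split with leakage-safe bin edges."""
    years = cfg.years
    data, scheme, _ = generate_histogram_dataset(cfg, train_years=years[:-1])
    return data.filter_years(years[:-1]), data.filter_years([years[-1]]), scheme


@dataclass
class RecoveryResult:
    oracle_rmse: dict[str, float]
    network_rmse: dict[str, float]

    @property
    def ratios(self) -> dict[str, float]:
        return {c: self.network_rmse[c] / self.oracle_rmse[c] for c in self.network_rmse}


def run_recovery_study(seed: int = 11, iterations: int = 600) -> RecoveryResult:
    """Train the dual network on the easy study and compare with the oracle."""
    train, test, scheme = _holdout(recovery_config(seed))
    _, yc, ys = test.to_arrays()
    oracle = oracle_predictor(train, scheme)
    po = oracle.predict(test)
    cfg = TrainingConfig(iterations=iterations, batch_size=32, seed=3)
    model, _ = train_yieldnet(train, cfg)
    pn = predict(model, test)
    return RecoveryResult(
        oracle_rmse={CORN: rmse(yc, po[CORN]), SOY: rmse(ys, po[SOY])},
        network_rmse={CORN: rmse(yc, pn[CORN]), SOY: rmse(ys, pn[SOY])},
    )


@dataclass
class AblationResult:
    """Per-seed test RMSEs for each variant and the July-truncated dual run."""

    seeds: list[int]
    dual: dict[str, list[float]]  # full-season (October cutoff)
    corn_only: list[float]
    soy_only: list[float]
    dual_july: dict[str, list[float]]

    def mean(self, values: list[float]) -> float:
        return float(np.mean(values))

    @property
    def dual_means(self) -> dict[str, float]:
        return {c: self.mean(v) for c, v in self.dual.items()}

    @property
    def single_means(self) -> dict[str, float]:
        return {CORN: self.mean(self.corn_only), SOY: self.mean(self.soy_only)}

    def monotone_fraction(self) -> float:
        """Fraction of (seed, crop) cases with October RMSE <= July RMSE."""
        wins = total = 0
        for crop in (CORN, SOY):
            for late, early in zip(self.dual[crop], self.dual_july[crop]):
                wins += late <= early
                total += 1
        return wins / total


def run_ablation_study(
    seeds=range(10), iterations: int = 600, include_july: bool = True
) -> AblationResult:
    """Dual vs single-head variants (and July vs October) across seeds.

    Every variant trains with the identical protocol (600 iterations of
    Adam at 1e-3, batch 16 — about 10 epochs over the 600 training
    location-years) and is scored on the same held-out year.
    """
    result = AblationResult(
        seeds=list(seeds),
        dual={CORN: [], SOY: []},
        corn_only=[],
        soy_only=[],
        dual_july={CORN: [], SOY: []},
    )
    for seed in result.seeds:
        train, test, _ = _holdout(ablation_config(seed))
        _, yc, ys = test.to_arrays()
        tcfg = TrainingConfig(
            iterations=iterations, batch_size=16, learning_rate=1e-3, seed=seed
        )
        runs = [("dual", "dual", OCTOBER_DOY), ("corn", "corn_only", OCTOBER_DOY),
                ("soy", "soy_only", OCTOBER_DOY)]
        if include_july:
            runs.append(("july", "dual", JULY_DOY))
        for label, variant, doy in runs:
            tr = train.map_histograms(lambda h: truncate_season(h, doy))
            te = test.map_histograms(lambda h: truncate_season(h, doy))
            model, _ = train_yieldnet(tr, tcfg, variant=variant)
            p = predict(model, te)
            if label == "dual":
                result.dual[CORN].append(rmse(yc, p[CORN]))
                result.dual[SOY].append(rmse(ys, p[SOY]))
            elif label == "corn":
                result.corn_only.append(rmse(yc, p[CORN]))
            elif label == "soy":
                result.soy_only.append(rmse(ys, p[SOY]))
            else:
                result.dual_july[CORN].append(rmse(yc, p[CORN]))
                result.dual_july[SOY].append(rmse(ys, p[SOY]))
    return result
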