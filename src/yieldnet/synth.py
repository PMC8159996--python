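"""Synthetic county-scale remote-sensing and yield generator.

Emulates the structure of the real inputs — per-county 8-day multispectral
composites (7 surface-reflectance bands plus day/night land-surface
temperature), per-county cropland masks, and county-level corn/soybean yield
tables — with a known generative model so the whole pipeline is testable
without any downloads.

Generative model, per location-year (l, k):

* a shared growing-condition latent ``z ~ N(0, 1)``;
* crop yields ``Y^c = mean_c + sd_c * (rho * z + sqrt(1 - rho^2) * u^c) + noise``
  with crop-specific latents ``u^c ~ N(0, 1)``, so ``rho`` controls how much
  yield-relevant information the crops share (corn/soybean county yields are
  strongly correlated in practice);
* cropland pixel values of band j at composite t drawn around
  ``mu_j + alpha_j * g(t) * z`` — the season ramp ``g`` is non-decreasing, so
  the imagery reveals progressively more about ``z`` as the season advances,
  which is what makes early-season forecasts genuinely harder.

Yield means and standard deviations default to the US Corn Belt 2004-2018
county statistics (corn 146.68 +/- 36.03 bu/acre, soybean 45.02 +/- 10.08).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .data import CORN, SOY, Entry, PairedDataset
from .histograms import (
    BinningScheme,
    CompositeFrame,
    CroplandMask,
    HistogramTensor,
    build_histogram_tensor,
    compute_bin_edges,
    frame_histogram,
)

# Plausible mid-season cropland values for the nine bands: MODIS-style
# reflectances (red, NIR, blue, green, 1.24um, SWIR1, SWIR2) and day/night
# land-surface temperatures in kelvin.
DEFAULT_BAND_MEANS = np.array(
    [0.08, 0.35, 0.05, 0.10, 0.30, 0.20, 0.12, 298.0, 285.0]
)
# Sensitivity of each band to the growing-condition latent: healthy
# vegetation raises NIR and lowers red/SWIR and daytime LST.
DEFAULT_BAND_EFFECTS = np.array(
    [-0.015, 0.06, -0.005, 0.01, 0.03, -0.03, -0.02, -3.0, -1.5]
)
DEFAULT_PIXEL_NOISE_SD = np.array(
    [0.02, 0.04, 0.015, 0.02, 0.03, 0.025, 0.02, 2.0, 1.5]
)


def linear_ramp(n_composites: int) -> np.ndarray:
    """Default season ramp g(t) = t/T: signal accrues linearly over the season."""
    return np.arange(1, n_composites + 1) / n_composites


@dataclass(frozen=True)
class GeneratorConfig:
    n_locations: int = 50
    n_years: int = 15
    start_year: int = 2004
    grid: tuple[int, int] = (64, 64)
    n_composites: int = 30
    n_bands: int = 9
    n_bins: int = 32
    band_means: np.ndarray = field(default_factory=lambda: DEFAULT_BAND_MEANS.copy())
    band_effects: np.ndarray = field(
        default_factory=lambda: DEFAULT_BAND_EFFECTS.copy()
    )
    pixel_noise_sd: np.ndarray = field(
        default_factory=lambda: DEFAULT_PIXEL_NOISE_SD.copy()
    )
    season_ramp: np.ndarray | None = None  # defaults to linear_ramp(T)
    corn_mean: float = 146.68
    corn_sd: float = 36.03
    soy_mean: float = 45.02
    soy_sd: float = 10.08
    shared_latent_weight: float = 0.8  # rho
    corn_noise_sd: float = 7.0
    soy_noise_sd: float = 2.0
    cropland_fraction: float = 0.5
    missing_rate: float = 0.0  # chance a composite is entirely cloud-void
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("band_means", "band_effects", "pixel_noise_sd"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (self.n_bands,):
                raise ValueError(f"{name} must have length n_bands={self.n_bands}")
            object.__setattr__(self, name, arr)
        ramp = self.season_ramp
        if ramp is None:
            ramp = linear_ramp(self.n_composites)
        ramp = np.asarray(ramp, dtype=np.float64)
        if ramp.shape != (self.n_composites,):
            raise ValueError("season_ramp must have length n_composites")
        if (np.diff(ramp) < 0).any():
            raise ValueError("season_ramp must be non-decreasing")
        object.__setattr__(self, "season_ramp", ramp)
        if not 0.0 <= self.shared_latent_weight <= 1.0:
            raise ValueError("shared_latent_weight must lie in [0, 1]")
        if not (self.corn_sd > 0 and self.soy_sd > 0):
            raise ValueError("yield standard deviations must be positive")
        if self.corn_noise_sd < 0 or self.soy_noise_sd < 0:
            raise ValueError("yield noise sds must be non-negative")
        if self.corn_noise_sd >= self.corn_sd or self.soy_noise_sd >= self.soy_sd:
            raise ValueError(
                "yield noise sd must be smaller than the total yield sd "
                "(the structural component carries the remaining variance)"
            )
        if not 0 < self.cropland_fraction <= 1:
            raise ValueError("cropland_fraction must lie in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.n_years))

    @property
    def location_ids(self) -> tuple[str, ...]:
        return tuple(f"loc{i:04d}" for i in range(self.n_locations))


@dataclass
class SyntheticTruth:
    """Ground-truth latents and noiseless yields, kept for recovery tests."""

    config: GeneratorConfig
    z: np.ndarray  # (L, K) shared latent
    u_corn: np.ndarray  # (L, K) crop-specific latents
    u_soy: np.ndarray
    corn_yield: np.ndarray  # (L, K) realized yields incl. noise
    soy_yield: np.ndarray

    def noiseless_yields(self) -> tuple[np.ndarray, np.ndarray]:
        """Structural (pre-noise) yields.

        The structural sd is ``sqrt(sd^2 - noise_sd^2)`` so that the
        *realized* yields have exactly the configured total sd.
        """
        cfg = self.config
        rho = cfg.shared_latent_weight
        w = np.sqrt(1.0 - rho**2)
        s_c = np.sqrt(cfg.corn_sd**2 - cfg.corn_noise_sd**2)
        s_s = np.sqrt(cfg.soy_sd**2 - cfg.soy_noise_sd**2)
        corn = cfg.corn_mean + s_c * (rho * self.z + w * self.u_corn)
        soy = cfg.soy_mean + s_s * (rho * self.z + w * self.u_soy)
        return corn, soy


def _latent_rng(cfg: GeneratorConfig) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 0])


def _frame_rng(cfg: GeneratorConfig, li: int, ki: int) -> np.random.Generator:
    # per-location-year stream: frames can be regenerated independently of
    # the order in which location-years are visited
    return np.random.default_rng([cfg.seed, 1, li, ki])


def generate_truth(cfg: GeneratorConfig) -> SyntheticTruth:
    """Draw the latents and yields for every location-year (vectorized)."""
    rng = _latent_rng(cfg)
    L, K = cfg.n_locations, cfg.n_years
    z = rng.standard_normal((L, K))
    u_corn = rng.standard_normal((L, K))
    u_soy = rng.standard_normal((L, K))
    eps_c = rng.standard_normal((L, K)) * cfg.corn_noise_sd
    eps_s = rng.standard_normal((L, K)) * cfg.soy_noise_sd
    truth = SyntheticTruth(cfg, z, u_corn, u_soy, np.empty((L, K)), np.empty((L, K)))
    corn0, soy0 = truth.noiseless_yields()
    truth.corn_yield = np.maximum(corn0 + eps_c, 1.0)  # yields are positive
    truth.soy_yield = np.maximum(soy0 + eps_s, 1.0)
    return truth


def yield_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Long-format county yield table: location_id, year, crop, yield_bu_per_acre."""
    cfg = truth.config
    rows = []
    for li, loc in enumerate(cfg.location_ids):
        for ki, year in enumerate(cfg.years):
            rows.append((loc, year, CORN, truth.corn_yield[li, ki]))
            rows.append((loc, year, SOY, truth.soy_yield[li, ki]))
    return pd.DataFrame(
        rows, columns=["location_id", "year", "crop", "yield_bu_per_acre"]
    )


def cropland_mask(cfg: GeneratorConfig, li: int, ki: int) -> CroplandMask:
    """Contiguous rectangular cropland block covering ~cropland_fraction."""
    H, W = cfg.grid
    rng = np.random.default_rng([cfg.seed, 2, li, ki])
    h = max(1, int(round(H * np.sqrt(cfg.cropland_fraction))))
    w = max(1, int(round(W * np.sqrt(cfg.cropland_fraction))))
    r0 = int(rng.integers(0, H - h + 1))
    c0 = int(rng.integers(0, W - w + 1))
    mask = np.zeros((H, W), dtype=bool)
    mask[r0 : r0 + h, c0 : c0 + w] = True
    return CroplandMask(cfg.location_ids[li], cfg.years[ki], mask)


def location_year_frames(
    cfg: GeneratorConfig, truth: SyntheticTruth, li: int, ki: int
) -> list[CompositeFrame]:
    """The season's composites for one location-year (missing ones skipped)."""
    H, W = cfg.grid
    rng = _frame_rng(cfg, li, ki)
    z = truth.z[li, ki]
    frames = []
    for t in range(1, cfg.n_composites + 1):
        missing = rng.random() < cfg.missing_rate
        noise = rng.standard_normal((H, W, cfg.n_bands))
        if missing:
            continue
        level = cfg.band_means + cfg.band_effects * cfg.season_ramp[t - 1] * z
        bands = level + noise * cfg.pixel_noise_sd
        frames.append(
            CompositeFrame(
                location_id=cfg.location_ids[li],
                year=cfg.years[ki],
                time_index=t,
                bands=bands,
            )
        )
    return frames


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[dict, dict, pd.DataFrame, SyntheticTruth]:
    """Materialize frames, masks, yield table and truth for every location-year.

    Memory scales as ``L*K*T*H*W*d``; for large simulations prefer the
    streaming :func:`generate_histogram_dataset`.
    """
    truth = generate_truth(cfg)
    frames, masks = {}, {}
    for li, loc in enumerate(cfg.location_ids):
        for ki, year in enumerate(cfg.years):
            frames[(loc, year)] = location_year_frames(cfg, truth, li, ki)
            masks[(loc, year)] = cropland_mask(cfg, li, ki)
    return frames, masks, yield_table(truth), truth


def _training_edges(
    cfg: GeneratorConfig, truth: SyntheticTruth, train_years: Sequence[int]
) -> BinningScheme:
    train_set = set(train_years)
    lo = np.full(cfg.n_bands, np.inf)
    hi = np.full(cfg.n_bands, -np.inf)
    for li in range(cfg.n_locations):
        for ki, year in enumerate(cfg.years):
            if year not in train_set:
                continue
            mask = cropland_mask(cfg, li, ki).mask
            for frame in location_year_frames(cfg, truth, li, ki):
                vals = frame.bands[frame.valid_mask & mask]
                if vals.size:
                    lo = np.minimum(lo, vals.min(axis=0))
                    hi = np.maximum(hi, vals.max(axis=0))
    if not np.isfinite(lo).all():
        raise ValueError("no valid training pixels for bin-edge computation")
    edges = np.linspace(lo, hi, cfg.n_bins + 1, axis=1)
    return BinningScheme(edges=edges)


def generate_histogram_dataset(
    cfg: GeneratorConfig,
    train_years: Sequence[int] | None = None,
    scheme: BinningScheme | None = None,
) -> tuple[PairedDataset, BinningScheme, SyntheticTruth]:
    """Run the full pipeline in a streaming fashion: frames are generated,
    histogrammed and discarded one location-year at a time.

    Bin edges are placed from training-year pixels only (default: every
    year), mirroring the leakage rule of the real pipeline.
    """
    truth = generate_truth(cfg)
    if scheme is None:
        scheme = _training_edges(cfg, truth, train_years or cfg.years)
    dataset = PairedDataset()
    for li, loc in enumerate(cfg.location_ids):
        for ki, year in enumerate(cfg.years):
            mask = cropland_mask(cfg, li, ki)
            frames = location_year_frames(cfg, truth, li, ki)
            if frames:
                tensor = build_histogram_tensor(
                    frames, mask, scheme, n_composites=cfg.n_composites
                )
            else:
                tensor = HistogramTensor(
                    np.zeros((cfg.n_composites, cfg.n_bins, cfg.n_bands)),
                    loc, year, cfg.n_composites,
                )
            dataset.append(
                Entry(
                    location_id=loc,
                    year=year,
                    histogram=tensor,
                    corn_yield=float(truth.corn_yield[li, ki]),
                    soy_yield=float(truth.soy_yield[li, ki]),
                )
            )
    return dataset, scheme, truth


def thin_labels(
    dataset: PairedDataset, both_fraction: float, seed: int
) -> PairedDataset:
    """Keep both crop labels for a fraction of entries; give the rest one.

    Emulates the partial overlap of the real corn and soybean county sets:
    only some location-years report both crops. Entries losing a label split
    evenly between corn-only and soybean-only. This is the regime where a
    shared backbone has something to gain — each crop's head benefits from
    the other crop's labeled counties through the common feature extractor.
    """
    if not 0.0 <= both_fraction <= 1.0:
        raise ValueError("both_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 4])
    out = PairedDataset()
    for e in dataset:
        u = rng.random()
        if u < both_fraction or e.corn_yield is None or e.soy_yield is None:
            out.append(e)
        elif rng.random() < 0.5:
            out.append(Entry(e.location_id, e.year, e.histogram, e.corn_yield, None))
        else:
            out.append(Entry(e.location_id, e.year, e.histogram, None, e.soy_yield))
    return out


# ---------------------------------------------------------------------------
# linear oracle: the transparent reference any learned model is compared to
# ---------------------------------------------------------------------------


def histogram_mean_features(values: np.ndarray, scheme: BinningScheme) -> np.ndarray:
    """Per-(composite, band) histogram mean pixel value -> ``T*d`` features.

    A zero slice (missing composite or truncated) maps to feature 0.
    """
    centers = (scheme.edges[:, :-1] + scheme.edges[:, 1:]) / 2.0  # (d, b)
    mass = values.sum(axis=1)  # (T, d)
    mean = np.einsum("tbd,db->td", values, centers)
    with np.errstate(invalid="ignore"):
        mean = np.where(mass > 0, mean / np.where(mass > 0, mass, 1.0), 0.0)
    return mean.reshape(-1)


class OraclePredictor:
    """Least-squares fit of yields on per-(composite, band) histogram means.

    A deliberately transparent linear reference: under the generative model
    the histogram mean of band j at composite t is (up to bin quantization
    and pixel-sampling noise) affine in the shared latent, so this fit
    establishes the error floor attainable from the histograms. Falls back
    to a ridge-stabilized solve when the design is singular.
    """

    def __init__(self, scheme: BinningScheme):
        self.scheme = scheme
        self.coef_: dict[str, np.ndarray] = {}

    def _design(self, dataset: PairedDataset) -> np.ndarray:
        X = np.stack(
            [histogram_mean_features(e.histogram.values, self.scheme) for e in dataset]
        )
        return np.hstack([np.ones((len(dataset), 1)), X])

    def fit(self, dataset: PairedDataset) -> "OraclePredictor":
        A = self._design(dataset)
        _, yc, ys = dataset.to_arrays()
        for crop, y in ((CORN, yc), (SOY, ys)):
            ok = np.isfinite(y)
            if not ok.any():
                continue
            Ak, yk = A[ok], y[ok]
            coef, _, rank, _ = np.linalg.lstsq(Ak, yk, rcond=None)
            if rank < A.shape[1]:
                lam = 1e-8 * np.trace(Ak.T @ Ak) / A.shape[1]
                coef = np.linalg.solve(
                    Ak.T @ Ak + lam * np.eye(A.shape[1]), Ak.T @ yk
                )
            self.coef_[crop] = coef
        return self

    def predict(self, dataset: PairedDataset) -> dict[str, np.ndarray]:
        A = self._design(dataset)
        return {crop: A @ coef for crop, coef in self.coef_.items()}


def oracle_predictor(
    train: PairedDataset, scheme: BinningScheme
) -> OraclePredictor:
    """Fit the linear oracle on a training dataset."""
    return OraclePredictor(scheme).fit(train)
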