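"""Pixel-histogram reduction of multispectral composite time series.

County-scale rasters are collapsed, per 8-day composite and per band, into
pixel-value histograms. Under the permutation-invariance assumption (end-of-
season yield depends on the composition of pixel values over cropland, not on
where the pixels sit), the full season becomes a compact ``T x b x d`` tensor:
``T`` composites, ``b`` bins, ``d`` bands. In-season forecasts are produced by
zeroing the composites acquired after the forecast date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Band order used throughout: 7 surface-reflectance bands, then day and
#: night land-surface temperature.
DEFAULT_N_BANDS = 9
DEFAULT_N_COMPOSITES = 30
DEFAULT_N_BINS = 32

Normalization = Literal["frequency", "count"]


@dataclass(frozen=True)
class CompositeFrame:
    """One multispectral 8-day composite for a location-year.

    ``bands`` is an ``H x W x d`` grid; ``valid_mask`` marks usable pixels
    (``False`` where the sensor delivered nodata).
    """

    location_id: str
    year: int
    time_index: int  # 1-based position within the season, 1..T
    bands: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        bands = np.asarray(self.bands, dtype=np.float64)
        if bands.ndim != 3:
            raise ValueError(f"bands must be H x W x d, got shape {bands.shape}")
        mask = self.valid_mask
        if mask is None:
            mask = np.isfinite(bands).all(axis=-1)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != bands.shape[:2]:
                raise ValueError(
                    f"valid_mask shape {mask.shape} does not match spatial "
                    f"dimensions {bands.shape[:2]}"
                )
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "valid_mask", mask)

    @property
    def n_bands(self) -> int:
        return self.bands.shape[2]


@dataclass(frozen=True)
class CroplandMask:
    """Boolean cropland mask for a location-year (union of crop layers)."""

    location_id: str
    year: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class BinningScheme:
    """Per-band histogram bin edges.

    ``edges`` has shape ``d x (b+1)`` and is strictly increasing along the
    last axis. Bins are half-open ``[lo, hi)`` with the last bin closed;
    out-of-range values clamp into the edge bins so mass is conserved.
    """

    edges: np.ndarray
    normalization: Normalization = "frequency"

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.float64)
        if edges.ndim != 2 or edges.shape[1] < 2:
            raise ValueError("edges must have shape d x (b+1) with b >= 1")
        if not np.isfinite(edges).all():
            raise ValueError("bin edges must be finite")
        if not (np.diff(edges, axis=1) > 0).all():
            raise ValueError("bin edges must be strictly increasing per band")
        if self.normalization not in ("frequency", "count"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return self.edges.shape[1] - 1

    @property
    def n_bands(self) -> int:
        return self.edges.shape[0]


@dataclass
class HistogramTensor:
    """Season histogram stack ``values``: shape ``T x b x d``.

    ``cutoff_index`` is the last composite (1-based) that carries data; slices
    beyond it are identically zero (used for in-season truncation).
    """

    values: np.ndarray
    location_id: str
    year: int
    cutoff_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be T x b x d")
        if not 0 <= self.cutoff_index <= self.values.shape[0]:
            raise ValueError("cutoff_index out of range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def default_composite_calendar(
    n_composites: int = DEFAULT_N_COMPOSITES, first_period: int = 9
) -> dict[int, int]:
    """Start day-of-year of each composite, keyed by 1-based time index.

    Standard 8-day compositing periods start on DOY ``1 + 8*(n-1)``. The
    growing-season window (March-October) retains periods 9..38, i.e. start
    DOYs 65, 73, ..., 297 — exactly 30 composites (non-leap calendar).
    """
    return {
        t: 1 + 8 * (first_period - 1 + (t - 1)) for t in range(1, n_composites + 1)
    }


def compute_bin_edges(
    training_frames: Iterable[CompositeFrame],
    b: int = DEFAULT_N_BINS,
    strategy: Literal["linear"] = "linear",
    normalization: Normalization = "frequency",
) -> BinningScheme:
    """Place ``b+1`` linearly spaced edges per band over the training frames.

    Only valid pixels of the *training* frames participate (edges computed
    from held-out years would leak). A band whose training values are all
    invalid, or non-finite, is an error.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if strategy != "linear":
        raise ValueError(f"unknown edge strategy {strategy!r}")
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    for frame in training_frames:
        vals = frame.bands[frame.valid_mask]  # (n_valid, d)
        if vals.size == 0:
            continue
        if not np.isfinite(vals).all():
            raise ValueError(
                f"non-finite pixel values in frame "
                f"({frame.location_id}, {frame.year}, t={frame.time_index})"
            )
        fmin, fmax = vals.min(axis=0), vals.max(axis=0)
        lo = fmin if lo is None else np.minimum(lo, fmin)
        hi = fmax if hi is None else np.maximum(hi, fmax)
    if lo is None:
        raise ValueError("training frames contain no valid pixels")
    degenerate = ~(hi > lo)
    if degenerate.any():
        # constant band: widen symmetrically so edges stay strictly increasing
        pad = np.where(np.abs(lo) > 0, np.abs(lo) * 1e-6, 1e-6)
        lo = np.where(degenerate, lo - pad, lo)
        hi = np.where(degenerate, hi + pad, hi)
    edges = np.linspace(lo, hi, b + 1, axis=1)
    return BinningScheme(edges=edges, normalization=normalization)


def frame_histogram(
    frame: CompositeFrame, cropland: CroplandMask, scheme: BinningScheme
) -> np.ndarray:
    """Histogram the frame's valid cropland pixels per band -> ``b x d``.

    Values below the first edge land in bin 1 and above the last edge in bin
    ``b`` (clamping conserves mass; nodata is excluded via ``valid_mask``
    beforehand). In frequency mode each band column sums to 1, or to 0 when
    no pixel was counted.
    """
    if cropland.mask.shape != frame.bands.shape[:2]:
        raise ValueError(
            f"cropland mask shape {cropland.mask.shape} does not match frame "
            f"spatial dimensions {frame.bands.shape[:2]}"
        )
    d = frame.n_bands
    if scheme.n_bands != d:
        raise ValueError(f"scheme covers {scheme.n_bands} bands, frame has {d}")
    b = scheme.n_bins
    counted = frame.valid_mask & cropland.mask
    vals = frame.bands[counted]  # (n, d)
    out = np.zeros((b, d), dtype=np.float64)
    n = vals.shape[0]
    if n == 0:
        logger.warning(
            "no valid cropland pixels for (%s, %s, t=%s); zero histogram",
            frame.location_id, frame.year, frame.time_index,
        )
        return out
    for j in range(d):
        # searchsorted on interior edges gives half-open [lo, hi) bins with
        # the last bin closed and out-of-range values clamped to edge bins.
        idx = np.searchsorted(scheme.edges[j, 1:-1], vals[:, j], side="right")
        out[:, j] = np.bincount(idx, minlength=b)
    if scheme.normalization == "frequency":
        out /= n
    return out


def build_histogram_tensor(
    frames: Sequence[CompositeFrame],
    cropland: CroplandMask,
    scheme: BinningScheme,
    n_composites: int = DEFAULT_N_COMPOSITES,
) -> HistogramTensor:
    """Stack per-composite histograms into a ``T x b x d`` tensor.

    Frames are placed by ``time_index`` (input order is irrelevant); a
    missing composite — e.g. fully cloud-contaminated — becomes an all-zero
    slice.
    """
    if not frames:
        raise ValueError("no frames supplied")
    values = np.zeros((n_composites, scheme.n_bins, scheme.n_bands))
    seen: set[int] = set()
    loc, year = frames[0].location_id, frames[0].year
    for frame in frames:
        t = frame.time_index
        if not 1 <= t <= n_composites:
            raise ValueError(f"time_index {t} outside 1..{n_composites}")
        if t in seen:
            raise ValueError(f"duplicate time_index {t} for ({loc}, {year})")
        seen.add(t)
        values[t - 1] = frame_histogram(frame, cropland, scheme)
    missing = set(range(1, n_composites + 1)) - seen
    if missing:
        logger.warning(
            "missing composites %s for (%s, %s); zero slices",
            sorted(missing), loc, year,
        )
    return HistogramTensor(
        values=values, location_id=loc, year=year, cutoff_index=n_composites
    )


def truncate_season(
    tensor: HistogramTensor,
    forecast_doy: int,
    composite_calendar: Mapping[int, int] | None = None,
) -> HistogramTensor:
    """Zero every composite whose start DOY exceeds the forecast date.

    Returns a new tensor of identical shape with ``cutoff_index`` set to the
    last retained composite (0 if the forecast precedes the season). The
    forecast dates of interest are the 23rd of July/August/September/October:
    DOYs 204, 235, 266, 296 in a non-leap year.
    """
    if not 1 <= forecast_doy <= 366:
        raise ValueError(f"forecast_doy {forecast_doy} outside the year")
    T = tensor.values.shape[0]
    calendar = composite_calendar or default_composite_calendar(T)
    missing = [t for t in range(1, T + 1) if t not in calendar]
    if missing:
        raise ValueError(f"composite calendar does not cover indices {missing}")
    cutoff = 0
    for t in range(1, T + 1):
        if calendar[t] <= forecast_doy:
            cutoff = max(cutoff, t)
    values = tensor.values.copy()
    values[cutoff:] = 0.0
    return HistogramTensor(
        values=values,
        location_id=tensor.location_id,
        year=tensor.year,
        cutoff_index=min(cutoff, tensor.cutoff_index),
    )


#: Forecast dates used for progressive in-season evaluation: the 23rd of
#: July, August, September and October (month, day).
FORECAST_DATES: tuple[tuple[int, int], ...] = ((7, 23), (8, 23), (9, 23), (10, 23))


def month_day_to_doy(month: int, day: int) -> int:
    """Day-of-year for a non-leap calendar."""
    lengths = [31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31]
    if not 1 <= month <= 12 or not 1 <= day <= lengths[month - 1]:
        raise ValueError(f"invalid month/day {month}/{day}")
    return sum(lengths[: month - 1]) + day
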