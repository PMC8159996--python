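"""Paired histogram/yield dataset container shared by training and simulation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .histograms import HistogramTensor

CORN = "corn"
SOY = "soybean"


@dataclass(frozen=True)
class Entry:
    """One location-year: histogram tensor plus the available yield labels."""

    location_id: str
    year: int
    histogram: HistogramTensor
    corn_yield: float | None = None
    soy_yield: float | None = None

    def __post_init__(self) -> None:
        if self.corn_yield is None and self.soy_yield is None:
            raise ValueError(
                f"entry ({self.location_id}, {self.year}) has no yield label"
            )
        for name, y in (("corn", self.corn_yield), ("soybean", self.soy_yield)):
            if y is not None and not y > 0:
                raise ValueError(f"{name} yield must be positive, got {y}")


class PairedDataset:
    """Collection of (histogram, corn yield?, soybean yield?) entries.

    (location, year) pairs are unique; every entry carries at least one crop
    label. Iteration order is insertion order.
    """

    def __init__(self, entries: Iterable[Entry] = ()):
        self.entries: list[Entry] = []
        self._keys: set[tuple[str, int]] = set()
        for e in entries:
            self.append(e)

    def append(self, entry: Entry) -> None:
        key = (entry.location_id, entry.year)
        if key in self._keys:
            raise ValueError(f"duplicate (location, year) {key}")
        self._keys.add(key)
        self.entries.append(entry)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Entry]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> Entry:
        return self.entries[i]

    def years(self) -> tuple[int, ...]:
        return tuple(sorted({e.year for e in self.entries}))

    def filter_years(self, years: Sequence[int]) -> "PairedDataset":
        keep = set(years)
        return PairedDataset(e for e in self.entries if e.year in keep)

    def tensor_shape(self) -> tuple[int, int, int]:
        if not self.entries:
            raise ValueError("empty dataset")
        return self.entries[0].histogram.shape

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack to ``(X, y_corn, y_soy)``; missing labels become NaN."""
        X = np.stack([e.histogram.values for e in self.entries]).astype(np.float32)
        yc = np.array(
            [np.nan if e.corn_yield is None else e.corn_yield for e in self.entries]
        )
        ys = np.array(
            [np.nan if e.soy_yield is None else e.soy_yield for e in self.entries]
        )
        return X, yc, ys

    def crop_means(self) -> dict[str, float]:
        _, yc, ys = self.to_arrays()
        out = {}
        if np.isfinite(yc).any():
            out[CORN] = float(np.nanmean(yc))
        if np.isfinite(ys).any():
            out[SOY] = float(np.nanmean(ys))
        return out

    def map_histograms(self, fn) -> "PairedDataset":
        """Apply ``fn`` to every histogram tensor (e.g. season truncation)."""
        return PairedDataset(
            Entry(e.location_id, e.year, fn(e.histogram), e.corn_yield, e.soy_yield)
            for e in self.entries
        )
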