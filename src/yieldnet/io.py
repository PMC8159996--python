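"""Readers and writers shared by the pipeline.

Yield tables are CSV with columns ``location_id, year, crop,
yield_bu_per_acre`` (crop in {corn, soybean}, yields strictly positive).
Rasters are multi-band float32 TIFF files, channels last, with NaN encoding
nodata; cropland masks are single-band 0/1 uint8 TIFFs. Histogram tensors
cache to ``.npy`` with a JSON sidecar carrying identity and binning
provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .data import CORN, SOY
from .histograms import BinningScheme, HistogramTensor

YIELD_COLUMNS = ["location_id", "year", "crop", "yield_bu_per_acre"]
VALID_CROPS = {CORN, SOY}


def read_yield_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a county yield CSV.

    Malformed rows are reported with their 1-based line numbers (header is
    line 1). An empty table (header only) is valid.
    """
    df = pd.read_csv(path)
    missing = [c for c in YIELD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return df[YIELD_COLUMNS]
    df = df[YIELD_COLUMNS].copy()
    df["crop"] = df["crop"].astype(str).str.strip().str.lower()
    lines = df.index + 2  # header occupies line 1
    bad = []
    year_num = pd.to_numeric(df["year"], errors="coerce")
    yld = pd.to_numeric(df["yield_bu_per_acre"], errors="coerce")
    for i, ln in enumerate(lines):
        problems = []
        if df["crop"].iloc[i] not in VALID_CROPS:
            problems.append(f"crop {df['crop'].iloc[i]!r}")
        if not np.isfinite(year_num.iloc[i]) or year_num.iloc[i] != int(
            year_num.iloc[i]
        ):
            problems.append("year")
        if not np.isfinite(yld.iloc[i]) or yld.iloc[i] <= 0:
            problems.append(f"yield {df['yield_bu_per_acre'].iloc[i]!r}")
        if problems:
            bad.append(f"line {ln}: " + ", ".join(problems))
    if bad:
        raise ValueError(f"{path}: invalid rows\n" + "\n".join(bad))
    df["year"] = year_num.astype(int)
    df["yield_bu_per_acre"] = yld.astype(float)
    return df


def write_yield_table(df: pd.DataFrame, path: str | Path) -> None:
    df[YIELD_COLUMNS].to_csv(path, index=False)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write an evaluation report as tidy CSV."""
    report.to_csv(path, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_raster(grid: np.ndarray, path: str | Path) -> None:
    """Write an H x W[x d] float32 raster; NaN marks nodata."""
    grid = np.asarray(grid, dtype=np.float32)
    kwargs = {"photometric": "minisblack"} if grid.ndim == 3 else {}
    if grid.ndim == 3:
        kwargs["planarconfig"] = "contig"
    tifffile.imwrite(str(path), grid, **kwargs)


def read_raster(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a raster; returns (grid, valid_mask) with NaN as nodata."""
    grid = tifffile.imread(str(path)).astype(np.float64)
    spatial_valid = np.isfinite(grid)
    if grid.ndim == 3:
        spatial_valid = spatial_valid.all(axis=-1)
    return grid, spatial_valid


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(bool)


def _edges_digest(scheme: BinningScheme) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(scheme.edges, dtype=np.float64).tobytes()
    ).hexdigest()[:16]


def write_histogram_cache(
    tensor: HistogramTensor, scheme: BinningScheme, directory: str | Path
) -> Path:
    """NPY tensor + JSON sidecar (identity, cutoff, bin-edge digest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{tensor.location_id}_{tensor.year}"
    np.save(directory / f"{stem}.npy", tensor.values)
    sidecar = {
        "location_id": tensor.location_id,
        "year": tensor.year,
        "cutoff_index": tensor.cutoff_index,
        "bin_edges_digest": _edges_digest(scheme),
        "normalization": scheme.normalization,
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / f"{stem}.npy"


def read_histogram_cache(npy_path: str | Path) -> HistogramTensor:
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    return HistogramTensor(
        values=np.load(npy_path),
        location_id=meta["location_id"],
        year=int(meta["year"]),
        cutoff_index=int(meta["cutoff_index"]),
    )
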