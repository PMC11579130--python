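"""Reading and writing rasters, label masks, region overlays and tables.

Images are 8-bit PNG/TIFF (gray or RGB); label masks are single-channel 8-bit
PNG; region overlays are single-channel 8/16-bit PNG or TIFF.  Region tables
and anchor-pair lists are plain CSV.  This module also implements the
down-sample + contrast-enhancement step that turns full-resolution slides
(~0.92 um/px, where individual cell bodies resolve) into the working
resolution (~9.2 um/px) at which laminae read as texture differences.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import (
    BACKGROUND,
    N_LAYERS,
    ConfigError,
    FormatError,
    LayerMask,
    Raster,
    RegionOverlay,
    RegionTable,
    as_gray,
)

__all__ = [
    "read_raster",
    "write_raster",
    "read_mask",
    "write_mask",
    "read_overlay",
    "write_overlay",
    "read_region_table",
    "write_region_table",
    "read_anchor_pairs",
    "downsample_enhance",
]


def _load(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return np.asarray(iio.imread(path))


def read_raster(path: str | Path, spacing_um: float, name: str | None = None) -> Raster:
    """Read an 8-bit gray or RGB image as a :class:`Raster`.

    An alpha channel, if present, is dropped.
    """
    arr = _load(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit image, got dtype {arr.dtype}")
    return Raster(arr, spacing_um, name=name if name is not None else Path(path).stem)


def write_raster(raster: Raster, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(raster.pixels, dtype=np.uint8))


def read_mask(path: str | Path, spacing_um: float) -> LayerMask:
    """Read a single-channel 8-bit layer mask; labels must lie in 0–6.

    Out-of-range values are an error, never clamped: the offending value(s)
    and their pixel counts are reported.
    """
    arr = _load(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path}: mask must be 8-bit, got dtype {arr.dtype}")
    bad = np.unique(arr[arr > N_LAYERS])
    if bad.size:
        counts = {int(v): int(np.sum(arr == v)) for v in bad}
        detail = ", ".join(f"label {v} at {n} pixel(s)" for v, n in counts.items())
        raise FormatError(f"{path}: values outside 0-{N_LAYERS}: {detail}")
    return LayerMask(arr.astype(np.uint8), spacing_um)


def write_mask(mask: LayerMask, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(mask.labels, dtype=np.uint8))


def read_overlay(path: str | Path, spacing_um: float) -> RegionOverlay:
    """Read a single-channel 8/16-bit region-ID overlay."""
    arr = _load(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: overlay must be single-channel, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path}: overlay must be 8- or 16-bit, got {arr.dtype}")
    return RegionOverlay(arr.astype(np.int64), spacing_um)


def write_overlay(overlay: RegionOverlay, path: str | Path) -> None:
    ids = np.asarray(overlay.ids)
    if ids.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("region IDs exceed 16-bit range")
    iio.imwrite(Path(path), ids.astype(np.uint16))


def read_region_table(path: str | Path) -> RegionTable:
    """Read a CSV with header ``region_id,abbreviation,definition``."""
    return RegionTable(pd.read_csv(path))


def write_region_table(table: RegionTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def read_anchor_pairs(path: str | Path) -> np.ndarray:
    """Read anchor pairs from CSV ``ref_row,ref_col,moved_row,moved_col``.

    Returns an ``(n, 4)`` float array in pixel coordinates.
    """
    frame = pd.read_csv(path)
    required = ["ref_row", "ref_col", "moved_row", "moved_col"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: anchor CSV is missing columns {missing}")
    return frame[required].to_numpy(dtype=np.float64)


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Area (block-mean) reduction; output dims are floor(input / factor)."""
    h, w = arr.shape[0] // factor, arr.shape[1] // factor
    arr = arr[: h * factor, : w * factor]
    if arr.ndim == 2:
        return arr.reshape(h, factor, w, factor).mean(axis=(1, 3))
    return arr.reshape(h, factor, w, factor, arr.shape[2]).mean(axis=(1, 3))


def downsample_enhance(img: Raster, factor: int, contrast: float) -> Raster:
    """Block-mean downsample by ``factor`` then linearly stretch contrast.

    The contrast stretch pivots about the grayscale mean ``m`` of the
    downsampled image: ``out = clip(m + contrast * (in - m), 0, 255)``;
    ``contrast = 1`` leaves values unchanged, ``contrast = 2`` doubles
    deviations from the mean.  Pixel spacing is multiplied by ``factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ConfigError(f"factor must be an integer >= 1, got {factor}")
    if contrast < 0:
        raise ConfigError(f"contrast must be >= 0, got {contrast}")
    h, w = img.shape
    if factor > h or factor > w:
        raise ConfigError(f"factor {factor} exceeds image dimensions {h}x{w}")
    factor = int(factor)

    down = _block_mean(np.asarray(img.pixels, dtype=np.float64), factor)
    mean = as_gray(down).mean()
    out = np.clip(mean + contrast * (down - mean), 0.0, 255.0)
    return Raster(
        np.round(out).astype(np.uint8),
        img.spacing_um * factor,
        name=img.name,
    )
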