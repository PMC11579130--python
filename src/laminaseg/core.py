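"""Core containers for histology-style imagery and laminar label masks.

Conventions used throughout the package: arrays are row-major with origin at
the top-left pixel, indices are 0-based, and windows are half-open
``[row, row + h) x [col, col + w)``.  Physical scale is carried as the side
length of one pixel in micrometres (``spacing_um``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: ITU-R BT.601 luma weights; the single RGB->gray convention of this package.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Number of cortical laminae; labels run 1 (Layer I, pial side) .. 6 (Layer VI).
N_LAYERS = 6

#: Background / outside-cortex label.
BACKGROUND = 0


class FormatError(ValueError):
    """An on-disk file violates the format contract (e.g. stray mask labels)."""


class ConfigError(ValueError):
    """A configuration value violates its invariants."""


class RegionLookupError(KeyError):
    """A requested region abbreviation is not present in the lookup table."""


def as_gray(pixels: np.ndarray) -> np.ndarray:
    """Return a float64 grayscale view of an ``(H, W)`` or ``(H, W, 3)`` array.

    RGB is collapsed with the 0.299/0.587/0.114 luma weights.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ np.asarray(LUMA_WEIGHTS)
    raise ValueError(f"expected (H, W) or (H, W, 3) array, got shape {arr.shape}")


@dataclass
class Raster:
    """An 8-bit intensity image (1 or 3 channels) with physical pixel spacing.

    Parameters
    ----------
    pixels
        ``(H, W)`` or ``(H, W, 3)`` array of values in 0–255.
    spacing_um
        Physical side length of one pixel in micrometres; must be positive.
    name
        Free-form identifier (e.g. slide / section name).
    """

    pixels: np.ndarray
    spacing_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3) or (
            self.pixels.ndim == 3 and self.pixels.shape[2] != 3
        ):
            raise ValueError(f"Raster needs (H, W) or (H, W, 3); got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("Raster must have height >= 1 and width >= 1")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be > 0")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"pixel values must lie in 0-255; found range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        """Canvas shape ``(H, W)`` regardless of channel count."""
        return self.pixels.shape[0], self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Grayscale (luma) float64 view of the pixels."""
        return as_gray(self.pixels)


@dataclass
class LayerMask:
    """Per-pixel laminar labels: 0 = background, 1–6 = cortical Layers I–VI."""

    labels: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"LayerMask labels must be 2D; got {self.labels.shape}")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be > 0")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LayerMask labels must be integer-typed")
        lo, hi = int(self.labels.min()), int(self.labels.max())
        if lo < BACKGROUND or hi > N_LAYERS:
            raise ValueError(f"labels must lie in 0-{N_LAYERS}; found range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def present_layers(self) -> list[int]:
        """Sorted list of laminar labels (1–6) present in the mask."""
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != BACKGROUND]


@dataclass
class RegionOverlay:
    """Per-pixel brain-region IDs; 0 marks unlabeled pixels."""

    ids: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        if self.ids.ndim != 2:
            raise ValueError(f"RegionOverlay ids must be 2D; got {self.ids.shape}")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be > 0")
        if not np.issubdtype(self.ids.dtype, np.integer):
            raise ValueError("RegionOverlay ids must be integer-typed")
        if int(self.ids.min()) < 0:
            raise ValueError("region IDs must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ids.shape  # type: ignore[return-value]


@dataclass
class RegionTable:
    """Lookup table mapping region IDs to abbreviations and definitions.

    Backed by a DataFrame with columns ``region_id, abbreviation, definition``;
    both IDs and abbreviations must be unique.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["region_id", "abbreviation", "definition"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise FormatError(f"RegionTable is missing columns: {missing}")
        self.frame = self.frame[required].copy()
        self.frame["region_id"] = self.frame["region_id"].astype(int)
        if self.frame["region_id"].duplicated().any():
            raise FormatError("region_id values must be unique")
        if self.frame["abbreviation"].duplicated().any():
            raise FormatError("abbreviations must be unique")

    @classmethod
    def from_rows(cls, rows: list[tuple[int, str, str]]) -> "RegionTable":
        return cls(pd.DataFrame(rows, columns=["region_id", "abbreviation", "definition"]))

    @property
    def abbreviations(self) -> list[str]:
        return list(self.frame["abbreviation"])

    def ids_for(self, wanted: set[str] | list[str]) -> set[int]:
        """Region IDs for a set of abbreviations; unknown names raise."""
        wanted = set(wanted)
        known = dict(zip(self.frame["abbreviation"], self.frame["region_id"]))
        unknown = sorted(wanted - set(known))
        if unknown:
            raise RegionLookupError(
                f"unknown region abbreviation(s) {unknown}; valid names: {sorted(known)}"
            )
        return {int(known[a]) for a in wanted}

    def abbreviation_for(self, region_id: int) -> str:
        match = self.frame.loc[self.frame["region_id"] == region_id, "abbreviation"]
        if match.empty:
            raise RegionLookupError(f"unknown region id {region_id}")
        return str(match.iloc[0])
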