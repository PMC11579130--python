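"""Region-of-interest extraction from brain-region overlays.

A registered atlas overlay assigns each pixel a brain-region ID; a lookup
table maps IDs to region abbreviations (e.g. the twelve auditory-cortex
areas AuA1, AuAL, ...).  Selecting a set of abbreviations yields a binary
cortex mask, which is then applied to the intensity image so that downstream
patching and segmentation see only the region of interest.
"""

from __future__ import annotations

import numpy as np

from .core import Raster, RegionOverlay, RegionTable

__all__ = ["extract_region_mask", "apply_cortex_mask"]


def extract_region_mask(
    overlay: RegionOverlay, table: RegionTable, wanted: set[str] | list[str]
) -> np.ndarray:
    """Binary mask that is True exactly where the overlay ID maps to a wanted region.

    Unknown abbreviations raise :class:`~laminaseg.core.RegionLookupError`
    listing the valid names.  An empty selection yields an all-False mask.
    """
    ids = table.ids_for(wanted)
    if not ids:
        return np.zeros(overlay.shape, dtype=bool)
    return np.isin(overlay.ids, sorted(ids))


def apply_cortex_mask(img: Raster, mask: np.ndarray) -> Raster:
    """Zero every pixel outside the binary cortex mask; keep the rest unchanged."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    pixels = np.asarray(img.pixels).copy()
    if pixels.ndim == 3:
        pixels[~mask, :] = 0
    else:
        pixels[~mask] = 0
    return Raster(pixels, img.spacing_um, name=img.name)
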