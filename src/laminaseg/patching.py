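"""Overlapping-window patch extraction and the three-rule training filter.

A sliding window (default 512 px, stride 32 px) tiles the section into
heavily overlapping feature/mask patch pairs.  For training, a patch pair is
kept only if (i) all six laminar labels appear in the mask window, (ii) every
laminar label covers at least ``min_pixels_per_layer`` pixels (default 5,
inclusive), and (iii) the mean grayscale intensity of the feature window is
strictly greater than ``min_mean_intensity`` (default 10).  Inference never
filters: stitching requires every pixel to be covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BACKGROUND, N_LAYERS, ConfigError, LayerMask, Raster

__all__ = [
    "PatchGridSpec",
    "PatchPair",
    "FilterCriteria",
    "make_patch_grid",
    "passes_filter",
    "extract_patches",
    "pad_to_window",
]


@dataclass(frozen=True)
class PatchGridSpec:
    """Sliding-window geometry: square window edge and stride, in pixels."""

    window: int = 512
    stride: int = 32

    def __post_init__(self) -> None:
        if not (1 <= self.stride <= self.window):
            raise ConfigError(
                f"stride must satisfy 1 <= stride <= window; got "
                f"stride={self.stride}, window={self.window}"
            )


@dataclass(frozen=True)
class FilterCriteria:
    """The three training-patch quality rules."""

    require_all_layers: bool = True
    min_pixels_per_layer: int = 5
    min_mean_intensity: float = 10.0

    def __post_init__(self) -> None:
        if self.min_pixels_per_layer < 1:
            raise ConfigError("min_pixels_per_layer must be >= 1")
        if self.min_mean_intensity < 0:
            raise ConfigError("min_mean_intensity must be >= 0")


@dataclass
class PatchPair:
    """A feature window and its mask window, anchored at ``origin`` (row, col)."""

    origin: tuple[int, int]
    feature: Raster
    mask: LayerMask


def _axis_origins(dim: int, window: int, stride: int) -> list[int]:
    origins = list(range(0, dim - window + 1, stride))
    if origins[-1] != dim - window:  # flush window so the border is covered
        origins.append(dim - window)
    return origins


def make_patch_grid(canvas: tuple[int, int], spec: PatchGridSpec) -> list[tuple[int, int]]:
    """Row-major list of window origins covering the canvas.

    Origins are multiples of the stride, plus one flush origin per axis when
    ``(dim - window)`` is not a stride multiple, so every pixel is covered.
    """
    h, w = canvas
    if h < spec.window or w < spec.window:
        raise ConfigError(
            f"canvas {h}x{w} is smaller than the {spec.window}px window; "
            "pad the inputs first (see pad_to_window)"
        )
    rows = _axis_origins(h, spec.window, spec.stride)
    cols = _axis_origins(w, spec.window, spec.stride)
    return [(r, c) for r in rows for c in cols]


def passes_filter(pair: PatchPair, criteria: FilterCriteria) -> tuple[bool, str]:
    """Apply the three-rule filter; returns (kept, reason).

    ``reason`` names the first failed rule (``missing_layer``,
    ``too_few_pixels``, ``low_intensity``) or is ``"ok"``.
    """
    labels = np.asarray(pair.mask.labels)
    counts = np.bincount(labels.ravel(), minlength=N_LAYERS + 1)
    if criteria.require_all_layers:
        missing = [k for k in range(1, N_LAYERS + 1) if counts[k] == 0]
        if missing:
            return False, "missing_layer"
        checked = range(1, N_LAYERS + 1)
    else:
        checked = [k for k in range(1, N_LAYERS + 1) if counts[k] > 0]
    if any(counts[k] < criteria.min_pixels_per_layer for k in checked):
        return False, "too_few_pixels"
    if not pair.feature.gray().mean() > criteria.min_mean_intensity:
        return False, "low_intensity"
    return True, "ok"


def pad_to_window(
    img: Raster, mask: LayerMask | None, window: int
) -> tuple[Raster, LayerMask | None, tuple[int, int]]:
    """Symmetrically pad feature (zeros) and mask (background) up to window size.

    Returns the padded pair and the (top, left) pad offsets; no-op when the
    canvas already fits the window.
    """
    h, w = img.shape
    pad_h, pad_w = max(0, window - h), max(0, window - w)
    if pad_h == 0 and pad_w == 0:
        return img, mask, (0, 0)
    top, left = pad_h // 2, pad_w // 2
    spec = [(top, pad_h - top), (left, pad_w - left)]
    pixels = np.asarray(img.pixels)
    if pixels.ndim == 3:
        pixels = np.pad(pixels, spec + [(0, 0)], constant_values=0)
    else:
        pixels = np.pad(pixels, spec, constant_values=0)
    padded_img = Raster(pixels, img.spacing_um, name=img.name)
    padded_mask = None
    if mask is not None:
        padded_mask = LayerMask(
            np.pad(np.asarray(mask.labels), spec, constant_values=BACKGROUND),
            mask.spacing_um,
        )
    return padded_img, padded_mask, (top, left)


def extract_patches(
    img: Raster,
    mask: LayerMask,
    spec: PatchGridSpec,
    criteria: FilterCriteria | None = None,
    pad: bool = True,
) -> list[PatchPair]:
    """Cut the overlapping patch grid; filter pairs when criteria are given.

    With ``criteria`` (training mode) only pairs passing :func:`passes_filter`
    are returned; without (inference mode) every grid pair is returned.
    Canvases smaller than the window are padded first when ``pad`` is True;
    origins then refer to the padded canvas.
    """
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    if pad:
        img, mask, _ = pad_to_window(img, mask, spec.window)
    origins = make_patch_grid(img.shape, spec)
    pixels = np.asarray(img.pixels)
    labels = np.asarray(mask.labels)
    wdw = spec.window
    out: list[PatchPair] = []
    for r, c in origins:
        pair = PatchPair(
            origin=(r, c),
            feature=Raster(pixels[r : r + wdw, c : c + wdw], img.spacing_um),
            mask=LayerMask(labels[r : r + wdw, c : c + wdw], mask.spacing_um),
        )
        if criteria is None or passes_filter(pair, criteria)[0]:
            out.append(pair)
    return out
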