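"""Heatmap-based stitching of overlapping patch predictions.

Each predicted patch contributes per-layer probabilities to six canvas-sized
heatmaps; overlapping contributions are averaged (every pixel is interpolated
from all windows that saw it, not copied from one).  Each heatmap is then
cleaned by locally adaptive thresholding — per-tile Otsu splitting of the
bimodal value histogram, falling back to the layer's global threshold where a
tile is effectively unimodal — and the six surviving maps are merged into a
single label mask by argmax (ties go to the smaller layer index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ConfigError, LayerMask, N_LAYERS

logger = logging.getLogger("laminaseg.stitching")

__all__ = [
    "PatchPrediction",
    "HeatmapStack",
    "accumulate",
    "threshold_stack",
    "merge_layers",
]


@dataclass
class PatchPrediction:
    """Per-layer probabilities for one window: ``probs`` is (h, w, 6) in [0, 1].

    Per-pixel layer probabilities may sum to less than 1; the residual is
    background.  One-hot values are the hard-backend special case.
    """

    origin: tuple[int, int]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3 or self.probs.shape[2] != N_LAYERS:
            raise ValueError(f"probs must be (h, w, {N_LAYERS}); got {self.probs.shape}")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.probs.sum(axis=2).max() > 1 + 1e-9:
            raise ValueError("per-pixel probabilities must sum to <= 1")


@dataclass
class HeatmapStack:
    """Six per-layer heatmaps plus the per-pixel window-coverage count."""

    maps: np.ndarray  # (6, H, W), values in [0, 1] after accumulation
    coverage: np.ndarray  # (H, W) int

    @property
    def canvas(self) -> tuple[int, int]:
        return self.maps.shape[1], self.maps.shape[2]


def accumulate(
    preds: list[PatchPrediction], canvas: tuple[int, int]
) -> HeatmapStack:
    """Average overlapping patch probabilities into per-layer heatmaps.

    ``maps[k][p]`` is the mean over all covering windows of their layer-k
    probability at pixel ``p``; uncovered pixels stay 0.  The operation is
    invariant to the order of the patch list.
    """
    h, w = canvas
    sums = np.zeros((N_LAYERS, h, w), dtype=np.float64)
    coverage = np.zeros((h, w), dtype=np.int64)
    for pred in preds:
        r, c = pred.origin
        ph, pw = pred.probs.shape[:2]
        if r < 0 or c < 0 or r + ph > h or c + pw > w:
            raise ValueError(
                f"window at {pred.origin} of size {ph}x{pw} falls outside canvas {h}x{w}"
            )
        sums[:, r : r + ph, c : c + pw] += np.moveaxis(pred.probs, 2, 0)
        coverage[r : r + ph, c : c + pw] += 1
    maps = np.divide(sums, coverage, out=np.zeros_like(sums), where=coverage > 0)
    return HeatmapStack(maps=maps, coverage=coverage)


def _otsu_split(values: np.ndarray, nbins: int = 256) -> tuple[float, float, float]:
    """Otsu threshold of a value sample.

    Returns ``(threshold, between_class_variance, total_variance)``; a
    degenerate (constant) sample reports zero variances.
    """
    values = values.ravel()
    total_var = float(values.var())
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin or total_var == 0.0:
        return vmin, 0.0, total_var
    hist, edges = np.histogram(values, bins=nbins, range=(vmin, vmax))
    hist = hist.astype(np.float64)
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between, nan=0.0)
    best = int(np.argmax(between[:-1]))  # last split leaves class 1 empty
    return float(edges[best + 1]), float(between[best]), total_var


# Tiles whose between-class variance is below this fraction of total variance
# are treated as unimodal and fall back to the layer's global threshold.
_UNIMODAL_FRACTION = 1e-6


def threshold_stack(
    stack: HeatmapStack, method: str = "adaptive", tile: int = 256
) -> HeatmapStack:
    """Zero heatmap values below a per-layer (per-tile) Otsu threshold.

    ``method='adaptive'`` thresholds tile-by-tile with a global fallback for
    effectively unimodal tiles; ``method='global'`` uses one threshold per
    layer.  Surviving values keep their magnitudes (the merge step uses them
    for argmax).  A layer that is entirely flat keeps threshold 0, i.e. is
    left untouched.
    """
    if method not in ("adaptive", "global"):
        raise ConfigError(f"unknown threshold method {method!r}")
    if method == "adaptive" and tile < 16:
        raise ConfigError(f"tile must be >= 16 px, got {tile}")
    h, w = stack.canvas
    out = stack.maps.copy()
    for k in range(N_LAYERS):
        layer_map = stack.maps[k]
        g_thr, g_between, g_total = _otsu_split(layer_map)
        if g_total == 0.0 or g_between < _UNIMODAL_FRACTION * g_total:
            g_thr = 0.0  # flat layer: nothing to separate, keep everything
        if method == "global":
            out[k][layer_map < g_thr] = 0.0
            logger.debug("layer %d: global threshold %.4f", k + 1, g_thr)
            continue
        for r0 in range(0, h, tile):
            for c0 in range(0, w, tile):
                sl = (slice(r0, min(r0 + tile, h)), slice(c0, min(c0 + tile, w)))
                sub = layer_map[sl]
                thr, between, total = _otsu_split(sub)
                if total == 0.0 or between < _UNIMODAL_FRACTION * total:
                    thr = g_thr
                block = out[k][sl]
                block[sub < thr] = 0.0
        logger.debug("layer %d: adaptive thresholds around global %.4f", k + 1, g_thr)
    return HeatmapStack(maps=out, coverage=stack.coverage.copy())


def merge_layers(stack: HeatmapStack, spacing_um: float = 1.0) -> LayerMask:
    """Merge thresholded heatmaps into one label mask by per-pixel argmax.

    Pixels where every layer is zero become background; ties between layers
    go to the smaller layer index (``np.argmax`` convention).
    """
    best = np.argmax(stack.maps, axis=0).astype(np.uint8) + 1
    peak = np.max(stack.maps, axis=0)
    labels = np.where(peak > 0, best, np.uint8(0)).astype(np.uint8)
    return LayerMask(labels, spacing_um=spacing_um)
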