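"""Pluggable per-patch segmentation backends.

The deep segmentation network is an adapter boundary in this framework: any
object with ``predict(feature, origin) -> (h, w, 6)`` probabilities can sit
in the pipeline's prediction seat.  Two concrete backends ship here:

* :class:`OracleBackend` — returns the one-hot ground truth restricted to
  the window; the stitching fixed-point fixture.
* :class:`TextureBackend` — a desk-scale nearest-centroid classifier over
  two hand-crafted texture features (local mean intensity and local
  dark-blob density in a 15x15 neighborhood), which segments the synthetic
  phantoms meaningfully on a CPU in seconds and exercises every pipeline
  stage with genuinely soft, imperfect probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .core import BACKGROUND, N_LAYERS, LayerMask, Raster
from .patching import PatchPair

__all__ = [
    "SegmentationBackend",
    "OracleBackend",
    "TextureBackend",
    "oracle_backend",
    "texture_backend",
]

#: Side of the square neighborhood over which texture features are pooled.
FEATURE_WINDOW = 15

#: Side of the fine neighborhood supplying the dark-blob reference tone; small
#: enough that a cell-cluster dot stands out against its own lamina rather
#: than against a neighboring band.
BLOB_REFERENCE_WINDOW = 7

#: A pixel darker than its fine local reference by this margin is blob material.
DARK_MARGIN = 15.0

#: Radius (px) of the structuring disk used to erase bright vessel holes, and
#: the white top-hat height above which a pixel counts as hole rather than
#: tissue.  The margin sits above the dot contrast of the tissue texture so
#: ordinary dark-dotted neuropil is never "repaired".
VESSEL_RADIUS = 5
VESSEL_MARGIN = 80.0


def _vessel_footprint(radius: int = VESSEL_RADIUS) -> np.ndarray:
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return dy * dy + dx * dx <= radius * radius


_FOOTPRINT = _vessel_footprint()


def _suppress_vessels(gray: np.ndarray) -> np.ndarray:
    """Replace bright vessel-hole pixels with their local neuropil tone.

    Grayscale opening gives a reference image with bright structures narrower
    than the footprint removed; pixels whose white top-hat (gray - opening)
    exceeds ``VESSEL_MARGIN`` are holes and take the opening's value.  This
    gives the patch classifier the 2D context a convolutional segmenter
    learns implicitly, and prevents hole-shaped islands in the output.
    """
    opened = ndimage.grey_opening(gray, footprint=_FOOTPRINT)
    return np.where(gray - opened > VESSEL_MARGIN, opened, gray)


@runtime_checkable
class SegmentationBackend(Protocol):
    """Interface: per-window layer probabilities.

    ``origin`` is the window's top-left corner in source-image coordinates;
    backends that classify from pixel content alone may ignore it.
    """

    def predict(self, feature: Raster, origin: tuple[int, int]) -> np.ndarray: ...


@dataclass
class OracleBackend:
    """One-hot ground truth restricted to the requested window.

    Windows overhanging the truth canvas (from symmetric padding of small
    inputs) are filled with background; a window entirely outside the truth
    is an error.
    """

    truth: LayerMask

    def predict(self, feature: Raster, origin: tuple[int, int]) -> np.ndarray:
        h, w = feature.shape
        r, c = origin
        th, tw = self.truth.shape
        if r + h <= 0 or c + w <= 0 or r >= th or c >= tw:
            raise ValueError(f"window at {origin} lies entirely outside the truth canvas")
        window = np.full((h, w), BACKGROUND, dtype=np.int64)
        r0, c0 = max(r, 0), max(c, 0)
        r1, c1 = min(r + h, th), min(c + w, tw)
        window[r0 - r : r1 - r, c0 - c : c1 - c] = np.asarray(self.truth.labels)[
            r0:r1, c0:c1
        ]
        return np.eye(N_LAYERS + 1, dtype=np.float64)[window][..., 1:]


def oracle_backend(truth: LayerMask) -> OracleBackend:
    return OracleBackend(truth)


N_FEATURES = 3


def _texture_features(gray: np.ndarray) -> np.ndarray:
    """Per-pixel texture features: local mean at two scales + dark-blob density.

    The fine (7x7) mean resolves thin laminae whose bands are narrower than
    the 15x15 pooling window; the coarse (15x15) mean supplies context; the
    dark-blob density counts pixels darker than their fine local reference by
    ``DARK_MARGIN``, pooled over the 15x15 neighborhood — a proxy for the
    layer's cell-cluster density.
    """
    gray = _suppress_vessels(gray)
    fine_mean = ndimage.uniform_filter(gray, size=BLOB_REFERENCE_WINDOW, mode="reflect")
    coarse_mean = ndimage.uniform_filter(gray, size=FEATURE_WINDOW, mode="reflect")
    dark = (gray < fine_mean - DARK_MARGIN).astype(np.float64)
    blob_density = ndimage.uniform_filter(dark, size=FEATURE_WINDOW, mode="reflect")
    return np.stack([fine_mean, coarse_mean, blob_density], axis=-1)


@dataclass
class TextureBackend:
    """Nearest-centroid texture classifier over 7 classes (background + 6 layers).

    ``centroids`` is (n_centroids, 2) in standardized feature space with
    ``centroid_class`` giving each centroid's label; ``k`` centroids per
    class (k-means sub-clusters when k > 1).  Scores are a softmax over the
    squared distance to each class's nearest centroid, so per-pixel layer
    probabilities sum to <= 1 with background as the residual.
    """

    centroids: np.ndarray
    centroid_class: np.ndarray
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    temperature: float = 1.0
    #: Gaussian sigma (px) for smoothing the per-class score maps; suppresses
    #: single-pixel speckle from texture noise while preserving band edges.
    smooth_sigma: float = 2.5

    def _class_scores(self, feats: np.ndarray) -> np.ndarray:
        z = (feats - self.feat_mean) / self.feat_scale
        d2 = ((z[..., None, :] - self.centroids) ** 2).sum(axis=-1)
        per_class = np.full(z.shape[:-1] + (N_LAYERS + 1,), np.inf)
        for cls in range(N_LAYERS + 1):
            sel = self.centroid_class == cls
            if sel.any():
                per_class[..., cls] = d2[..., sel].min(axis=-1)
        logits = -per_class / self.temperature
        logits -= logits.max(axis=-1, keepdims=True)
        expd = np.exp(logits)
        return expd / expd.sum(axis=-1, keepdims=True)

    def predict(self, feature: Raster, origin: tuple[int, int]) -> np.ndarray:
        probs = self._class_scores(_texture_features(feature.gray()))
        if self.smooth_sigma > 0:
            probs = ndimage.gaussian_filter(
                probs, sigma=(self.smooth_sigma, self.smooth_sigma, 0), mode="nearest"
            )
            probs /= np.maximum(probs.sum(axis=-1, keepdims=True), 1.0)
        return probs[..., 1:]


def texture_backend(
    training: list[PatchPair], k: int = 3, seed: int = 0
) -> TextureBackend:
    """Fit a :class:`TextureBackend` from training patch pairs.

    Raises if any of the six laminar labels never appears in the training
    masks.  Fitting is deterministic given ``seed``.
    """
    if not training:
        raise ValueError("training patch list is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    feats = []
    labels = []
    for pair in training:
        feats.append(_texture_features(pair.feature.gray()).reshape(-1, N_FEATURES))
        labels.append(np.asarray(pair.mask.labels).ravel())
    x = np.concatenate(feats)
    lab = np.concatenate(labels)
    present = set(np.unique(lab).tolist())
    missing = [cls for cls in range(1, N_LAYERS + 1) if cls not in present]
    if missing:
        raise ValueError(f"training patches lack layer label(s) {missing}")

    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - mean) / scale

    rng = np.random.default_rng(seed)
    centroids = []
    centroid_class = []
    for cls in sorted(present):
        zc = z[lab == cls]
        if len(zc) > 20000:  # cap the fit sample for speed, reproducibly
            zc = zc[rng.choice(len(zc), 20000, replace=False)]
        if k == 1 or len(zc) <= k:
            centroids.append(zc.mean(axis=0, keepdims=True))
            centroid_class.extend([cls])
        else:
            from sklearn.cluster import KMeans

            km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(zc)
            centroids.append(km.cluster_centers_)
            centroid_class.extend([cls] * k)
    return TextureBackend(
        centroids=np.concatenate(centroids),
        centroid_class=np.asarray(centroid_class),
        feat_mean=mean,
        feat_scale=scale,
    )
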