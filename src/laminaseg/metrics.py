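"""Overlap and surface-distance metrics for laminar segmentations.

Per layer k with ground-truth pixel set :math:`y_k` and prediction
:math:`\\hat y_k`:

* ``IoU  = |y ∩ ŷ| / |y ∪ ŷ|`` (Jaccard index),
* ``DSC  = (2|y ∩ ŷ| + 1) / (|y| + |ŷ| + 1)`` with the +1 smoothing term
  (disable via ``MetricsConfig(smoothing=False)`` for the classical Dice),
* recall ``TP/(TP+FN)`` and precision ``TP/(TP+FP)``.

Boundary distances use the directed nearest-point distance
``d(a, B) = min_b ||a - b||`` between the two layers' boundary point sets:
``HD`` is the max of the two directed maxima, ``AHD`` the mean of the two
directed means, ``HD95`` the max of the two directed 95th percentiles, and
``ASSD = (Σ_a d(a,B) + Σ_b d(b,A)) / (|A| + |B|)``.  All distances are
reported in micrometres.

The module also provides layer thickness (mean inner-to-outer contour
distance), anchor-based registration error, the acceptable-range rule for
region mapping, and an exact-small-sample Mann–Whitney U comparison between
pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import BACKGROUND, N_LAYERS, LayerMask, RegionOverlay, RegionTable

__all__ = [
    "MetricsConfig",
    "BoundaryPointSet",
    "MetricsReport",
    "AnchorPair",
    "RankSumResult",
    "overlap_metrics",
    "boundary_points",
    "distance_metrics",
    "layer_thickness",
    "evaluate",
    "anchor_error",
    "acceptable_range",
    "compare_pipelines",
]

#: Average auditory-cortex thickness threshold (um) for the mapping
#: acceptable-range rule, interpreted as the already-halved quantity.
DEFAULT_ACCEPTABLE_RANGE_UM = 1800.630


@dataclass(frozen=True)
class MetricsConfig:
    n_classes: int = N_LAYERS
    percentile: float = 95.0
    connectivity: int = 4
    smoothing: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.percentile <= 100):
            raise ValueError("percentile must lie in (0, 100]")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class BoundaryPointSet:
    """Pixel coordinates of a layer's boundary, with physical spacing."""

    points: np.ndarray  # (n, 2) int array of (row, col)
    spacing_um: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points))
        if self.points.shape[0] and self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class AnchorPair:
    """A matched landmark (vessel-hole center) before/after a mapping."""

    ref: tuple[float, float]
    moved: tuple[float, float]
    spacing_um: float = 1.0


@dataclass
class RankSumResult:
    u: float
    p_value: float
    method: str
    shapiro_p_a: float
    shapiro_p_b: float


@dataclass
class MetricsReport:
    """Per-layer (and optional per-region) metric table with layer means."""

    per_layer: pd.DataFrame
    means: dict[str, float]
    per_region: pd.DataFrame | None = None
    absent_layers: list[int] = field(default_factory=list)

    def to_csv(self, path) -> None:
        frames = [self.per_layer.assign(scope="layer")]
        if self.per_region is not None:
            frames.append(self.per_region.assign(scope="region"))
        pd.concat(frames).to_csv(path)

    def to_json(self, path) -> None:
        payload = {
            "per_layer": self.per_layer.to_dict(orient="index"),
            "means": self.means,
            "absent_layers": self.absent_layers,
        }
        if self.per_region is not None:
            payload["per_region"] = self.per_region.to_dict(orient="index")
        pd.Series(payload).to_json(path)


def overlap_metrics(
    y: LayerMask, yhat: LayerMask, cfg: MetricsConfig = MetricsConfig()
) -> dict:
    """Per-class and mean IoU / DSC / recall / precision.

    Classes absent from both masks are flagged and excluded from the means;
    means run over classes present in the ground truth.  No division by zero
    can occur: empty denominators report 0 (and the smoothed DSC is finite by
    construction).
    """
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    yl = np.asarray(y.labels)
    pl = np.asarray(yhat.labels)
    per_class: dict[int, dict] = {}
    for k in range(1, cfg.n_classes + 1):
        a = yl == k
        b = pl == k
        na, nb = int(a.sum()), int(b.sum())
        tp = int((a & b).sum())
        union = na + nb - tp
        if na == 0 and nb == 0:
            per_class[k] = {
                "iou": np.nan, "dsc": np.nan, "recall": np.nan,
                "precision": np.nan, "absent": True,
            }
            continue
        iou = tp / union if union else 0.0
        if cfg.smoothing:
            dsc = (2 * tp + 1) / (na + nb + 1)
        else:
            dsc = 2 * tp / (na + nb) if (na + nb) else 0.0
        per_class[k] = {
            "iou": iou,
            "dsc": dsc,
            "recall": tp / na if na else 0.0,
            "precision": tp / nb if nb else 0.0,
            "absent": False,
        }
    in_truth = [k for k in per_class if (yl == k).any()]
    means = {
        m: float(np.mean([per_class[k][m] for k in in_truth])) if in_truth else np.nan
        for m in ("iou", "dsc", "recall", "precision")
    }
    return {"per_class": per_class, "means": means}


def _connectivity_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def boundary_points(
    mask: LayerMask, layer: int, cfg: MetricsConfig = MetricsConfig()
) -> BoundaryPointSet:
    """Boundary pixels of a layer: members with a differing (4-)neighbor.

    Pixels on the canvas edge count as boundary (the outside is treated as a
    different label).
    """
    region = np.asarray(mask.labels) == layer
    if not region.any():
        raise ValueError(f"layer {layer} is absent from the mask")
    interior = ndimage.binary_erosion(
        region, structure=_connectivity_structure(cfg.connectivity), border_value=0
    )
    return BoundaryPointSet(np.argwhere(region & ~interior), mask.spacing_um)


def _directed(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distances from each src point to the dst set (pixels)."""
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return np.asarray(d, dtype=np.float64)


def distance_metrics(
    a: BoundaryPointSet, b: BoundaryPointSet, cfg: MetricsConfig = MetricsConfig()
) -> dict[str, float]:
    """Hausdorff-family boundary distances between two point sets, in um.

    Returns ``hd_um``, ``ahd_um`` (symmetrized mean of the two directed
    means; the directed values are exposed as ``ahd_ab_um`` / ``ahd_ba_um``),
    ``hd95_um`` (max of the two directed ``cfg.percentile`` percentiles,
    linear interpolation) and ``assd_um``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("boundary point sets must be non-empty")
    if a.spacing_um != b.spacing_um:
        raise ValueError("point sets must share spacing")
    s = a.spacing_um
    dab = _directed(a.points, b.points)
    dba = _directed(b.points, a.points)
    pct = cfg.percentile
    return {
        "hd_um": s * max(dab.max(), dba.max()),
        "ahd_um": s * float((dab.mean() + dba.mean()) / 2.0),
        "ahd_ab_um": s * float(dab.mean()),
        "ahd_ba_um": s * float(dba.mean()),
        "hd95_um": s * max(
            float(np.percentile(dab, pct)), float(np.percentile(dba, pct))
        ),
        "assd_um": s * float((dab.sum() + dba.sum()) / (len(a) + len(b))),
    }


def _side_points(labels: np.ndarray, layer: int, neighbor_label: int) -> np.ndarray:
    """Pixels of ``layer`` 4-adjacent (in canvas) to ``neighbor_label``."""
    labels = labels.astype(np.int16)  # room for the -1 out-of-canvas sentinel
    region = labels == layer
    adjacent = np.zeros_like(region)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(labels, shift, axis=axis)
        # invalidate wrap-around rows/cols
        if axis == 0:
            edge = 0 if shift == 1 else -1
            rolled[edge, :] = -1
        else:
            edge = 0 if shift == 1 else -1
            rolled[:, edge] = -1
        adjacent |= rolled == neighbor_label
    return np.argwhere(region & adjacent)


def layer_thickness(mask: LayerMask, layer: int) -> float:
    """Layer thickness in um: median inner-to-outer contour Euclidean distance.

    The layer's main body is its largest connected component; its bounding
    contours are the per-column extremal pixels of that body (so speckle
    islands and hole rims inside an imperfect prediction do not masquerade as
    contours).  Thickness is the median over columns of the distance between
    the two contours within that column, plus one pixel (a one-pixel band
    measures one pixel), scaled by the pixel spacing.  Pairing the contours
    column-by-column assumes the section crosses the laminae near-normally
    (the columnar geometry this whole workflow targets); a nearest-point
    distance would instead shortcut diagonally across contour jitter and
    systematically understate the thickness of an imperfect prediction, and
    the median keeps occasional mislabeled bumps from dominating.

    A layer without two distinct bounding contours — no pixel of its main
    body adjacent to the preceding side and to the following side (background
    for Layers I and VI) — is degenerate and raises.
    """
    labels = np.asarray(mask.labels)
    region = labels == layer
    if not region.any():
        raise ValueError(f"layer {layer} is absent from the mask")
    lab, n = ndimage.label(region, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(region, lab, index=np.arange(1, n + 1))
        region = lab == (1 + int(np.argmax(sizes)))

    prev_label = layer - 1 if layer > 1 else BACKGROUND
    next_label = layer + 1 if layer < N_LAYERS else BACKGROUND
    # keep all other labels; blank out only this layer's minor components
    body = np.where(region | (labels != layer), labels, -1)
    if (
        _side_points(body, layer, prev_label).shape[0] == 0
        or _side_points(body, layer, next_label).shape[0] == 0
    ):
        raise ValueError(f"layer {layer} does not have two distinct bounding contours")

    cols = np.flatnonzero(region.any(axis=0))
    top = np.argmax(region[:, cols], axis=0)
    bottom = region.shape[0] - 1 - np.argmax(region[::-1, cols], axis=0)
    d = (bottom - top).astype(np.float64)
    return float((np.median(d) + 1.0) * mask.spacing_um)


def _report_rows(
    y: LayerMask, yhat: LayerMask, cfg: MetricsConfig
) -> tuple[pd.DataFrame, list[int]]:
    ov = overlap_metrics(y, yhat, cfg)
    rows = {}
    absent: list[int] = []
    yl = np.asarray(y.labels)
    pl = np.asarray(yhat.labels)
    for k in range(1, cfg.n_classes + 1):
        row = {m: ov["per_class"][k][m] for m in ("iou", "dsc", "recall", "precision")}
        in_y, in_p = bool((yl == k).any()), bool((pl == k).any())
        if in_y and in_p:
            row.update(
                distance_metrics(
                    boundary_points(y, k, cfg), boundary_points(yhat, k, cfg), cfg
                )
            )
            try:
                row["thickness_um"] = layer_thickness(yhat, k)
            except ValueError:
                row["thickness_um"] = np.nan
        else:
            if not in_y and not in_p:
                absent.append(k)
            for key in ("hd_um", "ahd_um", "ahd_ab_um", "ahd_ba_um", "hd95_um", "assd_um",
                        "thickness_um"):
                row[key] = np.nan
        rows[k] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "layer"
    return frame, absent


def evaluate(
    y: LayerMask,
    yhat: LayerMask,
    regions: RegionOverlay | None = None,
    cfg: MetricsConfig = MetricsConfig(),
    region_table: RegionTable | None = None,
) -> MetricsReport:
    """Full per-layer report, optionally broken out per brain region.

    Region rows restrict both masks to the region's support before computing
    the same metrics.  Means are unweighted averages over layers present in
    the ground truth (undefined entries are skipped); layers absent from both
    masks are listed in ``absent_layers``.
    """
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    per_layer, absent = _report_rows(y, yhat, cfg)
    means = {
        col: float(np.nanmean(vals))
        for col, vals in per_layer.items()
        if np.isfinite(vals).any()
    }
    per_region = None
    if regions is not None:
        if regions.shape != y.shape:
            raise ValueError("region overlay shape mismatch")
        region_rows = {}
        for rid in np.unique(regions.ids):
            if rid == 0:
                continue
            support = regions.ids == rid
            ymask = LayerMask(np.where(support, y.labels, 0).astype(y.labels.dtype),
                              y.spacing_um)
            pmask = LayerMask(np.where(support, yhat.labels, 0).astype(yhat.labels.dtype),
                              yhat.spacing_um)
            sub, _ = _report_rows(ymask, pmask, cfg)
            key = (
                region_table.abbreviation_for(int(rid))
                if region_table is not None
                else str(int(rid))
            )
            region_rows[key] = sub.mean(axis=0, skipna=True)
        per_region = pd.DataFrame.from_dict(region_rows, orient="index")
        per_region.index.name = "region"
    return MetricsReport(
        per_layer=per_layer, means=means, per_region=per_region, absent_layers=absent
    )


def anchor_error(pairs: list[AnchorPair]) -> tuple[float, float]:
    """Mean and sample SD (um) of the Euclidean shift across anchor pairs.

    The SD of a single pair is defined as 0.
    """
    if not pairs:
        raise ValueError("need at least one anchor pair")
    dists = np.array(
        [
            np.hypot(p.ref[0] - p.moved[0], p.ref[1] - p.moved[1]) * p.spacing_um
            for p in pairs
        ]
    )
    sd = float(dists.std(ddof=1)) if len(dists) > 1 else 0.0
    return float(dists.mean()), sd


def acceptable_range(
    mean_error_um: float,
    avg_cortex_thickness_um: float = DEFAULT_ACCEPTABLE_RANGE_UM,
    halved: bool = True,
) -> bool:
    """Is a mean mapping error acceptable relative to cortex thickness?

    The rule compares the error against half the average cortex thickness.
    By default (``halved=True``) the supplied value is taken to already be
    that half-distance threshold; with ``halved=False`` it is divided by two
    first.  The comparison is inclusive.
    """
    if mean_error_um < 0 or avg_cortex_thickness_um <= 0:
        raise ValueError("inputs must be positive")
    threshold = avg_cortex_thickness_um if halved else avg_cortex_thickness_um / 2.0
    return mean_error_um <= threshold


def compare_pipelines(
    scores_a: list[float], scores_b: list[float]
) -> RankSumResult:
    """Two-sided Mann–Whitney U comparison of two score samples.

    Uses the exact null distribution for combined n <= 20 without ties and
    the tie-corrected normal approximation otherwise.  Shapiro–Wilk
    normality p-values for each sample are reported alongside but never
    change which test is run.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    shap_a = float(stats.shapiro(a).pvalue) if np.ptp(a) > 0 else np.nan
    shap_b = float(stats.shapiro(b).pvalue) if np.ptp(b) > 0 else np.nan
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:  # every observation identical: no evidence at all
        return RankSumResult(
            u=len(a) * len(b) / 2.0, p_value=1.0, method="degenerate",
            shapiro_p_a=shap_a, shapiro_p_b=shap_b,
        )
    has_ties = np.unique(combined).size < combined.size
    if len(combined) <= 20 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return RankSumResult(
        u=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        shapiro_p_a=shap_a,
        shapiro_p_b=shap_b,
    )
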