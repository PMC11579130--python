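"""Seeded six-layer cortex phantoms for end-to-end pipeline testing.

The generator emulates down-sampled (~9.2 um/px) Nissl-stained cortex, where
individual cell bodies no longer resolve and laminae differ by texture: each
layer is rendered as a neuropil tone (cell-dense laminae read darker) carrying
a homogeneous Poisson process of dark "cell cluster" dots with layer-specific
density and radius, plus white blood-vessel holes.  Layer thickness defaults
follow measured marmoset auditory-cortex values.  The ribbon is a horizontal
band with optional sinusoidal curvature, so the ground truth stays analytic:
scanning down any column crosses background, Layers I..VI in order, then
background again.

Every phantom is bit-reproducible from its config's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import ConfigError, LayerMask, Raster

__all__ = ["PhantomConfig", "Phantom", "generate_phantom", "perturb_mask"]

#: Default per-layer thickness in micrometres, Layers I..VI.
DEFAULT_THICKNESS_UM = (92.200, 80.620, 247.390, 186.820, 338.380, 177.200)

#: Dots per 100x100 px, Layers I..VI.  Adjacent layers differ by >= 2x except
#: the II/III pair (1.3x), mimicking the smoother II->III transition that makes
#: that boundary the hard case on real tissue.
DEFAULT_DOT_DENSITY = (20.0, 400.0, 300.0, 600.0, 60.0, 150.0)

#: Dot radius in px, Layers I..VI (Layer V carries larger pyramidal-cell blobs).
DEFAULT_DOT_RADIUS = (1, 1, 1, 1, 2, 1)

#: Neuropil base tone per layer, graded monotonically from the pale pial
#: surface toward the darker white-matter side.  Monotone tones keep every
#: inter-layer transition's intensity path clear of third classes, so texture
#: classifiers degrade gracefully at band edges; the II/III step is the
#: smallest, making that boundary the hard case, as on real tissue.
DEFAULT_BASE_INTENSITY = (222, 192, 172, 138, 105, 70)


@dataclass
class PhantomConfig:
    """Parameters of one synthetic cortex section.

    ``dot_density`` is in dots per 100x100 px; ``ribbon_curvature`` is the
    amplitude (px) of a sinusoidal vertical displacement of the whole ribbon
    (0 = straight horizontal band); ``vessel_radius_px`` is an inclusive
    integer range.
    """

    canvas: tuple[int, int] = (192, 320)
    spacing_um: float = 9.2
    layer_thickness_um: tuple[float, ...] = DEFAULT_THICKNESS_UM
    dot_density: tuple[float, ...] = DEFAULT_DOT_DENSITY
    dot_radius_px: tuple[int, ...] = DEFAULT_DOT_RADIUS
    base_intensity: tuple[int, ...] = DEFAULT_BASE_INTENSITY
    background_intensity: int = 240
    dot_contrast: int = 60
    noise_sigma: float = 3.0
    ribbon_curvature: float = 0.0
    vessel_count: int = 6
    vessel_radius_px: tuple[int, int] = (2, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("layer_thickness_um", "dot_density", "dot_radius_px", "base_intensity"):
            vals = tuple(getattr(self, name))
            setattr(self, name, vals)
            if len(vals) != 6:
                raise ConfigError(f"{name} must have 6 entries, got {len(vals)}")
        if any(t <= 0 for t in self.layer_thickness_um):
            raise ConfigError("layer thicknesses must be > 0")
        if any(d < 0 for d in self.dot_density):
            raise ConfigError("dot densities must be >= 0")
        if self.spacing_um <= 0:
            raise ConfigError("spacing_um must be > 0")
        if self.ribbon_curvature < 0:
            raise ConfigError("ribbon_curvature must be >= 0")
        if self.vessel_count < 0:
            raise ConfigError("vessel_count must be >= 0")
        h, _ = self.canvas
        if sum(self.band_heights_px()) + 2 * int(np.ceil(self.ribbon_curvature)) > h:
            raise ConfigError(
                f"layer thicknesses ({sum(self.band_heights_px())} px) plus curvature "
                f"do not fit the canvas height ({h} px)"
            )

    def band_heights_px(self) -> list[int]:
        """Per-layer band height in pixels: round(thickness_um / spacing_um)."""
        return [int(round(t / self.spacing_um)) for t in self.layer_thickness_um]

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("canvas", "vessel_radius_px", "layer_thickness_um", "dot_density",
                    "dot_radius_px", "base_intensity"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Phantom:
    """A generated section: intensity image, ground-truth mask, vessel record."""

    image: Raster
    truth: LayerMask
    vessels: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def vessel_centers(self) -> list[tuple[int, int]]:
        return [(r, c) for r, c, _ in self.vessels]


def _column_offsets(curvature: float, width: int) -> np.ndarray:
    """Integer vertical ribbon displacement per column (single sine period)."""
    if curvature == 0:
        return np.zeros(width, dtype=np.int64)
    cols = np.arange(width)
    return np.round(curvature * np.sin(2 * np.pi * cols / width)).astype(np.int64)


def _band_truth(cfg: PhantomConfig) -> np.ndarray:
    """Label grid: contiguous Layer I..VI bands along each column."""
    h, w = cfg.canvas
    heights = cfg.band_heights_px()
    total = sum(heights)
    top = (h - total) // 2
    edges = top + np.concatenate([[0], np.cumsum(heights)])  # 7 band edges
    off = _column_offsets(cfg.ribbon_curvature, w)
    rows = np.arange(h)[:, None] - off[None, :]
    # searchsorted over edges: 0 above ribbon, 1..6 inside, 7 below -> 0
    idx = np.searchsorted(edges, rows, side="right")
    labels = np.where((idx >= 1) & (idx <= 6), idx, 0)
    return labels.astype(np.uint8)


def _disk_offsets(radius: int) -> np.ndarray:
    """Pixel offsets of a Euclidean disk of the given integer radius."""
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy * dy + dx * dx <= r * r
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp_disks(
    grid: np.ndarray, centers: np.ndarray, radius: int
) -> None:
    """Mark disks of ``radius`` at ``centers`` (n, 2) into a boolean grid, clipped."""
    if centers.size == 0:
        return
    offs = _disk_offsets(radius)
    pts = centers[:, None, :] + offs[None, :, :]
    pts = pts.reshape(-1, 2)
    h, w = grid.shape
    ok = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[ok]
    grid[pts[:, 0], pts[:, 1]] = True


def generate_phantom(cfg: PhantomConfig) -> Phantom:
    """Render a phantom section from its config; deterministic given the seed."""
    h, w = cfg.canvas
    truth = _band_truth(cfg)

    root = np.random.SeedSequence(cfg.seed)
    ss_dots, ss_vessels, ss_noise = root.spawn(3)

    image = np.full((h, w), float(cfg.background_intensity))
    for layer in range(1, 7):
        image[truth == layer] = float(cfg.base_intensity[layer - 1])

    # Layer-specific Poisson dot texture, darkening the local tone.
    rng_dots = np.random.default_rng(ss_dots)
    dot_mask = np.zeros((h, w), dtype=bool)
    for layer in range(1, 7):
        coords = np.argwhere(truth == layer)
        if coords.size == 0:
            continue
        rate = cfg.dot_density[layer - 1] * coords.shape[0] / 1e4
        count = int(rng_dots.poisson(rate))
        if count == 0:
            continue
        pick = rng_dots.integers(0, coords.shape[0], size=count)
        layer_dots = np.zeros_like(dot_mask)
        _stamp_disks(layer_dots, coords[pick], cfg.dot_radius_px[layer - 1])
        # cell bodies belong to their lamina: clip disks at the band edge so
        # the rendered texture transition coincides with the label boundary
        dot_mask |= layer_dots & (truth == layer)
    image = np.where(dot_mask, image - cfg.dot_contrast, image)

    if cfg.noise_sigma > 0:
        rng_noise = np.random.default_rng(ss_noise)
        image = image + rng_noise.normal(0.0, cfg.noise_sigma, size=image.shape)

    image = np.clip(image, 0.0, 254.0)  # keep 255 exclusive to vessel holes

    # White vessel holes inside the ribbon.
    vessels: list[tuple[int, int, int]] = []
    if cfg.vessel_count > 0:
        rng_ves = np.random.default_rng(ss_vessels)
        ribbon = np.argwhere(truth > 0)
        lo, hi = cfg.vessel_radius_px
        for _ in range(cfg.vessel_count):
            r, c = ribbon[rng_ves.integers(0, ribbon.shape[0])]
            radius = int(rng_ves.integers(lo, hi + 1))
            hole = np.zeros((h, w), dtype=bool)
            _stamp_disks(hole, np.array([[r, c]]), radius)
            image[hole] = 255.0
            vessels.append((int(r), int(c), radius))

    return Phantom(
        image=Raster(np.round(image).astype(np.uint8), cfg.spacing_um, name=f"phantom-{cfg.seed}"),
        truth=LayerMask(truth, cfg.spacing_um),
        vessels=vessels,
    )


def write_vessel_csv(phantom: Phantom, path: str | Path) -> None:
    """Write vessel centers as CSV ``row,col,radius_px``."""
    lines = ["row,col,radius_px"]
    lines += [f"{r},{c},{rad}" for r, c, rad in phantom.vessels]
    Path(path).write_text("\n".join(lines) + "\n")


def _smooth_profile(rng: np.random.Generator, width: int) -> np.ndarray:
    """Random smooth curve over columns, normalised to max |value| = 1."""
    cols = np.arange(width)
    prof = np.zeros(width)
    for _ in range(3):
        freq = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0)
        prof += amp * np.sin(2 * np.pi * freq * cols / width + phase)
    peak = np.abs(prof).max()
    return prof / peak if peak > 0 else prof


def perturb_mask(truth: LayerMask, shift_px: int, seed: int) -> LayerMask:
    """Displace each inter-layer boundary by a smooth random offset <= shift_px.

    Produces an imperfect "prediction" with a known worst-case boundary
    displacement, for exercising the distance metrics.  The label set is
    preserved: boundaries are kept ordered so no band collapses to nothing.
    """
    if shift_px < 0:
        raise ValueError("shift_px must be >= 0")
    labels = np.asarray(truth.labels)
    if shift_px == 0:
        return LayerMask(labels.copy(), truth.spacing_um)

    h, w = labels.shape
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # Per-column band edges: edge[j][c] = first row of band j (bg->1, 1->2, ... 6->bg).
    inside = labels > 0
    top = np.argmax(inside, axis=0)  # first ribbon row per column
    edges = np.empty((7, w), dtype=np.int64)
    cum = top.copy()
    for j in range(6):
        edges[j] = cum
        cum = cum + (labels == j + 1).sum(axis=0)
    edges[6] = cum  # one past Layer VI

    new_edges = edges.copy()
    for j in range(7):
        offset = np.round(shift_px * _smooth_profile(rng, w)).astype(np.int64)
        new_edges[j] = edges[j] + offset
    # Keep edges strictly ordered so every layer retains >= 1 px per column.
    for j in range(1, 7):
        new_edges[j] = np.maximum(new_edges[j], new_edges[j - 1] + 1)
    new_edges = np.clip(new_edges, 0, h)

    rows = np.arange(h)[:, None]
    idx = np.zeros((h, w), dtype=np.uint8)
    for j in range(6):
        band = (rows >= new_edges[j][None, :]) & (rows < new_edges[j + 1][None, :])
        idx[band] = j + 1
    idx[:, ~inside.any(axis=0)] = 0  # columns with no ribbon stay background
    return LayerMask(idx, truth.spacing_um)
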