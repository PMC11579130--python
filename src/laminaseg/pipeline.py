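"""End-to-end orchestration: mask -> patches -> predict -> stitch -> evaluate.

``run_pipeline`` wires the stages together: the cortex mask is applied to the
image, the unfiltered overlapping patch grid is predicted by the configured
backend, predictions are averaged into per-layer heatmaps, adaptively
thresholded, merged by argmax, and pixels outside the cortex mask are forced
to background.  The whole path is deterministic given the config seed and a
deterministic backend.

``nested_cv_plan`` emits the rotation schedule for nested cross-validation
over whole-brain datasets (each brain is the test set exactly once; the inner
folds rotate the validation brain over the remainder).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import ConfigError, LayerMask, Raster
from .patching import FilterCriteria, PatchGridSpec, make_patch_grid, pad_to_window
from .regions import apply_cortex_mask
from .stitching import PatchPrediction, accumulate, merge_layers, threshold_stack
from .backends import SegmentationBackend

logger = logging.getLogger("laminaseg.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "nested_cv_plan"]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a pipeline run."""

    grid: PatchGridSpec = field(default_factory=PatchGridSpec)
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    threshold_method: str = "adaptive"
    tile: int = 256
    backend: str = "texture"
    backend_params: dict = field(default_factory=dict)
    seed: int = 0
    spacing_um: float = 9.2

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if isinstance(data.get("grid"), dict):
            data["grid"] = PatchGridSpec(**data["grid"])
        if isinstance(data.get("filter"), dict):
            data["filter"] = FilterCriteria(**data["filter"])
        return cls(**data)

    def apply_overrides(self, overrides: dict[str, str]) -> "PipelineConfig":
        """Return a copy with dotted ``key=value`` overrides applied."""
        data = asdict(self)
        for key, raw in overrides.items():
            parts = key.split(".")
            node = data
            for part in parts[:-1]:
                if part not in node:
                    raise ConfigError(f"unknown config key {key!r}")
                node = node[part]
            if parts[-1] not in node:
                raise ConfigError(f"unknown config key {key!r}")
            node[parts[-1]] = yaml.safe_load(raw)
        return PipelineConfig.from_dict(data)


def run_pipeline(
    img: Raster,
    cortex_mask: np.ndarray | None,
    cfg: PipelineConfig,
    backend: SegmentationBackend,
) -> LayerMask:
    """Segment a section into laminar labels 0–6.

    Inference patches are never filtered (stitching needs full coverage).
    Output pixels outside ``cortex_mask`` are background; no label outside
    0–6 can be produced.
    """
    if cortex_mask is not None:
        cortex_mask = np.asarray(cortex_mask).astype(bool)
        if cortex_mask.shape != img.shape:
            raise ValueError(
                f"pipeline/mask: cortex mask shape {cortex_mask.shape} "
                f"!= image shape {img.shape}"
            )
        img = apply_cortex_mask(img, cortex_mask)

    orig_shape = img.shape
    padded, _, (pad_top, pad_left) = pad_to_window(img, None, cfg.grid.window)
    origins = make_patch_grid(padded.shape, cfg.grid)
    logger.info("pipeline/patch: %d inference windows (%dpx / stride %dpx)",
                len(origins), cfg.grid.window, cfg.grid.stride)

    pixels = np.asarray(padded.pixels)
    wdw = cfg.grid.window
    preds = []
    for r, c in origins:
        window = Raster(
            pixels[r : r + wdw, c : c + wdw], padded.spacing_um, name=padded.name
        )
        probs = backend.predict(window, (r - pad_top, c - pad_left))
        preds.append(PatchPrediction(origin=(r, c), probs=probs))

    stack = accumulate(preds, padded.shape)
    logger.info("pipeline/stitch: coverage %d-%d windows/pixel",
                int(stack.coverage.min()), int(stack.coverage.max()))
    stack = threshold_stack(stack, method=cfg.threshold_method, tile=cfg.tile)
    merged = merge_layers(stack, spacing_um=img.spacing_um)

    labels = np.asarray(merged.labels)[
        pad_top : pad_top + orig_shape[0], pad_left : pad_left + orig_shape[1]
    ]
    if cortex_mask is not None:
        labels = np.where(cortex_mask, labels, 0).astype(np.uint8)
    logger.info("pipeline/merge: %d labeled pixels", int((labels > 0).sum()))
    return LayerMask(labels.astype(np.uint8), img.spacing_um)


def nested_cv_plan(brains: list[str]) -> list[dict]:
    """Rotation schedule for nested cross-validation over whole datasets.

    Each dataset is the test set in exactly one outer fold (rotating from the
    last name to the first); within an outer fold, every remaining dataset
    takes one turn as the validation set while the rest train.  The best
    inner model by validation score is then applied to the test set —
    executing the training itself is delegated to the configured backend.
    """
    names = list(brains)
    if len(names) < 3:
        raise ValueError("nested cross-validation needs at least 3 datasets")
    if len(set(names)) != len(names):
        raise ValueError("dataset names must be unique")
    plan = []
    for i in range(len(names)):
        test = names[len(names) - 1 - i]
        rest = [n for n in names if n != test]
        inner = [
            {"train": [n for n in rest if n != val], "val": val} for val in rest
        ]
        plan.append({"outer_fold": i, "test": test, "inner": inner})
    return plan
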