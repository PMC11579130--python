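"""Shared fixtures: phantoms, a trained texture backend, and the small grid.

Session-scoped where construction is expensive, so the whole suite reuses one
trained backend.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")

from laminaseg import (
    FilterCriteria,
    PatchGridSpec,
    PhantomConfig,
    PipelineConfig,
    apply_cortex_mask,
    extract_patches,
    generate_phantom,
    texture_backend,
)

#: Window/stride used throughout the tests: the window (128 px) exceeds the
#: ribbon height (122 px) so most patches can contain all six laminae, while
#: keeping runtimes in seconds.
TEST_GRID = PatchGridSpec(window=128, stride=32)

TRAIN_SEED = 1
HELD_SEED = 2


@pytest.fixture(scope="session")
def train_phantom():
    return generate_phantom(PhantomConfig(seed=TRAIN_SEED))


@pytest.fixture(scope="session")
def held_phantom():
    return generate_phantom(PhantomConfig(seed=HELD_SEED))


@pytest.fixture(scope="session")
def training_patches(train_phantom):
    masked = apply_cortex_mask(train_phantom.image, train_phantom.truth.labels > 0)
    return extract_patches(masked, train_phantom.truth, TEST_GRID, FilterCriteria())


@pytest.fixture(scope="session")
def trained_backend(training_patches):
    return texture_backend(training_patches, k=3, seed=0)


@pytest.fixture()
def pipeline_config():
    return PipelineConfig(grid=TEST_GRID, spacing_um=9.2)


def random_blob_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """Random contiguous-ish label field with values 0..6 for metric tests."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=4.0)
    edges = np.quantile(field, np.linspace(0, 1, 8)[1:-1])
    return np.digitize(field, edges).astype(np.uint8)
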