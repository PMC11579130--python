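"""Cut the overlapping patch grid and see what the training filter rejects.

Patches must contain all six laminae (>= 5 px each) and be bright enough
(mean intensity > 10); everything else is dropped from a training set.
At inference no filter is applied, so stitching sees full coverage.
"""

from collections import Counter

from laminaseg import (
    FilterCriteria,
    PatchGridSpec,
    PhantomConfig,
    extract_patches,
    generate_phantom,
    make_patch_grid,
    passes_filter,
)
from laminaseg.patching import PatchPair
from laminaseg.core import Raster, LayerMask
import numpy as np

phantom = generate_phantom(PhantomConfig(seed=1))
grid = PatchGridSpec(window=128, stride=32)
criteria = FilterCriteria()

origins = make_patch_grid(phantom.image.shape, grid)
pixels = np.asarray(phantom.image.pixels)
labels = np.asarray(phantom.truth.labels)
reasons = Counter()
for r, c in origins:
    pair = PatchPair((r, c),
                     Raster(pixels[r:r+128, c:c+128], 9.2),
                     LayerMask(labels[r:r+128, c:c+128], 9.2))
    reasons[passes_filter(pair, criteria)[1]] += 1

kept = extract_patches(phantom.image, phantom.truth, grid, criteria)
print(f"grid: {len(origins)} windows ({grid.window}px window, {grid.stride}px stride)")
print(f"kept for training: {len(kept)}")
print(f"verdicts: {dict(reasons)}")
# Windows near the top/bottom of the canvas miss the deepest or most
# superficial laminae and are rejected with reason 'missing_layer'.
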