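"""Detection of non-neuropil "holes" (somata, vessels, section artifacts).

Holes appear as large, nearly black regions in the stacks.  They are found by
inverting the normalized gray scale, smoothing each slice with a large-radius
median filter, and thresholding: pixels whose filtered inverted intensity is
at least ``holes_thr`` are holes (value 1), the rest is neuropil (value 0).
The binary holes stack is then projected by summing along z, giving a compact
2D mask whose pixels count in how many slices that column is non-neuropil.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import median as _median_filter
from skimage.morphology import disk

from .core import HolesMask, ImageStack

logger = logging.getLogger(__name__)


def detect_holes(
    stack: ImageStack, holes_thr: float = 0.9, median_radius: int = 10
) -> np.ndarray:
    """Binary 3D holes stack (1 = non-neuropil) from the raw image stack.

    Intensities are normalized to [0, 1] by the stack-wide maximum (holes span
    slices, so per-slice normalization would shift the threshold meaning),
    inverted, median-filtered per slice with a disk of ``median_radius``
    pixels, and thresholded at ``holes_thr`` (inclusive).
    """
    if not (0.0 <= holes_thr <= 1.0):
        raise ValueError("holes_thr must lie in [0, 1]")
    data = stack.data
    peak = float(data.max())
    if peak == 0:
        logger.warning("all-zero stack: every voxel classified as hole")
        return np.ones(data.shape, dtype=np.uint8)
    # Work on an 8-bit inverted image so the rank-based median filter is fast;
    # the half-gray-level quantization error is negligible at these radii.
    inverted = np.round((1.0 - data / peak) * 255.0).astype(np.uint8)
    footprint = disk(median_radius)
    holes = np.empty(data.shape, dtype=np.uint8)
    cutoff = holes_thr * 255.0
    for z in range(data.shape[0]):
        filtered = _median_filter(inverted[z], footprint)
        holes[z] = (filtered >= cutoff).astype(np.uint8)
    return holes


def project_holes(
    holes_stack: np.ndarray, pixel_size_xy: float = 1.0, z_step: float = 1.0
) -> HolesMask:
    """Sum the binary holes stack along z into a 2D :class:`HolesMask`."""
    holes_stack = np.asarray(holes_stack)
    if not np.isin(holes_stack, (0, 1)).all():
        raise ValueError("holes stack must be binary")
    counts = holes_stack.sum(axis=0).astype(np.int64)
    return HolesMask(
        counts=counts,
        n_slices=holes_stack.shape[0],
        pixel_size_xy=pixel_size_xy,
        z_step=z_step,
    )
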