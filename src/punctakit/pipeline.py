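"""End-to-end object detection pipeline.

The raw stack is conceptually duplicated: one copy is segmented (MaxLoGs +
automatic threshold -> binary mask), the other is median-denoised; the two
branches are independent and fused by pixel-wise minimum.  The fused stack is
then tagged slice by slice, objects are connected across slices by the
Bhattacharyya criterion, undersized objects are dissolved, and every
surviving object is measured.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_EXCLUSION_FACES,
    DetectionParams,
    ImageStack,
    LabelStack,
    PunctumRecord,
)
from . import segmentation, tagging

logger = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    """Labels, measured objects and optional intermediate images."""

    labels: LabelStack
    records: list[PunctumRecord]
    threshold: float
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return len(self.records)


def detect(
    stack: ImageStack,
    params: DetectionParams | None = None,
    exclusion_faces: Sequence[str] = DEFAULT_EXCLUSION_FACES,
    keep_intermediates: bool = False,
) -> DetectionResult:
    """Run segmentation, fusion, tagging, size checking and measurement."""
    params = params or DetectionParams()

    t0 = time.perf_counter()
    mask, threshold, response = segmentation.segment(
        stack, params.r_min, params.r_max, params.delta_step, params.thr_method
    )
    logger.info(
        "segmentation: threshold=%.4g, foreground=%.2f%% (%.1fs)",
        threshold,
        100.0 * mask.mean(),
        time.perf_counter() - t0,
    )

    t0 = time.perf_counter()
    denoised = segmentation.median_denoise(stack)
    fused = segmentation.fuse(mask, denoised)
    logger.info("denoise + fuse (%.1fs)", time.perf_counter() - t0)

    t0 = time.perf_counter()
    slice_labels = [
        tagging.slice_tagging(fused.data[z], params.toll, params.connectivity)
        for z in range(stack.n_slices)
    ]
    labels = tagging.connect_slices(slice_labels, fused, params.phi)
    n_before = int((np.unique(labels) > 0).sum())
    labels = tagging.size_check(labels, params.min_size)
    records = tagging.measure(
        labels, stack.pixel_size_xy, stack.z_step, exclusion_faces
    )
    logger.info(
        "tagging: %d objects (%d before size check) (%.1fs)",
        len(records),
        n_before,
        time.perf_counter() - t0,
    )

    result = DetectionResult(
        labels=LabelStack(labels, stack.pixel_size_xy, stack.z_step),
        records=records,
        threshold=threshold,
    )
    if keep_intermediates:
        result.intermediates = {
            "response": response,
            "mask": mask.astype(np.uint8),
            "denoised": denoised.data,
            "fused": fused.data,
        }
    return result
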