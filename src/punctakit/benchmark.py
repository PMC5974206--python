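"""Seeded end-to-end recovery benchmarks on synthetic stacks.

These routines generate a ground-truthed synthetic stack, run the full
detection (and, where relevant, holes) pipeline with the default parameters,
and score the result against the planted truth.  They back both the test
suite and the reproduction script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DetectionParams, RoiPolygon
from .density import density as estimate_density
from .holes import detect_holes, project_holes
from .pipeline import detect
from .synthetic import SyntheticSpec, generate
from .validation import match_points

logger = logging.getLogger(__name__)


@dataclass
class RecoveryResult:
    """Scores of one puncta-recovery run."""

    n_planted: int
    n_detected: int
    precision: float
    recall: float
    centroid_rmse_px: float
    d_per_um3: float
    dn_per_um3: float | None
    planted_density_per_um3: float


def full_frame_roi(n_y: int, n_x: int) -> RoiPolygon:
    """Rectangle covering every pixel center of an ``n_y x n_x`` frame."""
    return RoiPolygon(
        np.array(
            [
                (-0.5, -0.5),
                (n_x - 0.5, -0.5),
                (n_x - 0.5, n_y - 0.5),
                (-0.5, n_y - 0.5),
            ]
        )
    )


def _centroid_rmse(labels: np.ndarray, records, truth) -> float:
    """RMS distance (pixel units; z in slices) between planted centers and the
    centroids of the objects they fall in."""
    by_tag = {r.tag: np.array(r.centroid_px) for r in records}
    sq = []
    for p in truth:
        x, y, z = p.center_xyz
        tag = int(labels[int(round(z)), int(round(y)), int(round(x))])
        if tag in by_tag:
            sq.append(((by_tag[tag] - np.array([x, y, z])) ** 2).sum())
    if not sq:
        return float("nan")
    return float(np.sqrt(np.mean(sq)))


def run_puncta_recovery(
    seed: int,
    shape: tuple[int, int, int] = (15, 512, 512),
    n_puncta: int = 150,
    params: DetectionParams | None = None,
) -> RecoveryResult:
    """Plant Gaussian puncta, detect with default parameters, and score.

    Precision/recall treat the planted centers as expert points (a planted
    punctum is recovered when its center lies inside a detected object, one
    to one); the density is measured over a full-frame ROI and compared with
    the planted ``n_puncta / V``.
    """
    params = params or DetectionParams()
    spec = SyntheticSpec(shape=shape, n_puncta=n_puncta, seed=seed)
    truth = generate(spec)
    result = detect(truth.stack, params)

    centers = np.array([p.center_xyz for p in truth.puncta])
    match = match_points(result.labels, centers)
    rmse = _centroid_rmse(result.labels.labels, result.records, truth.puncta)

    roi = full_frame_roi(shape[1], shape[2])
    report = estimate_density(
        result.records,
        roi,
        n_slices=shape[0],
        pixel_size_xy=spec.pixel_size_xy,
        z_step=spec.z_step,
    )
    planted = n_puncta / report.volume_um3
    return RecoveryResult(
        n_planted=n_puncta,
        n_detected=match.n_algorithm,
        precision=match.precision,
        recall=match.recall,
        centroid_rmse_px=rmse,
        d_per_um3=report.d,
        dn_per_um3=report.dn,
        planted_density_per_um3=planted,
    )


@dataclass
class HoleRecoveryResult:
    """Scores of one hole-corrected density run."""

    hole_fraction_true: float
    hole_fraction_estimated: float
    d_per_um3: float
    dn_per_um3: float
    planted_neuropil_density_per_um3: float
    d_over_dn: float
    dn_over_planted: float


def run_hole_recovery(
    seed: int,
    shape: tuple[int, int, int] = (15, 512, 512),
    n_puncta: int = 120,
    hole_fraction: float = 0.25,
    params: DetectionParams | None = None,
) -> HoleRecoveryResult:
    """Plant a dark cylinder and puncta in the neuropil; compare d and dn.

    The cylinder's cross-section occupies ``hole_fraction`` of the frame, so
    the raw density d underestimates the neuropil density by that fraction
    while the hole-corrected dn should recover it.
    """
    params = params or DetectionParams()
    n_z, n_y, n_x = shape
    hole_radius = float(np.sqrt(hole_fraction * n_y * n_x / np.pi))
    spec = SyntheticSpec(
        shape=shape,
        n_puncta=n_puncta,
        n_holes=1,
        hole_radius_range=(hole_radius, hole_radius),
        seed=seed,
    )
    truth = generate(spec)
    result = detect(truth.stack, params)

    holes_stack = detect_holes(
        truth.stack, params.holes_thr, params.holes_median_radius
    )
    mask = project_holes(holes_stack, spec.pixel_size_xy, spec.z_step)

    roi = full_frame_roi(n_y, n_x)
    report = estimate_density(result.records, roi, mask)
    if report.dn is None:
        raise RuntimeError("holes cover the whole frame; dn undefined")
    true_hole_um3 = sum(h.volume_um3 for h in truth.holes)
    planted = n_puncta / (report.volume_um3 - true_hole_um3)
    return HoleRecoveryResult(
        hole_fraction_true=true_hole_um3 / report.volume_um3,
        hole_fraction_estimated=report.holes_um3 / report.volume_um3,
        d_per_um3=report.d,
        dn_per_um3=report.dn,
        planted_neuropil_density_per_um3=planted,
        d_over_dn=report.d / report.dn,
        dn_over_planted=report.dn / planted,
    )
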