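"""Stereological volume-number-density estimation in ROI-defined prisms.

Measurement volumes are prisms: a 2D polygon ``R`` in the x-y plane extruded
through the full stack depth ``delta = n_slices * z_step``.  The density of
puncta in the prism is

    d(R) = N_s(R) / V(R),          V(R) = A(R) * delta,

where ``N_s(R)`` counts centroids of objects not touching the exclusion
borders that fall strictly inside ``R``, and ``A(R)`` is the polygon area.
The neuropil density additionally subtracts the hole volume ``H(R)`` (sum of
the holes-mask values inside ``R`` times the voxel volume):

    dn(R) = N_s(R) / (V(R) - H(R)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .core import HolesMask, PunctumRecord, RoiPolygon

logger = logging.getLogger(__name__)


@dataclass
class DensityReport:
    """Densities of one ROI; ``dn`` is None when the neuropil volume vanishes."""

    roi_id: str
    n_included: int
    area_um2: float
    volume_um3: float
    holes_um3: float
    d: float
    dn: float | None

    def to_row(self) -> dict:
        return {
            "roi_id": self.roi_id,
            "n_included": self.n_included,
            "area_um2": self.area_um2,
            "volume_um3": self.volume_um3,
            "holes_um3": self.holes_um3,
            "d_per_um3": self.d,
            "dn_per_um3": self.dn if self.dn is not None else np.nan,
        }


def _centroid_xy(records) -> np.ndarray:
    """(x, y) centroid coordinates (pixel units) of non-excluded records."""
    if isinstance(records, pd.DataFrame):
        keep = ~records["touches_exclusion"].astype(bool)
        return records.loc[keep, ["x", "y"]].to_numpy(dtype=float)
    pts = [r.centroid_px[:2] for r in records if not r.touches_exclusion]
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def count_in_roi(records, roi: RoiPolygon) -> int:
    """Stereological count N_s: non-excluded centroids strictly inside ``roi``.

    ``records`` is a list of :class:`~punctakit.core.PunctumRecord` or a
    centroid DataFrame.  Centroids exactly on the polygon boundary are not
    counted.
    """
    xy = _centroid_xy(records)
    if len(xy) == 0:
        return 0
    poly = roi.to_shapely()
    inside = shapely.contains_xy(poly, xy[:, 0], xy[:, 1])
    return int(inside.sum())


def roi_volume(
    roi: RoiPolygon,
    n_slices: int,
    z_step: float,
    pixel_size_xy: float,
) -> tuple[float, float]:
    """Polygon area A(R) in um^2 and prism volume V(R) = A(R) * delta in um^3."""
    area_um2 = roi.area_px2 * pixel_size_xy**2
    if area_um2 <= 0:
        raise ValueError("degenerate polygon")
    return area_um2, area_um2 * (n_slices * z_step)


def holes_volume(mask: HolesMask, roi: RoiPolygon) -> float:
    """Hole volume H(R) in um^3: holes-mask counts inside ``roi`` times voxel volume.

    A mask pixel contributes when its center lies strictly inside the polygon.
    """
    n_y, n_x = mask.counts.shape
    poly = roi.to_shapely()
    x_min, y_min, x_max, y_max = poly.bounds
    if x_max < 0 or y_max < 0 or x_min > n_x - 1 or y_min > n_y - 1:
        raise ValueError("roi out of frame")
    # only evaluate pixel centers inside the polygon's bounding box
    xs = np.arange(max(int(np.floor(x_min)), 0), min(int(np.ceil(x_max)) + 1, n_x))
    ys = np.arange(max(int(np.floor(y_min)), 0), min(int(np.ceil(y_max)) + 1, n_y))
    if xs.size == 0 or ys.size == 0:
        return 0.0
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    total = float(mask.counts[np.ix_(ys, xs)][inside].sum())
    return total * mask.pixel_size_xy**2 * mask.z_step


def density(
    records,
    roi: RoiPolygon,
    mask: HolesMask | None = None,
    *,
    n_slices: int | None = None,
    pixel_size_xy: float | None = None,
    z_step: float | None = None,
    roi_id: str = "roi",
) -> DensityReport:
    """Volume number density d(R) and neuropil density dn(R) for one ROI.

    Calibration and depth are taken from ``mask`` when given, otherwise the
    keyword arguments are required.  When the hole volume reaches the prism
    volume, ``dn`` is undefined and reported as None with a logged warning.
    """
    if mask is not None:
        n_slices = mask.n_slices
        pixel_size_xy = mask.pixel_size_xy
        z_step = mask.z_step
    if n_slices is None or pixel_size_xy is None or z_step is None:
        raise ValueError("n_slices, pixel_size_xy and z_step are required without a mask")
    area_um2, volume_um3 = roi_volume(roi, n_slices, z_step, pixel_size_xy)
    holes_um3 = holes_volume(mask, roi) if mask is not None else 0.0
    n_s = count_in_roi(records, roi)
    d = n_s / volume_um3
    if holes_um3 >= volume_um3:
        logger.warning("roi %s: hole volume >= prism volume; dn undefined", roi_id)
        dn = None
    else:
        dn = n_s / (volume_um3 - holes_um3)
    return DensityReport(
        roi_id=roi_id,
        n_included=n_s,
        area_um2=area_um2,
        volume_um3=volume_um3,
        holes_um3=holes_um3,
        d=d,
        dn=dn,
    )
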