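"""Domain types, calibration and file I/O for puncta analysis.

Conventions used throughout the package:

* A stack is indexed ``(z, y, x)``: ``z`` is the TIFF page index, ``y`` the
  image row and ``x`` the image column.
* All coordinates are 0-based and voxel-centered.  Exported point lists are
  ordered ``x, y, z`` with ``x`` fastest.
* Calibration is supplied explicitly (``pixel_size_xy`` in um/pixel in the
  imaging plane, ``z_step`` in um between consecutive slices) and never
  parsed from microscope metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
import shapely.geometry
import tifffile

logger = logging.getLogger(__name__)

#: CSV column order of the centroid list written by the ``detect`` pipeline.
CENTROID_COLUMNS = [
    "tag",
    "x",
    "y",
    "z",
    "volume_vox",
    "volume_um3",
    "surface_um2",
    "touches_exclusion",
]

#: The six stack faces; the first three (minimal-coordinate faces) are the
#: default stereological exclusion borders.
STACK_FACES = ("x0", "y0", "z0", "x1", "y1", "z1")
DEFAULT_EXCLUSION_FACES = ("x0", "y0", "z0")


@dataclass
class ImageStack:
    """A calibrated 3D scalar intensity grid.

    Parameters
    ----------
    data
        Non-negative intensities, shape ``(n_z, n_y, n_x)``.
    bit_depth
        8 or 16; the maximum representable intensity is ``2**bit_depth - 1``.
    pixel_size_xy
        In-plane sampling, um per pixel.
    z_step
        Axial sampling, um per slice.
    """

    data: np.ndarray
    bit_depth: int = 8
    pixel_size_xy: float = 1.0
    z_step: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("stack must be 3D with all dimensions >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("calibration must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and (self.data < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def max_intensity(self) -> int:
        """Maximum representable intensity for this bit depth."""
        return (1 << self.bit_depth) - 1

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return self.pixel_size_xy**2 * self.z_step


@dataclass
class LabelStack:
    """3D grid of non-negative integer object tags; 0 is background."""

    labels: np.ndarray
    pixel_size_xy: float = 1.0
    z_step: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)

    @property
    def tags(self) -> np.ndarray:
        """Sorted array of positive tags present."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class HolesMask:
    """2D projection of the binary holes stack.

    ``counts[y, x]`` is the number of slices in which pixel ``(x, y)`` was
    classified as not belonging to neuropil.
    """

    counts: np.ndarray
    n_slices: int
    pixel_size_xy: float = 1.0
    z_step: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("holes mask must be 2D")
        if self.counts.min() < 0 or self.counts.max() > self.n_slices:
            raise ValueError("counts must lie in [0, n_slices]")

    @property
    def total_volume_um3(self) -> float:
        """Total hole volume over the full frame, in um^3."""
        return float(self.counts.sum()) * self.pixel_size_xy**2 * self.z_step


@dataclass
class RoiPolygon:
    """Closed 2D polygon (pixel coordinates) defining a measurement prism."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        # drop an explicitly repeated closing vertex
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError("a polygon needs at least 3 distinct vertices")
        poly = shapely.geometry.Polygon(v)
        if not poly.is_valid:
            raise ValueError(f"invalid polygon: {shapely.is_valid_reason(poly)}")
        if poly.area <= 0:
            raise ValueError("polygon area must be positive")
        self.vertices = v

    def to_shapely(self) -> shapely.geometry.Polygon:
        return shapely.geometry.Polygon(self.vertices)

    @property
    def area_px2(self) -> float:
        return self.to_shapely().area


@dataclass
class PunctumRecord:
    """One detected object.

    Centroids are the unweighted mean of the object's voxel coordinates,
    reported both in pixel units (``x, y, z``) and in um.  ``touches_exclusion``
    flags objects touching any configured stereological exclusion face.
    """

    tag: int
    centroid_px: tuple[float, float, float]
    centroid_um: tuple[float, float, float]
    volume_vox: int
    volume_um3: float
    surface_um2: float
    touches_exclusion: bool


@dataclass
class DetectionParams:
    """Tunable parameters of the detection pipeline.

    Defaults are the values used for the vGlut-1/vGAT experiments: LoG radii
    4..10 px in steps of 1, moment-preserving threshold, Bhattacharyya join
    threshold ``phi`` = 0.4, minimum object size 40 voxels, tag-propagation
    tolerance ``toll`` = 0.
    """

    r_min: float = 4.0
    r_max: float = 10.0
    delta_step: float = 1.0
    thr_method: str = "moments"
    phi: float = 0.4
    min_size: int = 40
    toll: float = 0.0
    holes_thr: float = 0.9
    holes_median_radius: int = 10
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= self.r_max):
            raise ValueError("need 0 < r_min <= r_max")
        if self.delta_step <= 0:
            raise ValueError("delta_step must be positive")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if self.min_size < 0 or self.toll < 0:
            raise ValueError("min_size and toll must be non-negative")
        if not (0.0 <= self.holes_thr <= 1.0):
            raise ValueError("holes_thr must lie in [0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("in-plane connectivity must be 4 or 8")

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectionParams":
        """Load parameters from JSON; missing keys keep their defaults."""
        with open(path) as fh:
            payload = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    pixel_size_xy: float | None = None,
    z_step: float | None = None,
) -> ImageStack:
    """Read a multi-page grayscale TIFF as an :class:`ImageStack`.

    Pages are stacked in file order as the z axis.  Calibration defaults to
    1.0 um/pixel and 1.0 um/slice (with a logged warning) when not supplied.
    """
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        axes = series.axes
        if any(ax in axes for ax in ("S", "C")):
            raise ValueError("single-channel required: multi-sample TIFF")
        data = series.asarray()
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError("single-channel required: unexpected TIFF layout")
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"unsupported sample type {data.dtype}; need 8- or 16-bit")
    if pixel_size_xy is None or z_step is None:
        logger.warning(
            "no calibration supplied for %s; defaulting to 1.0 um/pixel, 1.0 um/slice",
            path,
        )
    return ImageStack(
        data=data,
        bit_depth=bit_depth,
        pixel_size_xy=pixel_size_xy if pixel_size_xy is not None else 1.0,
        z_step=z_step if z_step is not None else 1.0,
    )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a multi-page grayscale TIFF."""
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")


def write_labels(labels: LabelStack | np.ndarray, path: str | Path) -> None:
    """Write a label stack as a multi-page TIFF, 16-bit when tags fit else 32-bit."""
    arr = labels.labels if isinstance(labels, LabelStack) else np.asarray(labels)
    dtype = np.uint16 if arr.max(initial=0) <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(str(path), arr.astype(dtype), photometric="minisblack")


def read_labels(
    path: str | Path, pixel_size_xy: float = 1.0, z_step: float = 1.0
) -> LabelStack:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return LabelStack(arr.astype(np.int64), pixel_size_xy, z_step)


def read_points(
    path: str | Path, shape: tuple[int, int, int] | None = None
) -> pd.DataFrame:
    """Read a point list CSV with header ``x,y,z[,id]``.

    Points are 0-based pixel coordinates.  When the source stack ``shape``
    (``(n_z, n_y, n_x)``) is given, out-of-range coordinates are rejected
    with the offending file row number.
    """
    df = pd.read_csv(path)
    required = {"x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"point CSV must have columns x,y,z; got {list(df.columns)}")
    if shape is not None:
        n_z, n_y, n_x = shape
        bounds = {"x": n_x, "y": n_y, "z": n_z}
        for axis, n in bounds.items():
            bad = df.index[(df[axis] < 0) | (df[axis] >= n)]
            if len(bad) > 0:
                # +2 converts 0-based data index to the file row (header is row 1)
                raise ValueError(
                    f"point out of range on axis {axis!r} at file row {bad[0] + 2}"
                )
    return df


def write_points(points: pd.DataFrame | np.ndarray, path: str | Path) -> None:
    if not isinstance(points, pd.DataFrame):
        points = pd.DataFrame(np.asarray(points), columns=["x", "y", "z"])
    points.to_csv(path, index=False)


def _rois_from_geometry(geom) -> list[RoiPolygon]:
    if geom.geom_type == "Polygon":
        return [RoiPolygon(np.asarray(geom.exterior.coords))]
    if geom.geom_type == "MultiPolygon":
        return [RoiPolygon(np.asarray(g.exterior.coords)) for g in geom.geoms]
    raise ValueError(f"unsupported geometry type {geom.geom_type}")


def read_roi(path: str | Path) -> list[RoiPolygon]:
    """Read ROI polygon(s) from GeoJSON or a plain ``x,y`` CSV vertex ring."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("type") == "FeatureCollection":
            geoms = [shapely.geometry.shape(f["geometry"]) for f in payload["features"]]
        elif payload.get("type") == "Feature":
            geoms = [shapely.geometry.shape(payload["geometry"])]
        else:
            geoms = [shapely.geometry.shape(payload)]
        rois: list[RoiPolygon] = []
        for g in geoms:
            rois.extend(_rois_from_geometry(g))
        return rois
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError("ROI CSV must have columns x,y")
    return [RoiPolygon(df[["x", "y"]].to_numpy(dtype=float))]


def records_to_frame(records: Iterable[PunctumRecord]) -> pd.DataFrame:
    """Tabulate punctum records in the canonical centroid-CSV column order."""
    rows = [
        {
            "tag": r.tag,
            "x": r.centroid_px[0],
            "y": r.centroid_px[1],
            "z": r.centroid_px[2],
            "volume_vox": r.volume_vox,
            "volume_um3": r.volume_um3,
            "surface_um2": r.surface_um2,
            "touches_exclusion": r.touches_exclusion,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CENTROID_COLUMNS)


def write_records(records: Iterable[PunctumRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CENTROID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"centroid CSV missing columns {sorted(missing)}")
    return df
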