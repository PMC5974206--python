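"""3D object tagging: per-slice tag propagation, Bhattacharyya slice linking,
size checking and object measurement.

The labeler works on the fused stack (denoised intensities on the foreground,
zero elsewhere) in three stages:

1. *Slice tagging* — independently on every slice, tags are propagated from
   the relative maxima of the intensity.  Pixels are visited in decreasing
   intensity order; a pixel with no brighter tagged neighbour starts a new
   object, otherwise it joins the object of its brightest tagged neighbour.
   Two objects meeting at a pixel of intensity ``I`` are merged when the
   fainter object's peak does not exceed ``I + toll``: with ``toll = 0`` every
   relative maximum (up to plateaus) yields its own object, while a ``toll``
   at least as large as the intensity range reduces the stage to plain
   connected-component labeling.
2. *Slice connection* — objects on adjacent slices are joined into 3D objects
   when the Bhattacharyya coefficient between their normalized intensity
   distributions exceeds ``phi``; joins are transitive (union-find).
3. *Size checking* — objects smaller than ``min_size`` voxels are dissolved
   into the touching neighbour with the largest contact surface, or into the
   background when they touch no other object.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    DEFAULT_EXCLUSION_FACES,
    ImageStack,
    LabelStack,
    PunctumRecord,
)

logger = logging.getLogger(__name__)

_OFFSETS = {
    4: ((-1, 0), (1, 0), (0, -1), (0, 1)),
    8: (
        (-1, -1), (-1, 0), (-1, 1),
        (0, -1), (0, 1),
        (1, -1), (1, 0), (1, 1),
    ),
}


class _DisjointSet:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: list[int] = [0]

    def make(self) -> int:
        self.parent.append(len(self.parent))
        return len(self.parent) - 1

    def find(self, i: int) -> int:
        parent = self.parent
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    def union(self, i: int, j: int) -> int:
        """Merge the set of ``i`` into the set of ``j``; returns the new root."""
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj
        return rj


def slice_tagging(
    fused_slice: np.ndarray, toll: float = 0.0, connectivity: int = 8
) -> np.ndarray:
    """Tag connected objects of one slice by intensity-ordered propagation.

    Foreground pixels (intensity > 0) are visited in decreasing intensity
    order and flooded from the relative maxima as described in the module
    docstring.  Returns an int32 label grid, 0 on the background; tags are
    renumbered 1..K in raster-scan order of first occurrence.
    """
    if toll < 0:
        raise ValueError("toll must be non-negative")
    offsets = _OFFSETS[connectivity]
    img = np.asarray(fused_slice, dtype=np.float64)
    h, w = img.shape
    flat = img.ravel()
    fg = np.flatnonzero(flat > 0)
    labels = np.zeros(h * w, dtype=np.int64)
    if fg.size == 0:
        return labels.reshape(h, w).astype(np.int32)
    order = fg[np.argsort(-flat[fg], kind="stable")]

    dsu = _DisjointSet()
    peak: list[float] = [0.0]  # per-region seed (relative maximum) intensity

    for idx in order:
        y, x = divmod(int(idx), w)
        intensity = flat[idx]
        best_label = 0
        best_key = None
        neighbour_roots: list[int] = []
        for dy, dx in offsets:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                lab = labels[ny * w + nx]
                if lab:
                    root = dsu.find(lab)
                    key = (-flat[ny * w + nx], root)
                    if best_key is None or key < best_key:
                        best_key, best_label = key, root
                    neighbour_roots.append(root)
        if best_label == 0:
            new = dsu.make()
            peak.append(float(intensity))
            labels[idx] = new
            continue
        labels[idx] = best_label
        if len(neighbour_roots) > 1:
            for root in set(neighbour_roots):
                root = dsu.find(root)
                target = dsu.find(best_label)
                if root != target and peak[root] <= intensity + toll:
                    merged = dsu.union(root, target)
                    peak[merged] = max(peak[root], peak[target])

    roots = np.array([0] + [dsu.find(i) for i in range(1, len(dsu.parent))])
    labels = roots[labels]
    return _relabel_first_occurrence(labels.reshape(h, w))


def _relabel_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Renumber positive labels 1..K by order of first occurrence (C order)."""
    flat = labels.ravel()
    pos = flat > 0
    if not pos.any():
        return labels.astype(np.int32)
    vals = flat[pos]
    uniq, first = np.unique(vals, return_index=True)
    lut = np.zeros(int(uniq.max()) + 1, dtype=np.int32)
    lut[uniq[np.argsort(first)]] = np.arange(1, len(uniq) + 1)
    out = np.zeros_like(flat, dtype=np.int32)
    out[pos] = lut[vals]
    return out.reshape(labels.shape)


def normalized_intensity(pixels: dict[tuple[int, int], float]) -> dict[tuple[int, int], float]:
    """Normalize a pixel->intensity map so the intensities sum to 1."""
    total = float(sum(pixels.values()))
    if total <= 0:
        raise ValueError("degenerate object: zero total intensity")
    return {k: v / total for k, v in pixels.items()}


def bhattacharyya(
    obj_i: dict[tuple[int, int], float], obj_j: dict[tuple[int, int], float]
) -> float:
    """Bhattacharyya coefficient between two objects' intensity distributions.

    Each object is a map from in-plane pixel ``(x, y)`` to intensity.  The
    intensities are normalized per object to sum to 1 and the coefficient is
    the sum over shared pixels of the square root of the product of the two
    normalized intensities; positions present in only one object contribute 0.
    The result lies in [0, 1], reaching 1 only for identical distributions.
    """
    ni = normalized_intensity(obj_i)
    nj = normalized_intensity(obj_j)
    bc = sum(np.sqrt(ni[k] * nj[k]) for k in ni.keys() & nj.keys())
    return float(min(bc, 1.0))


def connect_slices(
    slice_labels: Sequence[np.ndarray],
    fused: ImageStack | np.ndarray,
    phi: float,
) -> np.ndarray:
    """Join per-slice objects across adjacent slices into 3D objects.

    For every pair of objects on adjacent slices sharing at least one (x, y)
    position, the Bhattacharyya coefficient of their intensity distributions
    is computed from the fused stack; pairs with BC strictly greater than
    ``phi`` are merged, transitively.  Returns an int32 label stack with tags
    renumbered 1..K by first voxel occurrence in (z, y, x) scan order.
    """
    if not (0.0 <= phi <= 1.0):
        raise ValueError("phi must lie in [0, 1]")
    data = fused.data if isinstance(fused, ImageStack) else np.asarray(fused)
    data = data.astype(np.float64)
    n_z = len(slice_labels)
    if n_z != data.shape[0]:
        raise ValueError("slice count mismatch between labels and stack")

    # Offset per-slice tags into one global id space.
    global_labels = np.zeros(data.shape, dtype=np.int64)
    offset = 0
    for z, sl in enumerate(slice_labels):
        sl = np.asarray(sl)
        global_labels[z] = np.where(sl > 0, sl + offset, 0)
        offset += int(sl.max(initial=0))
    n_objects = offset

    # Per-object total intensity (Bhattacharyya normalizer).
    totals = np.bincount(
        global_labels.ravel(), weights=data.ravel(), minlength=n_objects + 1
    )

    parent = np.arange(n_objects + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for z in range(n_z - 1):
        a, b = global_labels[z], global_labels[z + 1]
        shared = (a > 0) & (b > 0)
        if not shared.any():
            continue
        ai, bi = a[shared], b[shared]
        w = np.sqrt(data[z][shared] * data[z + 1][shared])
        codes = ai * (n_objects + 1) + bi
        uniq, inverse = np.unique(codes, return_inverse=True)
        overlap = np.bincount(inverse, weights=w)
        for code, s in zip(uniq, overlap):
            i, j = divmod(int(code), n_objects + 1)
            bc = s / np.sqrt(totals[i] * totals[j])
            if bc > phi:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    roots = np.array([find(i) for i in range(n_objects + 1)])
    merged = roots[global_labels]
    return _relabel_first_occurrence(merged)


def _contact_counts(labels: np.ndarray, bbox: tuple[slice, ...], tag: int) -> np.ndarray:
    """Tally of 26-connected neighbour labels around the voxels of ``tag``."""
    grown = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n))
        for s, n in zip(bbox, labels.shape)
    )
    sub = labels[grown]
    mask = sub == tag
    shell = ndimage.binary_dilation(mask, structure=np.ones((3, 3, 3), bool)) & ~mask
    neigh = sub[shell]
    neigh = neigh[neigh > 0]
    return np.bincount(neigh)


def size_check(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Dissolve objects smaller than ``min_size`` voxels.

    Undersized objects (processed smallest first, repeatedly until stable)
    are merged into the 26-connected touching object with the largest contact
    surface (ties to the lowest tag); an object touching nothing becomes
    background.  Never increases the object count; total foreground is
    conserved except for voxels dissolved into the background.
    """
    if min_size < 0:
        raise ValueError("min_size must be non-negative")
    out = np.asarray(labels).copy()
    if min_size == 0:
        return out
    while True:
        counts = np.bincount(out.ravel())
        small = [t for t in range(1, len(counts)) if 0 < counts[t] < min_size]
        if not small:
            break
        small.sort(key=lambda t: (counts[t], t))
        bboxes = ndimage.find_objects(out)
        changed = False
        for tag in small:
            bbox = bboxes[tag - 1]
            if bbox is None or not (out[bbox] == tag).any():
                continue  # already absorbed earlier in this pass
            contact = _contact_counts(out, bbox, tag)
            recipient = 0
            if contact.size > 1:
                best = contact[1:].max()
                if best > 0:
                    recipient = int(np.flatnonzero(contact[1:] == best)[0]) + 1
            region = out[bbox]
            region[region == tag] = recipient
            changed = True
        if not changed:
            break
    return out


def measure(
    labels: LabelStack | np.ndarray,
    pixel_size_xy: float = 1.0,
    z_step: float = 1.0,
    exclusion_faces: Sequence[str] = DEFAULT_EXCLUSION_FACES,
) -> list[PunctumRecord]:
    """Centroid, volume, surface area and exclusion flag of every object.

    The centroid is the unweighted mean of voxel coordinates (x, y, z order);
    the volume is the voxel count times the voxel volume; the surface area
    counts exposed voxel faces (faces adjoining a different tag, the
    background, or the stack boundary), each weighted by its physical area.
    ``touches_exclusion`` is true when any voxel of the object lies on one of
    the configured exclusion faces of the stack (default: the three
    minimal-coordinate faces x=0, y=0, z=0).
    """
    if isinstance(labels, LabelStack):
        pixel_size_xy = labels.pixel_size_xy
        z_step = labels.z_step
        arr = labels.labels
    else:
        arr = np.asarray(labels)
    n_z, n_y, n_x = arr.shape
    max_tag = int(arr.max(initial=0))
    if max_tag == 0:
        return []

    voxel_volume = pixel_size_xy**2 * z_step
    # Face areas by axis the face normal points along: z-normal faces lie in
    # the xy plane, x-/y-normal faces span one pixel by one z step.
    face_area = {0: pixel_size_xy**2, 1: pixel_size_xy * z_step, 2: pixel_size_xy * z_step}

    surface = np.zeros(max_tag + 1, dtype=np.float64)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        a, b = arr[tuple(lo)], arr[tuple(hi)]
        diff = a != b
        for side in (a, b):
            vals = side[diff & (side > 0)]
            surface += face_area[axis] * np.bincount(vals, minlength=max_tag + 1)
        for edge_index in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = edge_index
            edge = arr[tuple(sl)]
            vals = edge[edge > 0]
            surface += face_area[axis] * np.bincount(vals, minlength=max_tag + 1)

    face_tests = {
        "x0": lambda zz, yy, xx: (xx == 0).any(),
        "x1": lambda zz, yy, xx: (xx == n_x - 1).any(),
        "y0": lambda zz, yy, xx: (yy == 0).any(),
        "y1": lambda zz, yy, xx: (yy == n_y - 1).any(),
        "z0": lambda zz, yy, xx: (zz == 0).any(),
        "z1": lambda zz, yy, xx: (zz == n_z - 1).any(),
    }
    unknown = set(exclusion_faces) - set(face_tests)
    if unknown:
        raise ValueError(f"unknown exclusion face(s): {sorted(unknown)}")

    records: list[PunctumRecord] = []
    for tag, bbox in enumerate(ndimage.find_objects(arr), start=1):
        if bbox is None:
            continue
        zz, yy, xx = np.nonzero(arr[bbox] == tag)
        zz = zz + bbox[0].start
        yy = yy + bbox[1].start
        xx = xx + bbox[2].start
        n_vox = len(zz)
        cx, cy, cz = float(xx.mean()), float(yy.mean()), float(zz.mean())
        records.append(
            PunctumRecord(
                tag=tag,
                centroid_px=(cx, cy, cz),
                centroid_um=(cx * pixel_size_xy, cy * pixel_size_xy, cz * z_step),
                volume_vox=n_vox,
                volume_um3=n_vox * voxel_volume,
                surface_um2=float(surface[tag]),
                touches_exclusion=any(
                    face_tests[f](zz, yy, xx) for f in exclusion_faces
                ),
            )
        )
    return records
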