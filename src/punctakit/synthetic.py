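"""Ground-truthed synthetic confocal-like stacks.

The generator emulates the geometry of the real acquisitions: shallow stacks
(15 slices by default, 0.14 um z-step) of bright, roughly Gaussian puncta on
a noisy diffuse background, optionally with large dark "holes" (cylinders
through the full depth, mimicking somata and vessels).  Each punctum of
nominal radius ``rho`` pixels is an anisotropic 3D Gaussian with in-plane
standard deviation ``rho / 2`` and axial standard deviation scaled by the
voxel anisotropy (``pixel_size_xy / z_step``), so a blob that is physically
isotropic in um appears compressed along z in voxel units.

Default in-plane sampling is 0.066 um/pixel (high-magnification oil-immersion
confocal at Nyquist-level zoom), which puts nominal radii of 4-8 px at
physical radii of about 0.26-0.53 um — the scale of presynaptic boutons.

All randomness flows from the single integer ``seed`` through a dedicated
``numpy`` generator; identical specs give bit-identical stacks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic stack."""

    shape: tuple[int, int, int] = (15, 512, 512)  # (n_z, n_y, n_x)
    n_puncta: int = 150
    radius_range: tuple[float, float] = (4.0, 8.0)
    peak_range: tuple[float, float] = (100.0, 200.0)
    background: float = 40.0
    noise_sigma: float = 8.0
    poisson: bool = False
    n_holes: int = 0
    hole_radius_range: tuple[float, float] = (60.0, 120.0)
    hole_dimming: float = 0.05
    margin_xy: float | None = None  # default: 2.5 * max radius
    margin_z: float | None = None   # default: keeps axial tails off the z faces
    min_separation_factor: float = 1.0  # centers at least this * (rho_i + rho_j) apart
    pixel_size_xy: float = 0.066
    z_step: float = 0.14
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] <= 0 or self.radius_range[0] > self.radius_range[1]:
            raise ValueError("invalid radius range")
        if self.n_puncta < 0 or self.n_holes < 0:
            raise ValueError("counts must be non-negative")
        max_val = (1 << self.bit_depth) - 1
        if self.peak_range[1] + self.background > max_val:
            raise ValueError("peak intensities exceed the bit depth")

    @property
    def axial_ratio(self) -> float:
        """Voxel anisotropy: axial sigma in slices per in-plane sigma in pixels."""
        return self.pixel_size_xy / self.z_step


@dataclass
class GroundTruthPunctum:
    """Exact parameters of one planted punctum."""

    center_xyz: tuple[float, float, float]  # (x, y, z) in pixel/slice units
    radius_px: float
    sigma_xy: float
    sigma_z: float
    peak: float


@dataclass
class GroundTruthHole:
    """One planted dark cylinder (full stack depth)."""

    center_xy: tuple[float, float]
    radius_px: float
    volume_um3: float


@dataclass
class SyntheticStack:
    """A generated stack with its complete ground truth."""

    stack: ImageStack
    puncta: list[GroundTruthPunctum]
    holes: list[GroundTruthHole]
    holes_stack: np.ndarray  # binary (n_z, n_y, n_x), 1 inside a hole
    spec: SyntheticSpec


def _sample_centers(
    spec: SyntheticSpec,
    radii: np.ndarray,
    rng: np.random.Generator,
    forbidden_xy: np.ndarray | None = None,
):
    """Sample blob centers with margins, pairwise in-plane separation, and
    (optionally) avoidance of forbidden columns such as holes."""
    n_z, n_y, n_x = spec.shape
    if len(radii) == 0:
        return np.empty((0, 3))
    rho_max = float(radii.max(initial=spec.radius_range[1]))
    margin_xy = spec.margin_xy if spec.margin_xy is not None else 2.5 * rho_max
    if spec.margin_z is not None:
        margin_z = spec.margin_z
    else:
        # keep the 2.5-sigma axial tail inside the stack
        margin_z = min(2.5 * (rho_max / 2.0) * spec.axial_ratio + 1.0, (n_z - 1) / 2.0)
    if 2 * margin_xy >= min(n_x, n_y) - 1 or 2 * margin_z > n_z - 1:
        raise ValueError("infeasible spec: margins leave no room for puncta")
    centers = np.empty((len(radii), 3))
    placed = 0
    attempts = 0
    max_attempts = 200 * max(len(radii), 1)
    while placed < len(radii):
        if attempts > max_attempts:
            logger.warning("could not keep all puncta separated; allowing overlap")
            break
        attempts += 1
        c = np.array(
            [
                rng.uniform(margin_xy, n_x - 1 - margin_xy),
                rng.uniform(margin_xy, n_y - 1 - margin_xy),
                rng.uniform(margin_z, n_z - 1 - margin_z),
            ]
        )
        if forbidden_xy is not None and forbidden_xy[
            int(round(c[1])), int(round(c[0]))
        ]:
            continue
        if placed:
            # separation measured in-plane; z offsets do not prevent in-plane merging
            d_xy = np.hypot(
                centers[:placed, 0] - c[0], centers[:placed, 1] - c[1]
            )
            min_sep = spec.min_separation_factor * (radii[:placed] + radii[placed])
            if (d_xy < min_sep).any():
                continue
        centers[placed] = c
        placed += 1
    while placed < len(radii):  # fallback: place without separation
        c = np.array(
            [
                rng.uniform(margin_xy, n_x - 1 - margin_xy),
                rng.uniform(margin_xy, n_y - 1 - margin_xy),
                rng.uniform(margin_z, n_z - 1 - margin_z),
            ]
        )
        if forbidden_xy is not None and forbidden_xy[
            int(round(c[1])), int(round(c[0]))
        ]:
            continue
        centers[placed] = c
        placed += 1
    return centers


def generate(spec: SyntheticSpec) -> SyntheticStack:
    """Render a synthetic stack and its exact ground truth."""
    rng = np.random.default_rng(spec.seed)
    n_z, n_y, n_x = spec.shape
    img = np.full(spec.shape, float(spec.background))

    # holes first, so puncta can be kept out of them
    holes_stack = np.zeros(spec.shape, dtype=np.uint8)
    holes: list[GroundTruthHole] = []
    yy_grid, xx_grid = np.mgrid[0:n_y, 0:n_x]
    for _ in range(spec.n_holes):
        r = rng.uniform(*spec.hole_radius_range)
        cx = rng.uniform(r, n_x - 1 - r)
        cy = rng.uniform(r, n_y - 1 - r)
        inside = (xx_grid - cx) ** 2 + (yy_grid - cy) ** 2 <= r**2
        holes_stack[:, inside] = 1
        area_px = float(inside.sum())
        holes.append(
            GroundTruthHole(
                center_xy=(cx, cy),
                radius_px=r,
                volume_um3=area_px * n_z * spec.pixel_size_xy**2 * spec.z_step,
            )
        )

    radii = rng.uniform(*spec.radius_range, size=spec.n_puncta)
    peaks = rng.uniform(*spec.peak_range, size=spec.n_puncta)
    # puncta live in the neuropil: hole columns are forbidden
    forbidden = holes_stack[0] > 0 if holes else None
    centers = _sample_centers(spec, radii, rng, forbidden_xy=forbidden)

    puncta: list[GroundTruthPunctum] = []
    for (cx, cy, cz), rho, peak in zip(centers, radii, peaks):
        sigma_xy = rho / 2.0
        sigma_z = sigma_xy * spec.axial_ratio
        ext_xy = int(np.ceil(4 * sigma_xy))
        ext_z = int(np.ceil(4 * sigma_z))
        x0, x1 = max(int(cx) - ext_xy, 0), min(int(cx) + ext_xy + 2, n_x)
        y0, y1 = max(int(cy) - ext_xy, 0), min(int(cy) + ext_xy + 2, n_y)
        z0, z1 = max(int(cz) - ext_z, 0), min(int(cz) + ext_z + 2, n_z)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        blob = peak * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_xy**2)
            - (zz - cz) ** 2 / (2 * sigma_z**2)
        )
        img[z0:z1, y0:y1, x0:x1] += blob
        puncta.append(
            GroundTruthPunctum(
                center_xyz=(float(cx), float(cy), float(cz)),
                radius_px=float(rho),
                sigma_xy=float(sigma_xy),
                sigma_z=float(sigma_z),
                peak=float(peak),
            )
        )

    if holes:
        img = np.where(holes_stack > 0, img * spec.hole_dimming, img)
    if spec.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    max_val = (1 << spec.bit_depth) - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    data = np.clip(np.round(img), 0, max_val).astype(dtype)
    stack = ImageStack(
        data,
        bit_depth=spec.bit_depth,
        pixel_size_xy=spec.pixel_size_xy,
        z_step=spec.z_step,
    )
    return SyntheticStack(
        stack=stack, puncta=puncta, holes=holes, holes_stack=holes_stack, spec=spec
    )
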