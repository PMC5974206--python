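"""Foreground segmentation: multi-scale Laplacian-of-Gaussian + auto-threshold.

The segmentation branch computes, slice by slice, the scale-normalized
negative Laplacian-of-Gaussian (LoG) response at a range of blob radii and
keeps, per pixel, the maximum response over scales ("MaxLoGs").  The pooled
response histogram of the whole stack is then binarized with an automatic
threshold (moment-preserving by default).  Independently, the raw stack is
denoised with a two-scale median filter; the binary mask and the denoised
stack are fused by pixel-wise minimum, which keeps the denoised intensity on
foreground pixels and zeroes the background.

A LoG filter at blob radius ``r`` uses a Gaussian of standard deviation
``sigma = r / 2``; the response is multiplied by ``sigma**2`` so responses at
different scales are comparable, and its sign is flipped so bright blobs give
positive responses.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import median as _median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .core import ImageStack

logger = logging.getLogger(__name__)

#: Gaussian kernels are truncated at this many standard deviations.
GAUSSIAN_TRUNCATE = 4.0


def _as_array(stack: ImageStack | np.ndarray) -> np.ndarray:
    return stack.data if isinstance(stack, ImageStack) else np.asarray(stack)


def log_filter(stack: ImageStack | np.ndarray, r: float) -> np.ndarray:
    """Scale-normalized negative LoG response at blob radius ``r`` (pixels).

    Each z-slice is filtered independently in 2D with ``sigma = r / 2``
    (reflective borders).  Returns a float array of the input shape; bright
    blobs of radius about ``r`` give a strong positive response at their
    center.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    data = _as_array(stack)
    sigma = r / 2.0
    kernel_radius = int(GAUSSIAN_TRUNCATE * sigma + 0.5)
    if 2 * kernel_radius + 1 > min(data.shape[1], data.shape[2]):
        raise ValueError(f"scale too large: r={r} kernel exceeds slice size")
    out = np.empty(data.shape, dtype=np.float64)
    for z in range(data.shape[0]):
        ndimage.gaussian_laplace(
            data[z].astype(np.float64),
            sigma=sigma,
            output=out[z],
            mode="reflect",
            truncate=GAUSSIAN_TRUNCATE,
        )
    out *= -(sigma**2)
    return out


def scale_range(r_min: float, r_max: float, delta_step: float) -> np.ndarray:
    """Radii ``r_min, r_min + delta, ...`` up to and including ``r_max``."""
    if r_min > r_max:
        raise ValueError("need r_min <= r_max")
    n = int(np.floor((r_max - r_min) / delta_step + 1e-9)) + 1
    return r_min + delta_step * np.arange(n)


def max_logs(
    stack: ImageStack | np.ndarray,
    r_min: float,
    r_max: float,
    delta_step: float = 1.0,
) -> np.ndarray:
    """Pixel-wise maximum LoG response over radii ``r_min..r_max`` step ``delta_step``."""
    radii = scale_range(r_min, r_max, delta_step)
    if radii.size == 0:
        raise ValueError("empty scale set")
    response = log_filter(stack, radii[0])
    for r in radii[1:]:
        np.maximum(response, log_filter(stack, r), out=response)
    return response


def moments_threshold(values: np.ndarray) -> float:
    """Moment-preserving (Tsai) threshold of a gray-level histogram.

    The input is pooled into a 256-bin histogram over its [min, max] range.
    The two-level image that preserves the first three gray-level moments
    determines a background fraction ``p0``; the returned threshold is the
    gray value (bin center) at which the cumulative histogram first reaches
    ``p0``.  A constant input is degenerate: the single value is returned
    with a logged warning.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    vmin = float(v.min())
    vmax = float(v.max())
    if vmax == vmin:
        logger.warning("degenerate histogram: constant input, returning its value")
        return vmin
    hist, edges = np.histogram(v, bins=256, range=(vmin, vmax))
    p = hist / hist.sum()
    z = np.arange(256, dtype=np.float64)
    m1 = float((p * z).sum())
    m2 = float((p * z**2).sum())
    m3 = float((p * z**3).sum())
    cd = m2 - m1**2
    if cd <= 0:
        logger.warning("degenerate histogram: zero variance after binning")
        return vmin
    c0 = (m1 * m3 - m2**2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1**2 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    t = int(np.searchsorted(cum, p0))
    t = min(t, 255)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[t])


#: Pluggable automatic threshold methods for the MaxLoGs response.
THRESHOLD_METHODS = {
    "moments": moments_threshold,
    "otsu": lambda values: float(threshold_otsu(np.asarray(values).ravel(), nbins=256)),
}


def binarize(values: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask, true where ``values > threshold`` (strict)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(values) > threshold


def median_denoise(stack: ImageStack) -> ImageStack:
    """Two-scale edge-preserving median filter (disk radius 1, then radius 2).

    Applied per slice in 2D; the bit depth and dtype are preserved.
    """
    data = stack.data
    out = np.empty_like(data)
    fp1, fp2 = disk(1), disk(2)
    for z in range(data.shape[0]):
        out[z] = _median_filter(_median_filter(data[z], fp1), fp2)
    return ImageStack(out, stack.bit_depth, stack.pixel_size_xy, stack.z_step)


def fuse(mask: np.ndarray, denoised: ImageStack) -> ImageStack:
    """Pixel-wise minimum of the (rescaled) binary mask and the denoised stack.

    The mask is scaled to the stack's maximum representable intensity before
    the minimum, so foreground voxels keep their denoised intensity and
    background voxels become 0.
    """
    mask = np.asarray(mask)
    if mask.shape != denoised.shape:
        raise ValueError("mask and stack shapes differ")
    fused = np.minimum(
        np.where(mask, denoised.max_intensity, 0).astype(denoised.data.dtype),
        denoised.data,
    )
    return ImageStack(
        fused, denoised.bit_depth, denoised.pixel_size_xy, denoised.z_step
    )


def segment(
    stack: ImageStack,
    r_min: float,
    r_max: float,
    delta_step: float = 1.0,
    thr_method: str = "moments",
) -> tuple[np.ndarray, float, np.ndarray]:
    """MaxLoGs + automatic threshold; returns ``(mask, threshold, response)``.

    The threshold is computed on the pooled whole-stack response histogram so
    that objects spanning several slices are binarized consistently.
    """
    if thr_method not in THRESHOLD_METHODS:
        raise ValueError(
            f"unknown thr_method {thr_method!r}; available: {sorted(THRESHOLD_METHODS)}"
        )
    response = max_logs(stack, r_min, r_max, delta_step)
    threshold = THRESHOLD_METHODS[thr_method](response)
    return binarize(response, threshold), threshold, response
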