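# Methods notes

This note records the model assumptions, parameter meanings, numerical
choices and known limitations of the punctakit pipeline, in the spirit of a
maintainer's design document. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and calibration conventions

Stacks are arrays indexed `(z, y, x)`; coordinates are 0-based and
voxel-centered with `x` = column, `y` = row, `z` = TIFF page. Exports order
point coordinates `x, y, z`. Calibration (`pixel_size_xy` in μm/pixel,
`z_step` in μm/slice) is passed explicitly — microscope metadata parsing is
deliberately out of scope — and defaults to 1.0/1.0 with a logged warning.
The centroid CSV columns are fixed
(`tag,x,y,z,volume_vox,volume_um3,surface_um2,touches_exclusion`) as a stable
machine interface.

## Segmentation

**Per-slice 2D LoG.** Confocal stacks of this kind are strongly anisotropic
(slices ~0.14 μm apart, in-plane sampling finer still, and the axial PSF much
wider than the lateral one), so the LoG is applied slice by slice in 2D and
never as a 3D filter.

**Scale normalization and sign.** The response is `−σ²·(G_σ * ∇²I)`: the sign
flip makes bright blobs positive, and the `σ²` factor makes responses
comparable across scales — without it the pixel-wise maximum over scales is
always dominated by the smallest σ, defeating the purpose of a multi-scale
maximum. With the defaults `(r_min, r_max, δ) = (4, 10, 1)` exactly 7 scales
are evaluated, and a blob of radius ρ responds maximally at the scale nearest
ρ (verified by a brute-force dense-convolution oracle in the tests).

**Kernel details.** Gaussian kernels are truncated at 4σ; borders are
reflected; this keeps responses unbiased near edges at negligible cost. The
truncated discrete kernel has a DC gain of order 10⁻⁴, so the response to a
constant image is near zero but not exactly zero; tests use a tolerance
relative to the constant level.

**Moment-preserving threshold.** Tsai's method: pool the whole stack's
response into a 256-bin histogram, solve the two-level moment-preservation
equations for the background fraction `p0`, and return the bin center at
which the cumulative histogram first reaches `p0`. Pooling across slices
(rather than thresholding per slice) is deliberate: one object spans several
slices and per-slice thresholds would fragment it. Returning the bin
*center* makes the degenerate two-value case split exactly between the two
populations. The test oracle is an exhaustive 256-candidate search that
picks the cut minimizing the third-moment error; the closed form ("first bin
reaching p0") and the brute-force argmin ("nearest cumulative value") can
legitimately land one bin apart, so agreement is asserted to within one
histogram bin — the quantization granularity of the method itself. The
threshold method is pluggable (`thr_method`: `moments` default, `otsu`
available).

**Denoising and fusion.** The two-scale median filter uses disk footprints,
radius 1 then radius 2 sequentially, per slice, preserving dtype. Fusion
rescales the binary mask to the stack's maximum representable intensity
(255 or 65535) before the pixel-wise minimum; this is exactly "keep the
denoised intensity on the foreground, zero the background".

## Tagging

**Slice tagging.** The canonical implementation visits foreground pixels in
strictly decreasing intensity order. A pixel with no already-tagged
neighbour starts a new object (it is a relative maximum); otherwise it joins
its brightest tagged neighbour (ties to the lowest tag). When a pixel of
intensity `I` touches several objects, any object whose peak (seed) intensity
is at most `I + toll` is merged into the retained one. This makes the
procedure deterministic and order-independent, and gives the two limiting
behaviours that define `toll`: with `toll = 0` every relative maximum (up to
plateaus) yields one object, and with `toll` at least the intensity range the
stage reduces exactly to connected-component labeling (asserted against the
`scipy.ndimage.label` oracle). Connected equal-intensity plateaus adjacent
to no brighter pixel receive a single tag. In-plane connectivity is
8-connected by default ("nearest pixels" read to include diagonals, which
preserves the continuity of small blobs), configurable to 4.

**Slice connection.** For each pair of objects on adjacent slices the
Bhattacharyya coefficient is computed between their per-object-normalized
intensity distributions over shared `(x, y)` positions; pairs with
`BC > ϕ` (strictly — "surpasses") are merged, and merging is transitive via
union-find, so chains A–B, B–C unify all three. Final tags are renumbered
1..K by first voxel occurrence in `(z, y, x)` scan order, which makes the
whole pipeline bit-deterministic.

**Size checking.** Object size is measured in 3D voxels after connection.
Undersized objects are dissolved smallest-first, repeatedly until stable;
voxels go to the 26-connected touching object with the largest contact count
(ties to the lowest tag), or to the background when nothing touches. This
never increases the object count and conserves foreground except for voxels
returned to background.

**Measurement.** Centroid = unweighted mean of voxel coordinates; volume =
voxel count × `pixel_size_xy² × z_step`; surface area counts exposed voxel
faces weighted by their physical areas (z-normal faces `pixel_size²`,
lateral faces `pixel_size × z_step`) — exact on boxes and testable, no mesh
smoothing. Exclusion borders default to the three minimal-coordinate faces
(`x=0, y=0, z=0`), configurable; an object touching any of them is flagged
and excluded from stereological counts.

## Holes

The raw stack (not the denoised one) is normalized by its global maximum —
per-slice normalization would make `holesThr` mean different things on
different slices — inverted, median-filtered per slice, and thresholded with
`≥ holesThr` for hole membership. The "large" median radius is not dictated
by the method; the default is 10 px, exposed as `holes_median_radius`. The
filter runs on an 8-bit quantization of the inverted image so the fast rank
median applies; the half-gray-level quantization error is negligible at
these radii. The projection (sum over z) preserves total hole volume
exactly, by exchange of sums.

## Density

ROI polygons live in pixel coordinates and are converted to μm only at area
computation, avoiding mixed-unit geometry. Point-in-polygon is strictly
interior (boundary centroids are not counted), consistent with the
exclusion-border philosophy and deterministic. `dn` is reported as undefined
(None / NaN) when the hole volume reaches the prism volume, never silently.

## Synthetic stacks

The generator emulates: 8-bit, 15-slice stacks; bright Gaussian puncta
(radius ρ ~ U[4, 8] px, in-plane σ = ρ/2, axial σ scaled by
`pixel_size_xy / z_step`), peaks U[100, 200] over a diffuse background of 40,
additive Gaussian noise σ = 8 (peak SNR ≥ 12.5; optional Poisson), and dark
through-cylinders at 5% transmission for holes. Puncta are Gaussian rather
than hard spheres precisely so MaxLoGs' scale selection is exercised. The
default in-plane sampling of 0.066 μm/px corresponds to a 63× oil objective
at near-Nyquist zoom and puts the blobs at bouton-like physical radii
(0.26–0.53 μm); with the 0.14 μm z-step the axial-to-lateral sigma ratio is
≈ 0.47, so blobs span a few slices of a 15-slice stack. Centers are sampled
with margins (2.5ρ in-plane, ~2.5 axial sigmas in z) and pairwise in-plane
separation ≥ ρᵢ + ρⱼ so that planted objects are resolvable and none touches
a stack face — making the planted count directly comparable to the
stereological count. When separation cannot be honoured the generator falls
back to overlapping placement with a logged warning.

What the generator does *not* model: the confocal PSF (blobs are ideal
Gaussians), intensity attenuation with depth, chromatic or stage drift,
autofluorescence texture, and clustered (non-uniform) punctum positions.
Passing recovery tests therefore demonstrate the pipeline's correctness and
self-consistency on well-posed inputs, not its accuracy on real tissue —
on real stacks expert disagreement itself is large (see the packaged
validation tables, where the two experts differ by a factor of two on some
samples).

## Benchmarks and problem sizes

The end-to-end benchmarks used by the tests and the acceptance script run on
15 × 512 × 512 stacks — half the linear field of the original acquisitions —
with 150 planted puncta (recovery) and 120 puncta plus a cylinder occupying
25% of the volume (hole correction). These sizes exercise every stage at
realistic object densities while keeping a full run in the tens of seconds
on a single core; results on the full 1024² field are statistically
identical since all stages are local.

The packaged CSV tables under `punctakit/data/` are the published expert
validation counts and per-sample precision/recall/F1 for the vGlut-1 and
vGAT hippocampal benchmark; the published F1 column is reproduced from the
2-decimal precision/recall within the ±0.01 input-rounding band (after
rounding the recomputed value to 2 decimals — one vGAT row, X13_Y7/expert 2,
is internally inconsistent by 0.015 at full precision and consistent only
under this reading).

## Known limitations

* The tag-propagation labeler is O(n log n) in foreground pixels but runs in
  pure Python; very dense foregrounds (>10⁶ foreground pixels per slice) are
  slow.
* Stacks are processed whole in memory; tile scans should be iterated
  file by file (each stack is independent).
* Surface areas use face counting and overestimate smooth surfaces by up to
  ~50% (the classic voxelization bias); they are comparable between objects,
  not absolute.
* On stacks containing no real puncta the automatic threshold adapts to
  noise and reports spurious objects; this is inherent to per-stack
  auto-thresholding and is why validation counts on near-empty regions have
  large relative errors. The holes mask can be used to filter out regions
  where no puncta are expected.
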