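# punctakit

Detection and quantification of fluorescent **puncta** — small bright spots
marking presynaptic axon terminals (e.g. vGlut-1 for excitatory, vGAT for
inhibitory terminals) — in shallow 3D confocal stacks, with
stereology-corrected estimation of puncta density in the **neuropil**.

It is written for neuroanatomists and image-analysis engineers who need to
count many thousands of low-SNR objects across large tile-scanned regions
without deconvolution, training data, or per-stack manual thresholds.

## Method

For a stack `I(x, y, z)` the pipeline is:

1. **Segmentation (MaxLoGs).** Each slice is filtered with a scale-normalized
   negative Laplacian-of-Gaussian at radii `r = r_min, r_min+δ, …, r_max`
   (`σ = r/2`); per pixel the maximum response over scales is kept, so blobs
   of any radius in `[r_min, r_max]` respond strongly. The pooled response
   histogram is binarized with Tsai's moment-preserving threshold (Otsu
   available via `thr_method`).
2. **Denoising.** A two-scale median filter (disk radius 1, then 2) applied
   per slice to the raw stack.
3. **Fusion.** Pixel-wise minimum of the rescaled binary mask and the
   denoised stack: foreground keeps its denoised intensity, background is 0.
4. **Tagging.** Per slice, tags propagate from the relative maxima of the
   intensity (tolerance `toll` controls how much two maxima may differ before
   they are considered one object). Objects `i, j` on adjacent slices are
   joined into one 3D object when the Bhattacharyya coefficient between their
   normalized intensity distributions,
   `BC(i,j) = Σ_(x,y) √(NI(i,x,y)·NI(j,x,y))`, exceeds `ϕ`. Objects smaller
   than `minSize` voxels are dissolved into their largest-contact neighbour
   or the background.
5. **Holes.** Somata, vessels and section artifacts appear as large dark
   regions; they are found by inverting the normalized image, median
   filtering with a large radius, and thresholding at `holesThr`. The binary
   holes stack is projected along z into a 2D counts mask.
6. **Density.** For a 2D polygonal region `R` extruded through the stack
   depth `δ`, the volume number density is `d(R) = N_s(R) / V(R)` with
   `V(R) = A(R)·δ`, where `N_s` counts centroids of objects not touching the
   three exclusion faces of the stack (unbiased stereological counting).
   The neuropil density subtracts the hole volume:
   `dn(R) = N_s(R) / (V(R) − H(R))`.

Default parameters: `r_min = 4`, `r_max = 10`, `δ = 1`, moments threshold,
`ϕ = 0.4`, `minSize = 40`, `toll = 0`.

## Worked example

Generate a ground-truthed synthetic stack (30 Gaussian puncta, radius 4–8 px,
on a noisy background), detect, validate against the planted centers, and
estimate the density over a full-frame ROI:

```
$ punctakit simulate --out-dir sim --seed 5 --shape 15 256 256 --n-puncta 30
wrote synthetic stack with 30 puncta to sim

$ punctakit detect sim/stack.tif --out-labels labels.tif \
      --out-centroids centroids.csv --pixel-size 0.066 --z-step 0.14
30 objects detected (threshold 16.15)

$ punctakit validate --labels labels.tif --points sim/puncta_truth.csv
algorithm=30 expert=30 correct=30 precision=1.00 recall=1.00 f1=1.00

$ punctakit density --centroids centroids.csv --roi roi.geojson \
      --n-slices 15 --pixel-size 0.066 --z-step 0.14 --out density.csv
roi 0: N=30 d=0.05004 dn=0.05004 /um^3
```

All 30 planted puncta are recovered one-to-one (precision = recall = 1), and
the measured density, 0.05 puncta/μm³, equals the planted 30 objects over the
256 × 256 px × 15-slice prism (285.5 μm² × 2.1 μm ≈ 599.5 μm³; 30/599.5 =
0.05004). With a
holes mask (`punctakit holes`) the `dn` column additionally corrects for
non-neuropil volume.

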