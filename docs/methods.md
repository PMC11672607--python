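# Methods

## The model

morphoseg treats segmentation as a pipeline of deterministic set and order
operations rather than a learned model. Its core assumption is that the
objects to be found are *pigmentation-coherent*: each object is a connected
patch whose color occupies a distinct mode of the image's color
distribution, separable by a small k-means palette. That is the regime of
uniform-coat livestock against pasture/sky, and the regime the synthetic
scenes emulate. Objects whose identity rests on texture or on color shared
with the background are outside the model.

Stages, in execution order, with the quantities that matter:

**Resize / normalize.** Optional bilinear downscale so the longest side is
`max_dimension` (default: none — no resizing); global min–max stretch of
intensities to [0, 255] when the dynamic range is narrower, with constant
images left untouched. Normalization makes the fixed edge threshold and the
palette comparable across exposures.

**3-D median filter.** `median_filter_3d` computes, for every output cell,
the exact median of a (rows × cols × channels) neighborhood with all-odd
kernel (default (5, 5, 5)) and reflected borders (the border sample is
included in the reflection, so a 3-channel axis supports a 5-tap kernel).
The kernel should track the smallest feature worth keeping: features
smaller than the kernel are treated as noise. Because the channel axis is
part of the neighborhood, the filter *mixes channels*: for a constant-color
interior each output channel is a weighted median of the three channel
values, so a saturated pure-red patch collapses toward its smallest channel.
Low-saturation colors (channel spread small against inter-object contrast)
pass through essentially intact; this is why the synthetic palette is
coat-like rather than primary-colored, and it mirrors the field situation —
animal coats and pasture are low-saturation, and detection rides on
brightness/pigmentation contrast.

**Quantization.** `fit_quantizer` is standard k-means (k-means++
initialization, 10 restarts, fixed `seed`) on the N×3 pixel table; k = 8 by
default. `assign_labels` is an explicit nearest-centroid scan with
squared-Euclidean distances and lowest-index tie-breaking — implemented
directly rather than through the fit object's predictor so the tie-break is
specified, and cross-checked against a brute-force scan in the tests.
Centroids stay real-valued in the model; colors are rounded half-up only
when an image is rebuilt, then widened to uint32. If the data hold fewer
than k distinct colors the fit degenerates to duplicate centroids; the model
is returned with a logged warning, since the reconstruction is still
well-defined. Fitting with k larger than the number of natural color modes
spends the surplus centroids on the highest-variance mode (in practice the
textured background), which fragments the background but leaves
constant-color objects intact.

**Edge detection and zeroing.** Directional responses are correlations with
the 3×3 Sobel kernels (a plain ±1 difference kernel is available), reflected
borders, computed on the *cluster-label grid* by default: after quantization
the label image is the cheapest single-channel carrier of region structure,
and any nonzero gradient on it marks a palette boundary. Hence the merge
rule |h| + |v| > threshold with threshold 0. On photographic single-channel
input (the `conv_input="gray"` path, fed by the dominant-intensity channel)
a nonzero threshold is appropriate. Zeroing sets flagged pixels to color 0
and label −1; the label sentinel is negative so it can never collide with a
cluster index. One consequence: each object loses a one-pixel boundary
ring, so measured extents are one pixel tighter per side than the painted
object — shape kernels describe the segment as the pipeline sees it.
A second consequence: with k = 1 the quantized image is constant, nothing
is flagged, and the whole frame survives as a single region (the degenerate
run completes; it does not produce zero regions, because the single cluster
does not collide with the reserved sentinel).

**Region isolation.** Connected components of equal label among
non-background pixels, 4-connected by default (8-connectivity is a flag),
labeled 1, 2, … in raster order of each component's first pixel, filtered by
`min_area` (default 1; the pipeline examples use 25 — the 5×5 spatial
footprint of the default median kernel — so that residual background
speckle smaller than the smallest preservable feature is dropped). Each
region's center of mass is the unweighted mean (row, col) of its pixels:
every member pixel counts once, i.e. "weight" means membership, not
intensity.

**Shape validation.** `measure_extents` measures from an anchor to the
mask's *bounding box* (up = anchor_row − min set row, etc.); components
where the anchor lies beyond the box are clamped to 0 and flagged. The
bounding-box reading reproduces a rectangular region-of-interest template
exactly; a per-ray mode (contiguous runs from the anchor) is available for
concave masks. The anchor is the center of mass rounded half-up to a pixel.
A segment is valid iff every |measured − target| ≤ tolerance (scalar or
per-direction; default 0). Tolerance 0 is strict and appropriate for
synthetic or template-derived kernels; real photographs call for a few
pixels of slack. Binary morphology (cross / ellipse / rectangle elements;
erode, dilate, open, close with background-padded borders — the semantics
of a finite-support set in an unbounded plane) is provided for pre-filters
but is not applied implicitly before validation.

**Delivery.** Valid segments are extracted bit-exactly from the original
image (masked-full or cropped), optionally annotated (1-px red bounding
square of radius `box_radius` around the anchor — default
max(kernel extents)+2 when a kernel is set, else ⌈√area⌉/2 — plus the
kernel's target-extents rectangle when one is configured), and recorded in
a metadata document `{"run": {...}, "objects": [...]}` serialized with
sorted keys. Filesystem paths are excluded from the persisted parameters,
so identical config + seed reproduces the metadata byte for byte.
Refinement is by re-invocation with an edited config, not interactive state.

## Synthetic scenes: what they emulate, and what not

`generate_scene` renders a Gaussian-textured background (base color +
clipped noise, default sd 6 — a stand-in for grass/sky texture, which the
median filter is expected to homogenize), solid rectangular or elliptical
blobs with declared centers, extents and colors, and optional salt-and-pepper
impulse noise for the median filter to remove. Blobs must be in-bounds,
pairwise disjoint, and all scene colors pairwise ≥ 32 apart in L∞ so the
palette survives quantization; the default palette is low-saturation
(coat-like) so it also survives the channel-mixing median filter, as argued
above. Ground truth carries the exact pre-noise masks, centroids and the
impulse pixel list.

What the scenes do *not* emulate: structured texture (grass blades, cloud
gradients), shading and specularity, partial occlusion, soft object edges,
and objects sharing a color mode with the background. Passing the synthetic
suite therefore shows the machinery is correct under the pigmentation-
contrast assumption; it does not certify performance on photographs that
violate it.

The end-to-end study conditions, fixed once: twenty scenes of 96×128 px,
3–6 blobs each on a six-slot grid, six coat-like colors, background sd 6,
1% impulse noise, k = 8, seed 0, min_area 25, tolerance 0. Under these
conditions the suite checks that ≥ 95% of blobs are recovered with centroid
error ≤ 2 px and that the designated blob's extent template validates
exactly one segment per scene.

## Numerical choices

- Coordinates are 0-based (row, col), row 0 at the top; "up" = decreasing
  row. Bounding boxes use inclusive endpoints everywhere.
- Rounding is half-up (⌊x + 0.5⌋) wherever a real value becomes a pixel or
  a palette color; numpy's ties-to-even is deliberately not used.
- Median and extent computations are exact integer order statistics — no
  floating-point medians on even counts can arise (kernels are all-odd).
- Nearest-centroid ties break to the lowest index; channel-sum ties in
  dominant-channel selection break to the lowest channel.
- Degenerate inputs: constant images pass normalization unchanged; empty
  masks raise; an anchor outside its own mask is measured against the
  bounding box anyway and flagged in the record (`origin_in_mask=False`).

## Known limitations

- The uint32 output is a widening cast per channel, not a packed integer;
  `pack_rgb` offers the packed view when a single-integer pixel is needed.
- Edge zeroing consumes a one-pixel boundary ring per object; very thin
  structures (≤ 2 px) can vanish entirely.
- Shape validation is axis-aligned and scale-sensitive by design; rotated
  or rescaled objects need their own kernels.
- k is fixed per run; there is no automatic palette-size selection.
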