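# Methods

This note documents the models, numerical choices and validation
strategy behind `nlcmorph`.  It is written for users who need to know
what the numbers mean and where the defaults come from.

## Coordinate system and geometry

All physical quantities are in millimetres.  The grid-based frame is
used: x grows with the column index × column pixel spacing (sagittal),
y with the row index × row pixel spacing (coronal), z with the slice
index × the inter-slice spacing δ (depth).  The origin is the centre of
the upper-left voxel of the first slice.  δ is taken from the
differences of the third component of consecutive Image Position
(Patient) tags, not from the slice-location annotation: positions
define the geometry, locations merely annotate it, and the consistency
checker reports any disagreement between the two.  A volume that fails
the consistency check (non-uniform spacing, non-canonical orientation
cosines, location/position mismatch) is refused by all volumetric
operations rather than silently measured.

Slices are ordered by ascending z.  Which end of the canal is cranial
(orbital) is a per-volume flag, `cranial_end ∈ {low-z, high-z}` with
default `low-z`; scanner table direction is acquisition-dependent and
cannot be inferred from the grid alone.

The voxel volume is pixel-spacing-row × pixel-spacing-col × δ.  The
nominal slice thickness may substitute for δ only when the slices are
confirmed contiguous (no gap/overlap), in which case the two agree
anyway.

## Segmentation

The canal lumen is a low-attenuation channel inside a thin bone wall.
The wall of the lacrimal canal is frequently thinner than a voxel and
its apparent HU is depressed by partial volume, so plain thresholding
of "bone" fails to close the ring.  The per-slice segmenter therefore:

1. thresholds bone at `bone_hu` (default **300 HU**);
2. morphologically closes the bone mask with a disk of radius
   `closing_radius_mm` (default **0.6 mm**) to seal sub-voxel wall
   gaps;
3. labels the 8-connected sub-threshold components and keeps those
   that are *enclosed* (do not touch the image border) and whose area
   lies in `[min_area_mm2, max_area_mm2]` (defaults **0.5–120 mm²**);
4. reclaims, by geodesic dilation limited to the closing radius, the
   boundary ring of sub-threshold pixels that step 2 converted to
   bone — the closing fixes topology but must not shrink the
   pixel-count area;
5. fills interior holes (the area measures the canal cross-section,
   holes are segmentation artefacts);
6. picks the component containing the seed, else the nearest one
   within `max_centroid_jump_mm` (default **3 mm**); ties break by
   smaller centroid displacement, then smaller area change.

Across slices the canal is tracked with the previous centroid as seed;
tracking stops when no admissible component exists or mask overlap
(intersection over the smaller area) drops below `min_overlap`
(default **0.25**).  The initial region is detected in the left or
right half-image window, taking the slice whose best in-window
candidate is largest.  All parameters live in `SegmentationParams`
(loadable from a `key = value` text file); the defaults were calibrated
on phantoms.

Areas are exact pixel counts × pixel area — no smoothing or sub-pixel
correction is applied to the count.  Centroids are the unweighted
arithmetic mean of member-pixel centres (the standard binary-region
centroid); intensity weighting was considered and rejected as the
cited convention is the unweighted form.

## Axis models

From the centroid sequence `(c_1 … c_p)` with constant z-step δ, two
model families are built on the extended domain
`[z_1 − δ/2, z_p + δ/2]` (the outer faces of the delimiting slices, so
the domain width is exactly p·δ):

* **Polygonal**: segments joining the centroids, extended from the two
  extreme centroids along the terminal segment directions to the outer
  planes (p + 2 vertices).  The tangent exactly at an interior vertex
  is the renormalised mean of the adjacent segment directions.
* **Polynomial (degree 2/3/4)**: x(z) and y(z) fitted separately by
  least squares.  Internally the fit runs on z rescaled to [−1, 1]
  about mid-domain — raw powers of depths up to ~70 mm are severely
  ill-conditioned — and the coefficients are mapped back to raw z for
  reporting (highest degree first in tables, matching the conventional
  layout).

Goodness of fit is the squared Pearson correlation between fitted and
observed coordinate values; for least-squares fits with intercept this
equals the coefficient of determination.  Degenerate case: when the
observed coordinate is constant (a perfectly straight canal) the
correlation is 0/0; we report r² = 1 when the residuals also vanish
and 0 otherwise.  Sufficiency is assessed via the Fisher
transform z = atanh(r) with standard error 1/√(p − 3): the 95%
confidence interval of r is mapped back through tanh, and the fit is
flagged sufficient when the implied lower bound of r² is ≥ 0.95.  With
p ≤ 3 the interval is undefined and the flag is indeterminate.

## Lengths

* **AxL** = p·δ (distance between the outer faces of the delimiting
  slices).
* **ExL** = Euclidean distance between the canal central points on the
  outer delimiting planes.  These endpoints are taken from the
  polygonal extensions, which makes AxL ≤ ExL ≤ PolygL an exact
  triangle-inequality chain rather than an approximate one.
* **PolygL** = sum of all p + 1 segment lengths.
* **Polyn{2,3,4}L** = arc length ∫√(1 + x′² + y′²) dz over the
  extended domain by adaptive quadrature with absolute tolerance
  10⁻³ mm.

## Cross-sectional areas

Per slice, the axial area A_k is the pixel count × pixel area.  The
orthogonal area is computed two ways:

* **Projection** (default): A_k⊥ = A_k · cos β_k, where cos β_k is the
  z-component of the unit axis tangent at the slice z.  Valid when the
  canal path does not change abruptly; implies A_k⊥ ≤ A_k always.
  An axis tangent with non-positive z-component (a canal doubling
  back) invalidates the method and is rejected.
* **Reslice** (reference): the volume is sampled on a regular grid in
  the plane through the axis point orthogonal to the tangent (cubic
  interpolation, grid step = the finer pixel spacing, field of view
  20 mm) and the resliced image segmented with the same rules; the
  area is again a pixel count.  When the tangent is axial the sampling
  grid snaps to the voxel lattice, so the reslice degenerates exactly
  to the axial measurement.

When both are available the pipeline cross-checks them on interior
slices and warns if they disagree by more than 10% anywhere (the
outermost slices are excluded: an oblique plane there leaves the canal
through its opening, so the comparison is meaningless).  Minimum-area
variables search over slice z-positions only (areas exist only there);
ties break toward the cranial end.  The minimum's depth is the
craniocaudal (z) distance to the cranial outer delimiting plane, not
an arc distance.

Volume is pure voxel summation (masked voxel count × voxel volume),
identical to δ·ΣA_k by construction.  No wedge correction is applied
at the canal ends where the true delimiting plane is oblique to the
slice faces; over a 7–22-slice canal the missing/extra end wedges are
sub-voxel effects.

## Surface model

Per-slice masks become 2-D signed distance fields (positive inside),
z-padded with the negative magnitude of the end-slice fields — linear
interpolation then crosses zero exactly halfway, producing flat end
caps on the outer delimiting planes — resampled to a near-isotropic
grid, Gaussian-smoothed, and contoured at level 0 with marching cubes.
The result is watertight.  The smoothing width is
`smoothing × in-plane voxel size`; the default 0.5 was calibrated on
cylinder phantoms (staircase artefacts removed, enclosed volume within
~2% of the voxel sum; larger widths progressively shrink convex
shapes).  `smoothing = 0` returns the exact blocky voxel-boundary
mesh, whose enclosed volume equals the voxel sum identically.

## Phantoms and what the tests show

A phantom is a tube with a polynomial centreline (degree ≤ 4), a
circular orthogonal cross-section of radius r(z) (constant, linear
taper, or quadratic waist), a constant-thickness bone wall, and solid
bone caps beyond the canal's slice range (so tracking terminates).
Membership is decided by distance to the local tangent line of the
axis — exact for straight tubes and accurate for the gently curved
validation axes (curvature radius ≫ tube radius).  Rasterisation uses
4× supersampled occupancy per axis (64 sub-samples per voxel),
emulating partial volume; optional i.i.d. Gaussian HU noise emulates
quantum noise.  Defaults mirror the study's acquisition: δ = 0.625 mm,
pixel spacing 0.3 mm (acquisitions ranged ≈0.293–0.418 mm), canal
slice counts within the observed 6–22, lumen radius 2 mm, lumen
−50 HU, wall 650 HU (thin lacrimal walls sit well below cortical
bone), background −1000 HU.  The lumen/wall levels deliberately
straddle the 300 HU threshold at their midpoint so that
boundary-voxel classification is unbiased under partial volume.

Ground truth is computed independently of the imaging pipeline: axial
area πr²/cos β, arc length and tube volume ∫πr² ds by dense
trapezoidal quadrature (2×10⁵ nodes).

What passing phantom tests do **not** show: real canals have irregular
(non-circular) sections, inhomogeneous walls with genuine gaps,
surrounding anatomy that can present competing low-HU components, and
spatially correlated CT noise.  The phantoms validate the geometry and
measurement chain, not the segmenter's robustness to real anatomy.

Problem sizes used in the validation suite: grids up to 96×96×26
voxels, canal slice counts 6–22, one noisy regression phantom at
20 HU with a fixed seed.  Typical measured recovery on noise-free
phantoms: lengths within 0.3%, mean areas within 2%, volume within
1.5%, waist depth within one slice spacing.

## Reference verification

The published six-subject degree-3 axis-model table (coefficients to
4 decimals, r² per coordinate, extended z-range, slice count) is used
as a verification fixture.  The underlying per-subject centroid
sequences are supplementary data that cannot be redistributed, so the
tests rebuild a **synthetic stand-in** per subject: centroids at the
slice depths of the printed z-range, coordinate values equal to the
printed polynomial plus a pseudo-random residual projected orthogonal
to the degree-3 design space (QR projection, independent of the
fitting code) and scaled to the printed r².  By construction a
least-squares refit must return the printed coefficients and r²
exactly — the stand-in therefore verifies the fitting machinery,
coefficient conventions and table layout, not the provenance of the
original centroids.  One printed value required interpretation: a
thousands separator in one subject's x-intercept (read as 1001.4566).
The printed z-ranges equal the extended domains (z_max − z_min =
n_slices × 0.625 for every subject), which fixes the centroid depths
unambiguously.

Axis recovery on phantoms is quantified in curve space — the relative
L2 error of the fitted coordinate functions over the centroid z-range
— rather than as a raw-coefficient distance, because raw-z coefficient
vectors are exactly the ill-conditioned representation the fitting
deliberately avoids; the curve-space error is basis-independent and
is what any downstream length/area computation consumes.

## Known limitations

* The laterality detector is a half-image window; heavily rotated
  acquisitions need an explicit seed.
* The projection area method degrades near canal openings under
  extreme obliquity (≳60°); the reslice method is the reference there.
* Multi-frame/enhanced DICOM, gantry-tilted geometry and
  contrast-enhanced protocols are unsupported.
* Anteroposterior/transverse diameters are not computed.
* Descriptive statistics only; hypothesis testing is left to external
  statistical software via the CSV export.
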