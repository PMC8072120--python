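# Methods

This note documents the models, operationalizations and numerical choices
behind `petalign`, in the order of the pipeline.

## Coordinate conventions

Pixel coordinates are 0-based `(x, y)` pairs, x rightward, y downward,
continuous (sub-pixel allowed), with a pixel's center at integer
coordinates. Vein and boundary polylines are stored distal→proximal; the
closed petal outline is stored starting from the left rim endpoint. An
annotation lives natively on the backlit (histological) image, where
anatomy is selected, and is transported to fresh-image coordinates by the
registration step; `frame_of_reference` records which space it is in.

## Segmentation

A 2-component Gaussian mixture (full covariance, k-means initialization,
fixed seed) is fitted in RGB to a uniform random subsample of at most
50,000 pixels, and every pixel is assigned to a component. The foreground
component is chosen by mean BT.601 luminance — brighter for fresh scans
(petal on dark cloth), darker for backlit scans (`foreground="dark"`). The
mask is closed with a 3 px disc, hole-filled, and reduced to its largest
connected component; the contour is traced at sub-pixel resolution and
resampled to 400 vertices by uniform arc length. Defaults balance
serration preservation (small closing radius) against scan noise. A
single-color image, or mixture components closer than 2 gray levels in
mean luminance, raise a "no contrast" error; a mask touching all four
image borders sets a `clipped` warning flag.

Invariances: re-running the morphological post-processing is a no-op, and
any channel-wise brightness map that preserves the ordering of the two
component means leaves the mask essentially unchanged.

## Registration

Histological→fresh registration is a least-squares planar transform on
paired landmarks: similarity (2+ pairs), affine (3+), or projective (4+,
the default — two flatbed passes of the same flattened petal can differ by
placement, scale and mild shear, all subsumed by a homography). Estimation
uses the normalized direct linear transform; collinear source points are
rejected. No outlier rejection is applied by default (control points are
few and manual). The root-mean-square residual is reported with the
transform and is non-increasing in model degrees of freedom.

## The canonical frame and the 161-point correspondence

The frame is a half-circle of radius R = 128 px (lobe) on a rectangle of
height H = 64 px (the annotated distal portion of the tube), giving a
256 × 192 raster with the apex on the top row. 161 destination points are
allocated 61/26/22/22/15/15 to the contour arc (uniform in angle,
180°→0°), the midvein center line, the two side-vein lines (abscissa
x = R ± R/2, from their intersection with the semicircle to the bottom
edge), and the two tube boundaries (the rectangle's vertical sides). Only
the total of 161 is canonical; the split and the side-vein abscissa are
configurable and recorded in output metadata. The annotated tube extent is
treated as already cropped (the physical cut at acquisition defines the
proximal edge); no computational re-cropping is applied.

Source points are resampled from the mapped anatomy by uniform arc length,
anchored at the rim endpoints (contour arc), at the distal/proximal line
ends (veins and boundaries). Stored vertex order is normalized
distal-first, and left/right labels are checked against the contour
orientation and swapped with a warning if mirrored.

Five destination points coincide by construction (midvein top = apex;
side-vein tops on the arc; tube-boundary tops at the rims). Before
triangulation, coincident destinations are merged and their sources
averaged; for a consistent annotation the corresponding sources coincide
too, so exact interpolation of all 161 pairs is preserved.

## Warping

The warp is piecewise affine over the Delaunay triangulation of the
(deduplicated) destination points: for each output pixel, barycentric
coordinates in its destination triangle are applied to the three source
vertices, and the fresh image is sampled bilinearly at the mapped
position. This is the classic control-point warp; it interpolates every
landmark pair exactly, which the test suite verifies to ≤ 0.5 px and is in
practice at floating-point precision. A single least-squares global affine
is available as a comparison fallback (`method="global_affine"`); with 161
pairs it cannot interpolate and exists only as a baseline.

The validity mask is the intersection of the destination points' convex
hull, the frame region (semicircle ∪ rectangle), and the set of pixels
whose mapped source position falls inside the image; it covers ≈ 99.6% of
the frame interior for a well-formed specimen. Source triangles collapsing
to zero area are excluded from the mask with a warning. Sampling
coordinates are clipped into the image domain so that border pixels kept
by the half-pixel validity bound sample the border rather than the
constant pad. Pixels outside the mask are zero. The warp is deterministic:
identical inputs give bit-identical rasters.

The frame's top corners are *not* added to the triangulation: they lie
outside the frame interior (the lobe is a half-circle) and have no source
anatomy; the bottom corners already coincide with tube-boundary
destination points.

## Pattern quantification (pixel PCA)

ROIs are converted to BT.601 grayscale on [0, 1], restricted to the
intersection of all validity masks (recorded with the model), and
flattened row-major. The specimen × pixel matrix is decomposed by
mean-centered SVD on raw (unstandardized) pixels. `min(n−1, p)` components
are retained, including numerically-zero-variance ones (ratio 0), so that
deviation maps of flat components are queryable. Signs are fixed by
orienting each loading so its largest-magnitude element is positive; all
downstream statistics are sign-invariant. Scores are standardized with the
sample SD (ddof = 1), which is also the σ_k used by the inverse-PCA
reconstructions: `virtual_roi(k, s) = mean + s·σ_k·loading_k` (clipped to
[0, 1] for display), and the deviation map `|virtual(+2σ) − virtual(−2σ)|
= 4σ_k·|loading_k|` computed before clipping.

When generative pattern fields are not mutually orthogonal, PCA recovers
their span only up to a rotation; `amplitude_recovery_r` therefore matches
axes by the best linear recombination of the top components (multiple
correlation) when testing amplitude recovery.

## Mode classification

The four patterning modes are defined visually/developmentally; this
module is an explicit geometric operationalization, with every threshold
in one `ModeConfig` block so sensitivity analyses are scriptable:

- **Pigment score**: median gray of valid pixels minus pixel gray —
  positive where darker than the petal ground color and invariant to
  global brightness shifts. A flag inverts polarity for pale-on-dark
  guides.
- **Pigment mask**: threshold at `max(Otsu of positive scores,
  min_contrast = 0.08)`; a specimen has pigment only if the masked
  fraction reaches `min_fraction = 0.005`.
- **Evidence split**: connected pigment components with area ≥ 50 px that
  contact the distal arc or the proximal edge over at least 20% of that
  border's width (`anchor_frac`) are *gradient evidence*; the rest is
  *interior* (variegated) evidence. The broad-contact requirement keeps a
  vein corridor that merely crosses a border from counting as a gradient.
- **Gradient label**: the longitudinal profile (mean pigment score per
  row, over valid pixels) is computed on the field restricted to gradient
  evidence; `gradient_delta` = mean over the apical third − mean over the
  proximal third; distal if > 0.04, proximal if < −0.04, else none.
  Restricting to anchored evidence — rather than using the raw field —
  matters because the frame narrows to zero width at the apex, where a
  vein corridor would otherwise dominate the apical mean and fake a
  distal call on purely vascular petals.
- **Variegated label**: the vein corridor is the destination vein lines
  dilated to half-width 6 px; `vein_enrichment` = (interior pigment
  fraction inside the corridor) / (corridor area fraction); vascular if
  ≥ 1.5, random below, none without interior pigment. Within each family
  labels are mutually exclusive by construction.

Species aggregation is a majority vote among non-none specimen labels per
family; "none" wins only if at least half the specimens are none; ties
break toward the larger mean supporting score (|delta|, enrichment
distance from threshold).

## Association statistics

Cross-tabulation counts species per (pollination type, mode) cell,
excluding undetermined types. Pearson's χ² is computed without continuity
correction (which reproduces the published statistics for the bundled
tables exactly); zero-marginal rows/columns are dropped with a warning
before computing df.

The LOD score is `(n/2)·log10(SST/SSW)` with SSW the within-pollination-
type sum of squares. Degenerate separation (SSW = 0) is an explicit
error. The permutation test shuffles the score/label pairing (default
10,000 times) and reports the add-one p-value `(1+b)/(N+1)`, which cannot
reach zero; when no null value attains the observed LOD the result is
flagged `floored`, i.e. p is below the test's resolution — the package
never extrapolates beyond it. No multiple-testing correction is applied
across PCs; p-values are reported raw and this is deliberate.

Stepwise regression is forward–backward OLS with partial-F thresholds
p_enter = 0.05 / p_remove = 0.10. The pollination response is coded
bee = 0, hummingbird = 1 by default (other types excluded — the
quantitative association analysis is restricted to the two
well-replicated types); the coding is configurable and recorded in the
result. Entry α-inflation across candidates is inherent to stepwise
selection and acknowledged rather than corrected. Forward entry stops
once the fit is numerically perfect (residual < 1e−10 of total SS), since
rounding noise would otherwise admit every remaining predictor. Rank
deficiency (e.g. a duplicated predictor) blocks entry.

## Synthetic specimens

The generator emulates the two acquisition products. A petal is a serrated
half-ellipse lobe (radial serration, an even harmonic so apex and rims are
unperturbed) on a linearly tapering tube; the midvein runs apex→base, side
veins from their lobe-boundary intersection at half the lobe radius. The
fresh image renders the silhouette in a pale base color on a dark field
(gray ≈ 10); pigment subtracts a fixed color vector scaled by per-mode
intensity fields: linear gradients spanning 45% of the petal length
anchored at either end, a soft vein corridor (half-width 5 px), and
off-vein Gaussian blobs constrained away from borders and veins. Additive
Gaussian noise (SD 2 gray levels) is applied. The backlit twin re-renders
the geometry under a recorded random projective perturbation (±8°
rotation, ±5% scale, mild shear and perspective) with darker tissue on a
bright field and visible veins; control points are the serration tips, rim
endpoints and tube corners, transformed exactly. Truth labels follow the
amplitudes (zero amplitude ⇒ none; vein and spot modes are mutually
exclusive by construction).

Cohorts draw species-level base shapes (lobe radius 72–104 px, aspect
1.05–1.45, serration depth 2–4 px, tube length 100–140 px, taper
0.65–0.85) and 3% within-species shape jitter from a single master seed
via spawned per-species/per-specimen sequences, so any specimen is
individually regenerable. Shapes vary strongly between species on
purpose: the method's claim is alignment across shapes, and the unaligned
pixel comparison (centroid-centered, isotropically area-normalized, union
of petal masks) is kept as a documented negative control that must fail
where the homologous warp succeeds.

What the generator does **not** emulate: petal texture and trichomes,
specular artifacts, color calibration drift, vein branching beyond the
three primary veins, and fixation-induced deformation beyond a global
projective map. Passing tests therefore demonstrate correctness of the
geometry and statistics under idealized imaging, not robustness to
real-scan artifacts.

## Problem sizes and tolerances in the test suite

The end-to-end cohorts are 40 specimens (4 species × 10, one pure strong
mode each) for mode recovery and 60 specimens (6 species × 10, independent
distal/proximal amplitudes) for PC–amplitude recovery; images are roughly
300 × 350 px. These sizes exercise every stage while keeping the full
suite under a minute of compute. Shape-homology comparisons erode the
common validity mask by 2 px before computing RMS: the contour-adjacent
ring is dominated by rasterization aliasing of serrated edges
(sub-landmark-scale noise), not by alignment error. The permutation
calibration uses 999 shuffles per replicate over 200 replicates.

## Known limitations

- The mode thresholds were chosen for darker-than-ground guides at
  moderate amplitude; faint patterns near `min_contrast` will be called
  none.
- Higher-order vein patterning (pigment following secondary veins, or
  evading them) is outside the three-vein correspondence and is not
  classified.
- The warp assumes the annotated anatomy is complete and the petal lies
  flat; folds or tears violate the piecewise-affine model silently.
- Quantitative association is restricted to two pollination types by the
  default response coding; multi-class codings must be supplied
  explicitly.
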