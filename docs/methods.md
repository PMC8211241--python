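# Methods

This note records the model behind `thoraseg`, the parameter choices
that matter, what the synthetic phantoms do and do not emulate, and the
numerical conventions the implementation fixes where the procedure
itself leaves them open.

## The segmentation model

The pipeline assumes a non-contrast mouse thorax scan in which four
density populations are separable in one dimension: air-filled lung,
an intermediate population (ground-glass-like lesions, vessel partial
volume, mild motion blur), solid soft tissue (heart, mediastinum,
tumor), and bone. It makes no use of a calibrated intensity scale —
bone is found by a data-driven threshold and the three soft classes by
a per-scan 1-D k-means — so the method tolerates scanner drift and
reconstruction differences. The corollary is that classes are defined
*relatively*: a scan consisting almost entirely of one density would
still be split into three clusters. The pipeline is therefore a
composition readout, not a detector of individual nodules.

### Thoracic mask

- **Bone threshold** (`bone_threshold="auto"`): Otsu's threshold
  computed on intensities above the volume median. The rule assumes
  the animal (not air) dominates the field of view, so the upper half
  of the histogram contains the soft-tissue and bone modes. A fixed
  scalar can be supplied instead.
- **Largest 3-D component** (26-connectivity by default) isolates the
  ribcage+spine skeleton. Exact ties are broken toward the component
  containing the smallest linear voxel index, so the result is
  reproducible.
- **Slice stacking** (`stack_window=3`, union): thin oblique ribs can
  miss individual slices; a 3-slice union restores per-slice support.
  Union rather than averaging preserves single-voxel-thin structure.
- **Outline**: per slice, boundary pixels of all bone regions with at
  least `min_region_px=3` pixels are pooled (the spine is included —
  it supplies the dorsal support of the outline), ordered clockwise
  (decreasing `atan2` angle starting at π; radial ties inward first),
  and interpolated with a closed periodic cubic spline sampled at 4×
  point density. Sparse control polygons (< 12 points) are first
  subdivided along their chords, because an interpolating cubic
  through widely spaced points overshoots its polygon; dense rib
  outlines are left free to bulge outward between ribs, which is the
  shape the cavity actually has. Self-intersecting contours fall back
  to the filled control polygon.
- **Two passes**: pass 1 uses every boundary point about the global
  ribcage centroid and only seeds pass 2, which re-centres on the
  pass-1 mask's own centroid (computed per slice) and keeps the
  innermost `refine_fraction=0.3` of points. The final slice mask is
  the pass-2 outline *intersected* with pass 1, so refinement can only
  shrink the cavity — this is what keeps intercostal muscle out on
  blurred scans. Slices whose outline cannot be formed inherit the
  nearest successful slice's mask only if it is within 2 slices;
  otherwise they stay empty rather than inventing anatomy.

### Density clustering

One k-means model is fitted per scan on the pooled in-mask intensities
(an intra-scan normalization; bone voxels are already excluded by the
mask). Seeding is k-means++; Lloyd iterations stop when assignments
stabilise or after `max_iter=100`. An emptied cluster is re-seeded at
the point farthest from its nearest centroid. By default the best of
`restarts=3` runs (lowest within-cluster SSE) is kept; `restarts=1`
reproduces a single-run regime. Exact intensity ties in classification
go to the lower-density class. Above 5·10⁶ voxels the model is fitted
on a deterministic stride subsample (classification still labels every
voxel); at the default grid this path is never taken.

An exact 1-D optimum (dynamic programming over contiguous partitions
of the sorted values, O(k·n²)) ships alongside as a reference; on
clustered arrays of ≤ 200 values the best-of-5 Lloyd objective stays
within 5 % of it (usually within 2 %).

### Axial bounds

- **Carina**: scanning caudally through the cranial quarter of
  nonempty mask slices, lung-class 2-D components of ≥
  `min_airway_px=4` pixels whose centroids lie within half the
  slice's equivalent cavity radius of the mask centroid are taken as
  the tracheal structure; the first slice with exactly two such
  components is the cutoff. Restricting the search to the cranial
  quarter avoids mistaking paired structures deep in the lung for the
  bifurcation. A manual override (`z_cranial`) exists for scans where
  detection fails.
- **Interface**: argmax over slices of (lung voxels / mask voxels);
  ties break caudally. Under extreme tumor burden the "highest lung
  percentage" definition could select an off-dome slice; this regime
  is logged, not corrected.
- **Diaphragm**: each in-mask (x, y) column's intensity trace from the
  caudal end to the interface is smoothed with a centred moving
  average (`smoothing_window=5`, chosen for robustness to voxel noise
  and validated against a closed-form logistic step, whose inflection
  it recovers within one slice); the inflection is the steepest
  descending gradient, and everything caudal of it is diaphragm.
  Columns with no descending gradient, or whose smoothed dynamic range
  is below noise (< 2 MADs of the raw trace), contribute nothing.
  Removal happens after classification, so a tumor sitting cranial of
  the dome surface stays in the counts.

## The phantom

`generate_phantom` builds, in image space, the anatomy the pipeline
relies on: a body ellipse filling most of the field of view; a helical
ribcage (arcs sweeping ~18° over the cage height) tied to a dorsal
spine and a cranial inlet ring so bone forms one 3-D component; an
elliptical cavity tapering toward the thoracic inlet; a solid
diaphragm dome (dome surface plus everything caudal of it — diaphragm
muscle and the abdominal tissue it rests on — carries one "diaphragm"
label, since that is precisely the material the z-trace inflection
removes); two lung fields whose cross-section peaks at the dome apex
and tapers toward hilum and costophrenic angles; an in-plane
intermediate rim on the lung margin standing in for ground-glass edges
and vessels; a heart ellipsoid resting on the dome; a tracheal column
splitting into two bronchi at the designed carina; and optional
spherical tumors (soft core, one-voxel intermediate halo) that
overwrite lung.

Default intensities are arbitrary units — lung 0.05, intermediate
0.35, soft 0.55, bone 1.0, Gaussian noise SD 0.03 per class — chosen
so class means sit > 4 SDs apart; only their ordering matters to the
pipeline. The default tumor-free composition (~45 % lung, ~36 % soft,
~19 % intermediate of the cavity) matches a healthy mouse thorax with
heart and mediastinum binned into soft tissue. Motion artifact is
modelled as in-plane Gaussian blur of the intensities only (labels stay
sharp), which is enough to exercise the two-pass mask refinement.
Geometry is deterministic given the spec; the seed only drives noise.

What the phantom does *not* emulate: projection-space physics
(reconstruction artifacts, beam hardening, rings), respiratory motion
beyond isotropic in-plane blur, lobar fissures, airway trees beyond the
main bronchi, and textured ground-glass — intermediate tissue is a
uniform-density shell, a simplification rather than a validated model
of lesion texture. Passing tests therefore certify the pipeline's
geometric and statistical machinery, not its performance on real
scanner data.

## Problem sizes and tolerances

Tests and the acceptance script run phantoms at 160 × 160 × 120 voxels
(0.1 mm isotropic), about a third of a full acquisition grid in each
axis, with a 96 × 96 × 64 grid for fast unit tests; the geometry is
expressed in grid-relative units so both scale consistently. The
tumor-burden family injects up to ~170 mm³ of lesions, the most the
desk-scale lung fields (~215 mm³) accommodate, spanning ground-truth
lung fractions from roughly 16 % to 45 %. Against exact phantom labels
the pipeline holds: mid-thorax mask Dice ≥ 0.90 (typically ~0.96),
carina within ±1 slice, interface within ±2 slices of the designed
dome apex, recovered lung percentage within ±3 points of truth with
rank correlation ≥ 0.9, diaphragm Dice ≥ 0.7, and exact count
conservation (reported counts equal the bounded mask census minus
diaphragm voxels).

## Design choices where the procedure was open

- The innermost-30 % rule pools *boundary pixels* of all rib regions,
  not one point per rib; dense support is what the spline needs.
- The pass-2 centroid is the per-slice mask centroid (a global
  centroid would mis-centre tapering slices).
- Burden is reported both as `pct_lung` and as soft+intermediate
  (`combined_burden_pct`); no attempt is made to subtract heart and
  vessels from the soft class, which non-contrast imaging cannot
  separate from tumor.
- Group summaries carry SEM, not SD.
- `dice` of two empty masks is defined as 1.0.
- `spearman_rho` on constant input raises rather than returning NaN.
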