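# Methods

This note records how `bonemap` models the problem, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Geometry conventions

Volumes are 3D scalar grids with `data[i, j, k]` indexing the `(x, y, z)`
axes; world coordinates are voxel centers, `world = origin + index ·
spacing`, all in millimetres. Spacing must come from the file header —
a missing spacing is an error, never a silent 1 mm default, because every
downstream quantity (thickness, margins, band thresholds) is metric.
The default working resolution is 0.4 mm isotropic, matching clinical
temporal-bone CBCT protocols, so the voxelization tolerances quoted below
transfer to real scans.

## Segmentation policy

Bone is labelled by a global intensity threshold (CBCT intensity tracks
density). The anatomically important correction is topological, not
intensity-based: **enclosed** low-density pockets (mastoid air cells) count
as "inside" — they lie within the cortical envelope and do not shield the
dura — while **open** cavities (middle ear; the cranial side of a cropped
region of interest) stay "outside". A background connected component is
absorbed iff it (a) does not touch the volume boundary, (b) has
sphere-equivalent diameter ≤ `fill_diameter_mm`, and (c) contains no
user-placed exclusion seed.

* `fill_diameter_mm` default 5 mm: typical air cells are a few millimetres,
  the middle-ear cavity is much larger; the seed mechanism covers the rare
  borderline case.
* Equivalent diameter is the diameter of the equal-volume sphere —
  a rotation-invariant single-number size.
* Connectivity: 26 for background, 6 for foreground (the standard
  complementary pair that avoids topological paradoxes).
* The interactive slice-by-slice labelling this replaces is not
  reproducible; the policy above encodes its intended *outcome* as code.
  The threshold itself is an engineering parameter with no published value.

## Surfaces

The isosurface of the binary mask is extracted by marching cubes at level
0.5; vertices are in world mm; duplicate vertices are merged at 1e-6 mm,
degenerate triangles dropped, and components under a triangle-count floor
(default 10) discarded as speckle. Face winding is oriented so normals
point from bone into air, verified by probing the mask half a voxel along
each face normal. **No smoothing is applied by default**: smoothing moves
the surface and therefore changes thickness.

The external/internal split classifies each connected component by *air
reachability*: points half a voxel along the outward face normals are
looked up in the labelled background. Components facing background that is
reachable from the user-designated exterior volume faces (`exterior_faces`,
default all six — correct for closed phantoms; a cropped temporal-bone scan
should designate the skin-side face(s)) are external; components facing
enclosed or non-designated air are internal. A component is assigned only
on a ≥ 80% probe majority; mixed components are kept aside as
"unclassified" rather than polluting the thickness field. A single closed
component (a solid object with no cavity) cannot be partitioned and is an
error.

Known artefact: marching cubes over a binary mask leaves staircase facets.
This biases mesh *area* upward by several percent (it does not average out
with refinement) and adds sub-voxel noise to vertex normals. Thickness is
much less affected because the closest-point distance is an extremum, not
an integral, over the jagged geometry; the phantom tests quantify this.

## Thickness field

For every external vertex, the thickness is the exact minimum Euclidean
distance to the internal surface treated as a continuous triangle set —
point-to-triangle, since point-to-vertex distance overestimates on coarse
meshes. The accelerated path prunes with two KD-trees: the nearest internal
*vertex* gives an exact upper bound `u` on the surface distance, and only
triangles whose centroid lies within `u + r_max` (with `r_max` the largest
centroid-to-corner radius) can contain the true minimizer, so the pruning
is lossless. An independently written all-pairs implementation (plane
projection + barycentric sign test + clamped edge projections, a different
formulation than the region-walk used by the fast path) serves as the
oracle; the two agree to 1e-9 mm on random meshes.

The field is directional (external → internal), deliberately: the map asks
"how much bone lies under this point of the skull", not the symmetric
Hausdorff question.

Banding uses left-closed intervals [5,6), [6,7), [7,∞): a vertex at exactly
6 mm is credited to the higher band. The boundary convention is display
cosmetics only — the safety rule always evaluates raw thickness with a
strict inequality, never band labels. Default band colors (white/blue/
green/pink) remain distinguishable in grayscale print; white flags the
do-not-implant region. On a uniformly 6 mm shell phantom at 0.4 mm voxels
the recovered values stay within ±0.7 mm (one voxel diagonal) of truth and
the mean within ±0.2 mm.

## Landmark frame and registration

Positions are charted in 2D as (posterior, cranial) mm with the Henle's
spine at the origin and the zygoma-line direction as x-axis. Two points on
a line do not define the "cranial" axis in 3D, so the frame carries a third
reference point above the ZL; cranial is the component of (point − HS)
orthogonal to the ZL direction, signed toward that reference. Both axes are
defined intrinsically per side, so left and right cases chart consistently
without an explicit mirror. Isodistance rings around the HS default to a
5 mm interval (display only, configurable).

Rigid registration of matched landmark sets uses the closed-form
least-squares orthogonal fit (SVD with determinant correction): it is
deterministic, exact on noiseless data, and never returns a reflection even
when one fits better. Per-landmark fiducial registration errors are
returned alongside the transform.

## Site evaluation

The port footprint (default 10 mm × 5 mm) is laid on the tangent plane at
the candidate site and its sample grid (1 mm step) snapped to nearest
external vertices; a sample further than 2 mm from the mesh makes the
verdict "off-surface". The drilling-depth profile is two-level: 3.5 mm
bedding everywhere, 6 mm at the designated deepest point (default the
footprint center); all values are configurable. Criteria:

1. thickness at the deepest point **> max depth** (strict, on raw values);
2. thickness − required depth ≥ 0 under every sample;
3. RMS deviation of the contact patch from its best-fit plane ≤
   `flatness_tol_mm` (default 1 mm — there is no clinically established
   number; the requirement is only "as flat as possible").

The tangent-plane approximation is valid because the footprint is small
against skull curvature; on a 40 mm-radius sphere the induced sampling
error is a few tenths of a millimetre, which the phantom tests absorb.
The site normal is averaged over a footprint-radius neighbourhood because
single-vertex normals carry staircase noise of up to ~45°. Scanning
evaluates every `stride`-th vertex at four orientations and ranks passing
sites by (margin desc, flatness asc, vertex index) — fully deterministic.
An empty result is meaningful: it is the patient-exclusion signal.

## Phantoms and what they show

* **Shell** — spherical shell, analytically constant thickness; validates
  the whole pipeline against an exact answer.
* **Slab** — a region-of-interest crop, open at the crop faces, with a
  designated skin-side face; the tilted variant separates closest-point
  thickness (correct: the perpendicular value) from vertical-ray thickness.
* **Temporal** — a curved plate with smoothly varying 3–9 mm thickness,
  sealed air cells (must be absorbed), a pocket open to interior air
  (middle-ear analogue, must stay open) and an inner-surface groove
  (sigmoid-sinus analogue, must show as local thinning). Its ground truth
  is computed by a voxel Euclidean distance transform to interior air —
  a different algorithm than the mesh pipeline, so their agreement (95th
  percentile within one voxel diagonal) is evidence, not tautology.
  Air cells are placed with a minimum mutual separation so the generated
  cell count equals the count of enclosed components.

What the phantoms do **not** emulate: CBCT noise, beam hardening, partial
volume effects, trabecular texture, or real anatomical shape variation.
Passing the phantom suite shows the geometry pipeline is correct at the
stated voxel size; it does not certify segmentation quality on real scans,
where the threshold choice and manual review still matter.

## Study statistics

The bundled 15-row experiment table (checksummed at load) records the
postoperative status of Dura Mater, sigmoid sinus and facial nerve —
intact (I), skeletonized (S), uncovered (U) — for 5 unguided and 10
map-guided surgeries. Exposure rates are exact rationals until formatting;
demographics aggregate over *unique specimens* (the guided arm reuses heads
across ears: 10 surgeries on 7 specimens), which is the only aggregation
that reproduces the published summary row (83.3 ± 4.5 years, 3/7 male).
Note 3/7 = 42.86%, which formats to 42.9% at one decimal; the published row
prints a truncated 42.8%.

The group comparison is an exact Wilcoxon–Mann–Whitney test: statuses are
ordinally coded I=0 < S=1 < U=2 (exposure severity; the coding is an
argument, not a constant, since it is a convention), mid-ranks handle ties,
and the permutation distribution is built by full enumeration of all
C(15,5) = 3003 group assignments. On the Dura-Mater outcomes the one-sided
exact p is 21/3003 ≈ 0.0070 (< 0.01); the doubled two-sided p is ≈ 0.0140.
The original analysis does not state its sidedness, so both are always
reported rather than forcing one reading.

## Problem sizes and determinism

Tests run phantoms at 0.5–0.8 mm voxels (seconds each); the acceptance
script uses the clinical 0.4 mm for the 40/34 mm shell (~190k external
vertices, about a minute of closest-point queries). All randomness flows
through explicit seeds (`numpy.random.default_rng`); phantom generation,
scanning and ranking are bit-reproducible for a fixed configuration.

## Known limitations

* The external/internal classifier is validated on phantoms only; real
  cropped anatomies with unusual topology may need the exclusion seeds and
  `exterior_faces` set thoughtfully, and unclassified components reviewed.
* Footprint mapping is tangent-plane + nearest-vertex snap, not geodesic
  unrolling; adequate at 10 mm footprints, increasingly wrong for much
  larger implants on strongly curved bone.
* Thickness is geometric bone thickness; it does not model bone quality or
  density, and no Hounsfield calibration is attempted.
* The chart flattening (posterior, cranial) discards the out-of-plane
  component; it is a reporting convention, not an invertible mapping.
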