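# Methods

## Problem and model

Monocular multi-view reconstruction (SfM followed by MVS) recovers the
geometry of a plant only up to a global similarity transform: the point
cloud has arbitrary units, orientation, and origin. `ringcal` recovers
the missing metric scale and an upright world frame *after*
reconstruction, from a planar red ring of known physical diameter
(default D_true = 200 mm) lying in the scene, and then extracts 3D
phenotypic traits from the calibrated cloud.

The recovery pipeline is:

1. **Color segmentation.** Points are classified as candidate ring
   points by HSV thresholding of their per-point colors. Red wraps the
   hue circle, so the gate is a union of two hue intervals,
   [0°, 20°) ∪ [340°, 360°), with saturation ≥ 0.4 and value ≥ 0.2.
2. **Ring-cluster selection.** The red subset is partitioned by
   single-linkage Euclidean clustering at radius ε (default 5× the
   median nearest-neighbor distance of the red subset — scale-free,
   since the units are unknown). Each cluster of at least 100 points is
   scored by *planarity* (smallest/largest PCA eigenvalue, ≤ 0.05) and
   *annularity* (coefficient of variation of in-plane radial distances
   about the cluster's algebraic circle-fit center, ≤ 0.25). The largest
   passing cluster is the ring; ties break by lower annularity, then
   lower planarity.
3. **Plane frame.** PCA of the ring cluster: the eigenvectors of the
   covariance, sorted by descending eigenvalue, form the axes of a new
   coordinate system; the smallest-eigenvalue axis e₃ is the ring-plane
   normal. The normal's sign is fixed by requiring the centroid of the
   non-ring remainder (the plant) to lie on its positive side.
4. **Rotation.** The rotation aligning the ring normal with the world
   vertical is built by Rodrigues' formula
   R = I + sinθ·[k]× + (1−cosθ)·[k]×², with
   k = z_old×z_target/‖z_old×z_target‖ and θ = arccos(z_old·z_target).
   The stored transform applies Rᵀ to points, with R chosen so that
   Rᵀ·(ring normal) = +ẑ.
5. **Circle fit.** Ring points are projected to the (e₁, e₂) plane and
   fitted in two stages: RANSAC over three-point circumcircle
   hypotheses (2000 iterations, scored by inlier count, ties by lower
   RMS inlier residual), then geometric (orthogonal-distance)
   least squares Σ(‖p−c‖−r)² on the inliers via Levenberg–Marquardt,
   followed by up to two inlier re-selection rounds against the refined
   circle. D_fitted = 2r.
6. **Scale and translation.** s = D_true / D_fitted converts
   reconstruction units to millimeters. The translation places the
   fitted circle center at the world origin, so the ring/ground plane
   is z = 0 and heights are measured from the ground (disable with
   `center_origin: false`). The full map is p_world = s·(Rᵀp) + t.

### Why geometric least squares

Algebraic circle fits (Kåsa) are fast but biased toward smaller radii
on partial arcs. The fiducial's main selling point is surviving heavy
occlusion, where exactly the partial-arc case arises; geometric LS is
exact on noiseless arcs of any extent, so the diameter (hence the
scale) does not degrade with occlusion beyond sampling noise. Kåsa is
used only to seed the optimizer and to estimate residual spread.

### Adaptive RANSAC inlier tolerance

A printed ring has a finite stroke width. A tolerance narrower than the
stroke locks RANSAC onto a thin sub-band of it, which biases the
diameter (by up to the half-width, ~2% here) and starves the inlier
fraction under occlusion. The default tolerance is therefore adaptive:
3× the median absolute radial residual of a Kåsa prefit, floored at 2%
of the point spread. For contaminated point sets (background points not
removed by cluster selection) an explicit tolerance should be passed;
in the pipeline the cluster stage has already isolated the ring, so
the adaptive default is safe.

### Annularity about the fitted center, not the centroid

The centroid of a half arc lies far off the circle center, so radial
spread measured about the centroid grows with occlusion (CV ≈ 0.35 at
50% occlusion, worse beyond) and would reject exactly the occluded
rings the fiducial is designed to survive. Measured about the algebraic
circle-fit center, the statistic is nearly occlusion-invariant: ≈
(w/√12)/r ≈ 0.03 for a 10 mm stroke at r = 100 mm, versus ≈ 0.5 for a
filled disk (what a sphere or cube projects to). The 0.25 threshold
separates these with a wide margin.

### Degenerate cases

* Parallel Rodrigues inputs (θ < 1e-9): identity, exactly.
* Antiparallel inputs: the axis formula is 0/0; a 180° rotation about a
  deterministic axis orthogonal to z_old is used (the larger of
  z_old×x̂, z_old×ŷ, normalized).
* Collinear ring points: no unique plane — a degenerate-geometry error.
* Plant centroid on the ring plane (|offset| < 1e-9): the up-direction
  is undecidable — an ambiguous-orientation error rather than a guess.
* Refinement never returns a worse objective than its initialization;
  non-convergence returns the best iterate with a flag.

## Traits

All traits assume a metric, upright cloud (mm, ground plane z = 0).
Every resolution and percentile is recorded in the report.

| trait | definition | default parameters |
|---|---|---|
| plant height | z-percentile span | 0.5 / 99.5 % (outlier-proof; 0/100 for raw bbox) |
| canopy width | diameter of the xy convex hull (max pairwise hull-vertex distance = rotating-calipers diameter) | — |
| vertical distribution | z histogram from the ground plane to the canopy top, normalized | 20 bins |
| canopy projection area | convex-hull area of the xy projection | — |
| main projection area | occupancy-grid (concave) xy area: occupied cells × cell area | 2 mm cells |
| total leaf area | summed triangle area of a surface triangulation | k = 12, edge cap 6× median NN spacing |
| compactness | occupied-voxel volume / 3D convex-hull volume, clipped to [0,1] | 5 mm voxels |
| spatial occupancy | occupied voxels / bounding-box grid voxels | 5 mm voxels |

Where the field names a trait without a standard formula ("main
projection area", "compactness", "spatial occupancy"), the definitions
above are this package's documented choices; both the convex and the
concave projection areas are always reported so either reading is
available.

The surface triangulation is local: each point's k-nearest-neighbor
patch is projected onto its PCA tangent plane and Delaunay-triangulated;
triangles incident to the patch center are collected, deduplicated by
vertex triple, and filtered by edge length (edges beyond 6× the median
nearest-neighbor spacing bridge gaps rather than surface). On exactly
planar patches all local triangulations agree, so a densely sampled
planar disk recovers πr² to well under 5%. On curved or creased
surfaces neighboring patches can disagree slightly, overlapping a few
triangles: a box's surface is overestimated by ~7%, and tubular organs
(stems) are approximate. Leaves — the area that matters — are locally
planar.

Statistical-outlier cleaning (mean k-NN distance beyond mean + 2σ of
the population) assumes roughly uniform density. A scene mixes the
densely sampled marker sheet with sparser foliage, so the filter is
applied per segment: once on the scene for ring detection, and
separately on the non-ring remainder before trait extraction.

## Synthetic scenes and what they do (not) show

The generator produces a red annulus of nominal diameter 200 mm on the
ground plane, a stylized plant above it, optional red clutter, and then
applies a known similarity (rotation, uniform scale s*, translation) to
mimic the arbitrary reconstruction frame. The correct recovered scale
is exactly 1/s*, and every generated quantity (per-point labels, leaf
areas, heights) is recorded, so the pipeline can be graded without any
real reconstruction.

Conditions and defaults:

* **Ring sampling**: 30 000 points on the full ring (~5 pts/mm² of
  stroke — a conservative dense-MVS density), radius uniform across the
  10 mm stroke so the sample's mean circle equals the nominal diameter.
  A zero stroke width is the idealized fiducial, sampled on a regular
  angular grid with random phase; it is what "noiseless" exactness
  statements refer to, since with a 10 mm stroke the fitted radius has
  an intrinsic sampling fluctuation of order (w/√12)/√N ≈ 0.07 mm —
  far above 1e-6 relative.
* **Occlusion** removes the points of one contiguous arc (a leaf lying
  over the ring); the count scales with the visible fraction.
* **Inclination** tilts the ring; **noise** is isotropic Gaussian in
  mm; **chromatic jitter** is wrap-aware Gaussian hue noise plus
  saturation/value shifts (print and illumination variation); clutter
  primitives are red spheres/cubes.
* **Plants** are parametric: a horizontal disk leaf, a box, or a stem
  with elliptical leaves (30° pitch, 0.6 aspect) — chosen for analytic
  ground truth, not realism.

Passing on these scenes demonstrates the geometry and the estimators,
not photometric robustness of real captures: there is no specular
print, no reconstruction error structure beyond isotropic noise, no
soil or pot clutter in plant colors, and no partial plant occlusion of
itself. The robustness sweep (`ringcal sweep`) exposes noise,
occlusion, inclination, clutter, and jitter as independent axes for
exactly this reason.

## Problem sizes

Recovery checks run 20 seeds per condition with the default 30 000-point
ring; trait checks use 5 000–60 000-point analytic shapes (denser where
a discretized estimator is compared to a continuous area); the growth
sequence uses 6 steps at 6 000 ring + 3 000 plant points.

## Known limitations

* Exactly one ring is assumed; multi-marker scenes are out of scope.
* Azimuth is unobservable by design: a ring fixes scale, plane, and
  origin, but not the rotation about the vertical.
* Red-heavy plants (some amaranths, red lettuce) would need retuned
  color thresholds; thresholds are config-exposed for that reason.
* The annulus stroke width of the physical marker trades detection
  robustness against diameter precision; the fit targets the stroke's
  mean circle, so the printed diameter should be specified to the
  stroke centerline.
* Surface-area estimates on tubular or heavily creased organs are
  approximate (see above).
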