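# Methods

This note documents the models, estimators and numerical choices behind
`shoremapper`, and what the synthetic test conditions do and do not show
about real kite surveys.

## Coordinate and camera conventions

* World frame: local east-north-up (ENU) tangent plane, metres, anchored at
  a configured geodetic origin (WGS84). Handheld-GPS altitudes are treated
  as relative heights above the origin; at ±2 m receiver accuracy the
  ellipsoidal/orthometric distinction is immaterial.
* Camera frame: x right, y down, z along the optical axis. A pose is
  `(R, C)` with `x_cam = R (X − C)`.
* Pixels: origin at the top-left pixel centre, 0-based, x right, y down.
* Distortion: two-parameter even radial polynomial,
  `d = 1 + k1 r² + k2 r⁴` on normalised coordinates; the principal point is
  held at the sensor centre throughout (consumer bodies with fixed lenses;
  freeing it adds gauge-like directions without measurable benefit at these
  noise levels). Undistortion inverts the model by fixed-point iteration.

## Feature matching and tracks

SIFT (scikit-image implementation, no initial upsampling, detection
threshold lowered to keep ≳1000 features per 640×480 frame) runs on the
luminance of colour frames and directly on single-band NIR frames. The same
descriptor matches within and across bands: surface texture produces similar
gradient structure in both, even where the albedo differs. Matching is
mutual-nearest-neighbour with Lowe's ratio test applied in both directions
(making the result symmetric in argument order); default ratio 0.8. All
O(N²) image pairs are matched. Epipolar filtering uses RANSAC over the
Hartley-normalised 8-point fundamental-matrix estimate with an adaptive
iteration count (confidence 0.999), a 2 px Sampson-distance threshold, and
two guided re-fit passes on the inlier set. Tracks are connected components
of the inlier graph; any track observing one image twice is contradictory
and dropped.

## Incremental structure-from-motion

* **Seeding.** Candidate pairs are ranked by shared-track count; each is
  trial-initialised (8-point essential matrix on undistorted normalised
  coordinates, four-fold decomposition disambiguated by cheirality) and
  scored by clean triangulations × median parallax angle. Pairs under 100
  shared tracks or 1.5° median parallax are rejected.
* **Resection.** New views register by P3P (Grunert's quartic with Newton
  root polishing; both `u` branches kept and disambiguated by the RANSAC
  inlier count) inside RANSAC at a 4 px threshold, then two
  Levenberg–Marquardt pose polishes. P3P is used deliberately: DLT-style
  minimal solvers degenerate on coplanar points, and shore terrain is close
  to a plane.
* **Triangulation.** Multi-view DLT; points must reproject within 4 px in
  every observing view, have positive depth everywhere, and subtend ≥ 2°
  somewhere.
* **Bundle adjustment.** Levenberg–Marquardt on the Huber-robustified
  (scale 2 px) reprojection error over all poses, both bodies' shared
  `(f, k1, k2)` and all points. The normal equations are reduced onto the
  camera/intrinsics block by eliminating the block-diagonal point Hessian
  (Schur complement; the reduced system is a few hundred parameters
  regardless of point count), so each LM step is solved exactly and
  convergence takes tens of iterations. The robust loss enters by IRLS
  weights. Rotations are axis-angle with the closed-form SO(3) left
  Jacobian; the analytic Jacobian blocks are unit-tested against finite
  differences. Gauge: first camera fixed, global scale left free (fixed
  later by geo-registration).
* **Self-calibration schedule.** Intrinsics stay frozen at their priors
  while the model grows — releasing focal/distortion on a handful of views
  of quasi-planar terrain locks in a warped solution that later adjustments
  cannot leave — and are released only in the final bundles once all views
  constrain them. Two safeguards against the focal-length/flying-height
  ambiguity of near-planar, near-nadir surveys remain: a one-dimensional
  sweep that warm-starts the final bundle at focal scalings
  {0.95, 1, 1.05} with the compensating camera-height stretch and keeps
  the lowest robust cost, and an *optional* Gaussian prior on the
  intrinsics (off by default: along the ambiguity valley even a weak
  zero-centred distortion prior measurably biases the solution, so it is
  reserved for surveys whose geometry cannot constrain the calibration at
  all).
* Outlier observations beyond 4 px are pruned after each bundle; points
  left with fewer than two observations are deleted.

## Densification

For each registered frame, one candidate point per 5×5-pixel cell: the
cell-centre ray is swept over the depth range of the sparse points seen in
that frame (40 samples, uniform in inverse depth, range floored strictly
above zero), scored by 7×7 ZNCC in a partner view, and refined to
sub-sample precision by parabolic interpolation of the correlation peak.
Partner views (up to four, ranked by covisibility with baseline-to-depth
ratios in [0.05, 0.8]) are tried per cell in order, so swath-edge cells fall
back to a partner that actually sees them. Every accepted point must pass
the primary threshold (ZNCC ≥ 0.7) in one partner *and* an independent
narrow-band re-search in a different partner agreeing in depth to 1%
(ZNCC ≥ 0.5 there); single-view cells are dropped. This two-view scheme is
a deliberate simplification of patch-expansion multi-view stereo — a
documented fidelity reduction — chosen because it reaches the intended
density regime (about one point per 5×5-pixel patch) on textured scenes at
a fraction of the cost. The fronto-parallel patch assumption makes the
depth error grow with terrain slope within a patch footprint, which is why
dense accuracy in units of the pixel ground sampling distance degrades at
coarser image scales.

## Geo-registration

Two-stage, exactly mirroring how the information was measured:

1. **Scale** = mean over all triad edges of (tape-measured length /
   reconstructed length). GPS plays no part.
2. **Pose**: Horn's closed-form quaternion absolute orientation aligns the
   *scaled* GCP positions to their ENU-converted GPS coordinates with the
   scale frozen (rotation + translation only). The quaternion eigenvector
   solution cannot return a reflection.
3. **Vertical datum**: after alignment, a rigid vertical shift pins the
   mean elevation of the annotated waterline to the known tide height.

The residual report carries the two headline numbers separately: the global
residual (mean 3D — and, because the question is convention-dependent, also
2D — distance between GPS positions and transformed reconstruction
positions) and the local residual (mean |tape length − reconstructed edge
length|). Under simulated 1.2 m GPS noise with an exact reconstruction the
global residual is of the order of the noise while the local residual stays
at numerical precision — the accuracy decoupling that motivates the triad
design.

## Terrain and map products

The dense cloud is filtered against a coarse robust median surface (0.6 m
cells; rejection beyond max(6×MAD, 0.25 m)) to remove isolated depth
blunders, gridded by median elevation (0.12 m default), Delaunay-triangulated
in plan view, and faces with an edge over 10× the median edge length
(bridges over data gaps) are flagged invalid. Normals are stored as
north-east-down components with the down component negative;
slope = arccos(−n_D), aspect = atan2(n_E, n_N) mod 360 — 0° = north,
clockwise, pointing downslope; horizontal faces have undefined aspect
(NaN / nodata). Rasters interpolate elevation barycentrically and take
slope/aspect from the covering face; nodata −9999. GeoTIFFs are written
with raw model-pixel-scale / tiepoint tags and the geodetic origin in the
citation key.

Texturing assigns each face the four nearest images per band that pass
projection-bounds, front-facing and z-buffer tests (the z-buffer is a
point-splat of face centres at 8 px bins with a 0.2 m depth tolerance —
adequate for 2.5D terrain under near-nadir views). Distance ties break
deterministically towards the lower image id (stable sort). Blend weights
are fixed inverse-rank (4,3,2,1)/10 renormalised over however many sources a
face has — a documented simplification of frequency-band blending. The
orthomosaic samples the blended images at each cell's 3D surface point;
colour and NIR coverage may differ.

White balance: with `W_c` the mean Spectralon channel value at the survey
exposure and `t_ref` the colour body's exposure time, `g_c = t_ref / W_c`.
The defining (unit-tested) property is that a spectrally flat surface maps
to equal balanced values in both channels — NDVI exactly 0 — which folds in
the exposure-time ratio between the bodies. NDVI is computed per mosaic
cell with a 1e-12 denominator guard; predicted NDVI for a reflectance
spectrum multiplies the band-response integrals by the same gains *and*
exposure times, so measured and predicted values live on one scale.
Patch validation takes 15×15-pixel patches per coverage class, reports
per-patch mean/sd and per-class aggregates, and pairs them with the
closed-form predictions.

## Synthetic scenes: what they emulate and what they do not

The generator produces a temperate intertidal rocky shore: a cross-shore
ramp dipping below the tidal datum (0.16 m default, so a waterline exists),
three octaves of band-limited noise relief plus carved rock-pool
depressions, and contiguous coverage patches (dry/wet rock, sand, three
macroalgae classes with chlorophyll red-edge spectra, cunjevoi, water).
Water cells are exactly the cells below the datum. Flights are serpentine
two-strip tracks with small random tilt (≤5°) and position jitter emulating
kite motion under a self-levelling suspension; the tilt statistics are
configuration, not claims. Rendering integrates class reflectance against
each channel's sensitivity, scales by exposure time, and multiplies by a
per-class speckle field — the stand-in for natural rock texture that local
features need. Two properties of that texture matter and are deliberate:
it is **non-repeating** across the scene (periodic texture lets distant
image pairs match each other consistently, which collapses the
reconstruction — no natural surface does this), and its correlation length
is tied to the fixture's ground sampling distance (~2.5 pixels; texture far
below the pixel footprint renders as view-inconsistent aliasing noise and
biases matching). The default 640×480 fixture at 15 m altitude has a
~3.5 cm pixel GSD and a ~21×16 m footprint.

Not emulated: shadows and sun glint, moving water, lens vignetting, motion
blur, BRDF effects, and the manual culling of degraded frames (an exclusion
list stands in). Passing tests therefore demonstrate the correctness of the
geometry and radiometry chain under clean imaging, not robustness to those
field effects.

## Test and acceptance problem sizes

The acceptance fixture is 24 colour + 20 NIR frames at 640×480 over a
68×28 m scene — the package's chosen desk-scale operating point, where the
full pipeline completes in about 8–10 minutes on one CPU. "Topographic
ground sampling distance" means the dense product's sampling distance
(5 pixels × pixel GSD), matching how the survey literature quotes
topographic resolution separately from imagery resolution; accuracy bounds
on terrain products are stated against it, and the dense-point median error
is additionally reported against the stricter pixel GSD. Determinism is
verified by running the reduced survey twice and comparing manifest
fingerprints (stage parameters + output content hashes, wall-clock times
excluded) and raster contents bit-for-bit.

## Known limitations

* Two-view ZNCC densification under-performs true multi-view patch
  expansion on slanted surfaces and near occlusions.
* The quasi-planar focal/height ambiguity is handled by schedule, prior and
  sweep; surveys with even less relief or tilt diversity than the fixture
  may still need an external focal calibration.
* The z-buffer visibility test is approximate at the size of its bins;
  overhangs are outside the 2.5D terrain model entirely.
* GCP and waterline identification is taken from annotation files; the
  synthetic surveys generate them from ground truth, so annotation error is
  modelled only through an optional jitter parameter.
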