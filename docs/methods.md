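# Methods

This note documents the models, algorithms and numerical choices behind
`pamorph`, and what the synthetic-data validation does and does not show.

## Spatial conventions

Voxel indices are 0-based `(i, j, k)` with `k` the slice axis; the world
frame is LPS in millimetres; a voxel's world position is its center,
`world = origin + index * spacing`.  Files in other orientations are
reorientated to axis-aligned LPS on read; oblique acquisitions are rejected
rather than resampled.

## Vessel segmentation

Segmentation reproduces the clinical 3D-modelling workflow: threshold the
volume to the contrast window −200…500 HU (inclusive bounds — the window is
stated as a min/max pair and inclusivity is the conventional reading),
optionally crop to an axis-aligned region of interest (the reproducible
stand-in for manual free-hand removal of bones and mediastinum), then keep
exactly the connected component containing a seed placed in the main
pulmonary artery.  Default connectivity is 26 (most permissive, least
sensitive to staircase breaks in thin vessels); a seed±deviation intensity
mode is available for data where the window alone is too permissive.
Manual correction by radiologists is not emulated beyond the ROI crop — no
reproducible specification of it exists.

## Centerline extraction

**Skeleton.** The skeleton is traced by medialness-weighted minimal paths
rather than parallel thinning.  Classical 3D thinning is unreliable on fat,
bluntly-cut tubes: it retracts open ends by roughly one radius, and on a
capped cylinder with length below ~2 diameters it can erode the entire
object (we observed an empty skeleton for r = 21.6 mm, L = 72 mm at a 1 mm
grid, and complete loss of a phantom trunk into its junction).  Instead:

1. the Euclidean distance transform D(x) of the mask provides a
   centeredness field;
2. the two geodesically farthest tips are connected by the cheapest path
   under edge cost `length / D²`, which hugs the medial ridge;
3. further tips are attached while they lie more than `min_branch_mm`
   (default 5 mm, the spur-pruning scale) from the skeleton;
4. path ends are trimmed while D climbs faster than 0.5 mm/mm along the
   path — near a flat cap the medial surface is the 45° cone where cap and
   side wall are equidistant, so the climb rate there is ~1, while along a
   tube axis (even a tapering one, slope ≤ ~0.2) it is much smaller;
5. every path point is recentered to the centroid of the in-plane connected
   lumen region on the plane orthogonal to the local path direction
   (window ≈ 1.3 local radii), which removes the residual off-axis bias of
   ridge-following near blunt ends;
6. free branch ends are extended along their end tangents to the 0.5-level
   lumen surface, recovering the millimetres lost to end trimming.

On a straight cylinder (r = 15 mm, L = 50 mm, 0.5 mm grid) the resulting
centerline stays within 0.1 mm of the true axis and reproduces the length
to 0.1%.

**Branches and bifurcation.** Short leaf twigs (< `spur_length_min`, 5 mm)
are pruned; the graph is split at junction clusters; the trunk is the branch
containing the user seed (longest branch otherwise); the two longest
children are named `child_1`/`child_2` by ascending mean x (right pulmonary
artery first in LPS).  The raw skeleton junction node is biased about one
inscribed radius proximal to the geometric branch point (the children's
medial paths merge where their lumens overlap), so the bifurcation is
refined: branch axes are fitted by PCA on windows just outside the junction
zone (sized by the inscribed radius at the junction, read from the distance
transform) and intersected in least squares.  Children are re-originated so
that arclength 0 is their path's closest approach to the refined
bifurcation; the trunk records the bifurcation's (possibly extrapolated)
arclength on its axis.  On the standard tree phantom the refined bifurcation
lands within ~1 mm of the analytic one.  The child origin is deliberately
the *projection* of the bifurcation, not the bifurcation point itself:
prepending the bifurcation would fold the lateral projection gap (~5 mm for
an 18 mm trunk) into the arclength and shift every "x mm distal to the
bifurcation" measurement into the junction (verified: it inflates the right
branch diameter error from +0.7% to +11%).

**Smoothing.** Each raw path is fitted with a cubic smoothing spline and
resampled uniformly at `control_spacing` (1 mm).  The dimensionless
smoothing factor f ∈ [0, 1] (default 0.5) maps to a residual tolerance of
`smoothing_scale · tan(f·π/2)` mm per point (`smoothing_scale` 0.5 mm, the
staircase amplitude of voxel paths at millimetric grids): f = 0
interpolates, f = 1 degenerates to the least-squares straight line.
Tangents come from the spline derivative, normalized.  The spline is
evaluated at `resample_resolution` (1 mm) before arclength resampling.

## Morphometry

All measurement sites are anchored at the bifurcation, 15 mm along each
branch (`diameter_offset`; for the trunk, 15 mm proximal — the trunk ends at
the bifurcation, so the distal convention cannot apply to it).

* **Diameter (1D).** An axial MIP through a `mip_slab` = 10 mm slab centered
  on the site; the width is the in-lumen chord through the site
  perpendicular to the branch's in-plane long-axis direction.  Edges are
  located at half maximum between the lumen and background HU of the
  mask-restricted projection (mask dilated by 2 voxels so the
  partial-volume ramp survives), giving sub-voxel precision; for an axis
  perpendicular to the slab the chord direction is arbitrary (circular
  section) and defaults to x.
* **Area (2D).** The mask is sampled with trilinear interpolation on a
  `section_halfsize` = 30 mm plane grid (step 0.25 mm) orthogonal to the
  centerline tangent, thresholded at 0.5; only the in-plane connected
  region containing the center point is counted, so an adjacent vessel
  crossing the plane cannot inflate the area.
* **Volume (3D).** `V = Σ A(sᵢ)·Δsᵢ` with Δsᵢ the local control spacing —
  the sum of per-slice areas at the standard 1 mm spacing, equivalent to
  trapezoidal integration extended half a slice beyond each end point.  The
  covered arclength window is recorded per artery.
* **Exclusion margin.** Control points within `exclusion_margin` of the
  bifurcation (and of the trunk's valve end) are excluded.  The default is
  5 mm, but for fat vessels the margin must be at least the trunk radius:
  a section plane of a child at arclength s from the bifurcation still
  intersects trunk lumen while s < √(r_trunk² − r_child²) (≈ 13.4 mm for
  r = 18/12 mm), so the tree phantoms are measured with an 18 mm margin.
  The 15 mm measurement site itself clears the junction for the default
  geometry (branch angles 70°).

## Synthetic phantoms

Tubes are parametric curves (segments, circular arcs, polylines) with
constant or linearly tapering radii; arcs keep arclength and tangents in
closed form, so the truth (centerline samples, area profile π r(s)²,
volume π∫r²ds, bifurcation) is analytic and independent of rasterization.
Voxels are lumen HU (350) inside, lung-like background (−850) outside, with
partial-volume blending in the boundary shell: HU is linear in the in-voxel
lumen fraction estimated by 3×3×3 supersampling.  Tube ends are flat
(membership requires the perpendicular foot on the curve), so the cylinder
closed form holds exactly; polyline joints carry joint balls to stay
watertight.  Gaussian HU noise is added last through a seeded generator.
The standard tree phantom uses trunk radius 18 mm and branch radii 12 mm
(central-PA calibers in pulmonary hypertension), branch angles 70° from the
trunk axis with a 15° arc turn, and a 12° posterior tilt of both children —
real branch arteries run posteriorly, and an exactly coplanar tree has a
degenerate medial plane.  Grid defaults mimic a CTPA reconstruction
(0.68 × 0.68 × 0.45 mm); tests use coarser isotropic grids (0.5–1 mm) for
speed.

What the phantoms do *not* emulate: cardiac/respiratory motion, beam
hardening and streak artifacts, contrast-timing inhomogeneity, wall versus
lumen distinction, non-circular lumina, and surrounding mediastinal anatomy.
Passing the phantom suite therefore demonstrates the geometric correctness
of the chain on clean tubular objects, not clinical robustness.

## Synthetic cohorts

Patients are drawn from two arms sized like the study groups (18 non-PH /
41 PH).  Pressures printed as median (IQR) are modelled lognormal matched to
median and quartiles (those variables were non-normally distributed);
pressures printed as mean ± SD as zero-truncated normal.  SPAP and DPAP are
drawn jointly with mPAP through a Gaussian copula (ρ = 0.7) and
conditionally resampled, then clamped, to enforce SPAP ≥ mPAP ≥ DPAP; mPAP
itself is never touched, so its marginal is exact.  The published PH-group
summaries are mutually inconsistent with that ordering (the printed DPAP
mean exceeds the printed mPAP median), so the enforced constraint biases
the PH-arm DPAP downward — an unavoidable consequence of honoring the
hemodynamic ordering, documented rather than hidden.

Each of the nine measurements is linear in mPAP within its arm,
`m = α_g + β_g·mPAP + ε`.  The within-arm link strength ρ_w is solved in
closed form from the mixture-correlation identity so that (a) per-arm means
and SDs equal the configured group values exactly in expectation and (b)
the whole-cohort Pearson correlation with mPAP equals the configured target
(defaults: 0.744 for V_MPA; the others inside the reported per-artery
ranges, with the 3D parameter lowest for the LPA).  An infeasible target
raises a configuration error.  The PH label is re-derived from the strict
mPAP > 20 mmHg rule, so a few patients cross arms; the sampling arm is kept
in an `arm` column, and generator-fidelity checks evaluate per-arm moments,
since relabelling truncates the group distributions by construction.

## Statistics

Conventions follow the clinical software this mirrors: Pearson χ² without
continuity correction when all expected counts are ≥ 5, otherwise Fisher's
exact (two-sided point-probability rule); Student's t with pooled variance;
Wilcoxon rank-sum reported as a tie-corrected normal Z; Shapiro–Wilk at
α = 0.05 gates both the two-group test and the Pearson/Spearman choice.
The AUC is the Mann–Whitney estimator (ties ½); the ROC cutoff maximizes
Youden's J over observed score values with ties broken toward the lower
cutoff (higher sensitivity), a subject being positive when score ≥ cutoff;
the AUC's 95% CI uses the DeLong variance.  DeLong's test uses structural
components; a degenerate (zero) variance reports Z = 0, p = 1.  Decision
curves calibrate scores by univariable logistic regression (rank-preserving
min-max scaling with a logged warning under perfect separation) over a
0.01…0.99 step 0.01 threshold grid.  Stepwise regression is forward-only
with p-to-enter 0.05 via partial-F tests, stops when the current model fits
exactly (further partial-F tests on a zero residual are meaningless), and
rejects selected designs with condition number > 10⁸.  Reference
pressure-prediction equations from the published 59-patient study ship as
`REFERENCE_PRESSURE_MODELS` for evaluation against new measurements.

## Validation problem sizes

The test suite and the acceptance script use: a 0.5 mm cylinder
(r = 15 mm, L = 50 mm) and a 0.5 mm curved tube (r = 8 mm, arc radius
40 mm, 90°); the standard tree at 1 mm and its ×1.2-scaled copy (the
similarity law is checked on diameters, areas, and volumes integrated over
geometrically matched arclength windows, since raw extents differ by
endpoint effects); exhaustive AUC checks at n ≤ 12; a 10⁵-replicate
bootstrap of the DeLong variance at n = 20; 5 000 null replicates at
n = 18/41 for the type-I error; 2 000 replicates at n = 59 for DeLong
p-value uniformity; cohorts of 5 000 (moments) and 2 000 (correlation).

## Known limitations

* Oblique CT orientations are rejected, not resampled.
* The tracer assumes one vessel tree per mask; loops (e.g. from touching
  vessels) are broken heuristically along the cheapest path.
* Branches shorter than ~1.3 tube radii may be absorbed into the end-cone
  trim and not reported.
* Translation equivariance is exact up to tie-breaking in the
  farthest-tip search (sub-voxel, only visible on perfectly symmetric
  phantoms).
* The cohort generator reproduces group moments and correlations, not the
  full joint distribution of real hemodynamics; in particular PH-arm DPAP
  is biased low (see above), and measurements are conditionally Gaussian.
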