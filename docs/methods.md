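# Methods

This note documents the models, numerical choices and limitations of
`unfoldreg` at the level of detail a user needs to interpret results or
extend the package.

## Unfolding

Hippocampal gray matter (labels Sub, CA1–CA4; CA4 includes the dentate
gyrus) is parameterized by three harmonic fields solved with red-black
successive over-relaxation (ω = 1.8, 6-neighbor stencil, zero-flux walls
by masked stencil renormalization, relative residual tolerance 1e-5,
iteration cap 10,000):

- **ap** — 0 at the anterior terminus label, 1 at the posterior;
- **pd** — 0 at the proximal edge label, 1 at the distal edge;
- **io** — 0 at the SRLM (inner) side, 1 at the outer background.

Dirichlet cells can be imposed at the neighbor-cell center
(`boundary="cell"`, the plain stencil) or at the shared voxel face
(`boundary="face"`, double-weight boundary links). The pipeline uses the
face convention: the tissue boundary physically lies on the face between
gray matter and SRLM/background, and streamline thickness then reproduces
an axis-aligned slab's thickness exactly.

The mid-thickness surface (io = 0.5) is resampled onto a regular lattice
(default 256 × 128 over a 40 × 20 mm unfolded rectangle; the benchmark
and test suites use 64 × 32 to keep runtimes in minutes) by linear
scattered interpolation of voxel world-centers in (ap, pd), restricted to
the laminar band |io − 0.5| < 0.25; lattice nodes outside the data's
convex hull (rectangle corners) fall back to nearest-neighbor
extrapolation and are flagged invalid. Outward normals come from the
world-space gradient of the laminar field.

Label maps are projected to unfolded space by majority vote: every
gray-matter voxel votes its label into the pixel at its (ap, pd)
coordinate; empty pixels are filled from the nearest labeled pixel. The
full-thickness vote makes the map robust to single-voxel coordinate
noise.

## Morphometry

- **Thickness** — arc length of the streamline traced (RK4, step
  0.25 × min voxel) through ±∇io from each mid-surface vertex until the
  laminar field leaves (0.01, 0.99) or the position leaves gray matter
  (bisected to sub-step precision); the two half-lengths sum to the
  local thickness in mm. Streamlines exceeding ten times the
  slab-average estimate are marked invalid. At 0.5 mm voxels the
  staircase boundary inflates curved-sheet thickness by up to ~1 voxel;
  axis-aligned slabs are exact because the phantom grid aligns voxel
  faces with integer world coordinates.
- **Gyrification index** — per-vertex ratio of native dual-cell area
  (each grid quad contributes a quarter of its triangulated area to each
  corner) to the matching unfolded area. Node coordinates are denoised
  with a 0.5 mm NaN-aware Gaussian before area computation:
  scattered-interpolation jitter otherwise inflates areas by ~20-30%,
  and this σ reproduces GI = 1 on both the flat and cylindrical
  analytic sheets to better than 1%.
- **Mean curvature** — quadric fit (z = ax² + bxy + cy² + dx + ey + f)
  over each vertex's 5 × 5 neighborhood expressed in a local frame whose
  z-axis is the outward normal; H = a + c, positive when the sheet
  bends toward the outer side. Neighbors whose normals disagree with the
  center (dot < 0.3; the grid folds back on itself inside tight curls)
  are excluded, |H| > 1 mm⁻¹ is treated as a failed fit, and the node
  coordinates are pre-smoothed at 0.75 mm — the smallest σ at which both
  the flat-slab (|H| < 0.005) and cylinder (H = 1/2r within 10%)
  oracles hold.
- Gyrification and curvature maps are Gaussian-smoothed at σ = 1 mm in
  unfolded space. All channels are z-scored over valid pixels (NaNs
  filled from nearest valid values first) so "equal weighting" of
  channels with heterogeneous units is meaningful; the per-channel
  (mean, sd) is retained for inversion.

## Registration

A dimension-generic greedy demons scheme over a stationary velocity
field drives both the 2D unfolded registration and the 3D volumetric
control; the displacement is the velocity's exponential by scaling and
squaring, which keeps the Jacobian determinant positive. Per iteration,
a symmetric demons force from the warped moving image is smoothed
(fluid σ, default 3.5 px), scaled to a maximum step (1 px), added to the
velocity, and the velocity is smoothed (elastic σ, default 2 px).
Similarity is the mean per-channel SSD on standardized channels
(an optional large-window local-normalized-correlation metric exists but
is not the default: it is amplitude-robust yet blind to the smooth
global profiles that carry most of the curvature channel's
information). A 3-level pyramid (×4, ×2, ×1) runs up to 200/150/100
iterations with a convergence window; sampling clamps at the rectangle
edge — nothing wraps, matching the sheet's four true edges.

Forces are masked to pixels that are valid in **all** samples (measured,
not NaN-filled or hull-extrapolated): imputed pixels otherwise inject
systematic boundary drift.

Inverses are computed by damped (factor ½) fixed-point iteration with
cubic field sampling, seeded from exp(−v); undamped or linear variants
leave composition residuals an order of magnitude larger where the field
is rough. Transform composition also samples cubically.

Groupwise template building starts from the arithmetic mean, then four
times registers every sample to the template and averages the warped
samples; between iterations the inverse of the mean displacement is
applied to the average so the template stays centered. Label
propagation to the reference concatenates the inverse of the reference's
warp with each sample's warp and resamples labels by a 3 × 3
supersampled majority vote (anti-aliasing: plain nearest sampling
occasionally produces single-pixel label islands at boundaries that are
resampling artifacts, not topology errors).

The rigid initializer for the 3D control aligns world centroids and
principal second-moment axes, choosing among the four proper axis-sign
assignments by mask overlap, with a translation-only fallback when the
moments are near-isotropic.

## Volumetric control

The control arm is a best-case conventional registration: binarized
gray-matter masks (perfect tissue contrast), right hemispheres mirrored,
moment-based rigid initialization to the reference, resampling to an
isotropic 0.5 mm working grid, light mask smoothing (σ = 1 voxel) for
gradient support, 3D single-channel template building with the same
engine (40/25/10 iterations), propagation of subfield labels through the
concatenated 3D transforms into the reference's native space, sampling
at the reference mid-thickness surface, and nearest-neighbor imputation
of missing values in unfolded space. Differences from the unfolded arm
are attributable to the representation, not the optimizer.

## The phantom

The generator emulates the study design this package is built to
evaluate: a cohort of folded-sheet "hippocampi" with known subfield
boundaries. One sample is a parametric sheet S(u, v), u along A-P
(40 mm), v along P-D (20 mm arc):

- the cross-section is a variable-curvature curl (total angle 1.6π by
  default) whose curvature density follows a per-subfield profile
  (0.2, 0.8, 0.8, 1.2, 1.6 for Sub…CA4): the subicular side is nearly
  flat and the curl tightens around the CA4 end, so curl features track
  the subfield layout as they do anatomically;
- sinusoidal gyral waves run along A-P (3 waves, 0.8 mm amplitude),
  with a per-subfield amplitude profile (strongest over Sub/CA1, zero in
  the tight distal curl — which also prevents self-intersection);
- laminar thickness is a per-subfield profile (2.0, 2.0, 1.4, 1.7,
  2.0 mm) with smooth 1 mm transitions and 20% anterior→posterior
  tapering. Sub and CA1 share a thickness, so the thickness channel is
  deliberately blind at the Sub|CA1 boundary (curvature and
  gyrification carry it): each feature is a partial boundary cue, as in
  real data;
- voxelization at 0.5 mm paints voxels within half the local thickness
  of the surface, adds a 1-voxel SRLM shell on the concave side and
  terminus/edge labels on the four sheet edges, and stores ground-truth
  (u, v, laminar) coordinates per voxel.

Cohort variation (seeded): gyral count ±1, amplitude ±30%, phase ±45°,
curl ±8%, length/width ±10%, and Dirichlet-resampled subfield fractions
(concentration 70, i.e. boundary shifts of roughly 1–3 unfolded pixels
between samples); hemispheres split 4 left / 3 right at n = 7. These
magnitudes are calibration choices that reproduce the qualitative regime
of real specimen cohorts — gross morphological variability that the
unfolded representation factors out but volumetric registration must
absorb — not quantitative claims about anatomy.

What the phantom does **not** emulate: image intensities and stains
(labels only), realistic cytoarchitecture, dentate-gyrus topology,
measurement noise in manual segmentation, field-of-view truncation, and
a fully closed vestigial sulcus (the curl leaves a ≥1.5 mm gap between
banks at the frozen settings). Passing benchmarks on the phantom
therefore demonstrates the pipeline's correctness and the
representation-level advantages of unfolded registration, but absolute
Dice values do not transfer to histological material.

## Known limitations

- At 0.5 mm desk-scale resolution, mean-Dice differences between feature
  subsets on a 7-sample cohort are at cohort-noise level (±0.03 across
  seeds and sub-voxel alignment); single-draw inequalities between
  subsets should not be over-interpreted. The benchmark's aggregate
  ordering (registration > unfolding alone > volumetric control) is the
  robust finding.
- The binarized-mask control at these settings aligns the open sulcus
  well enough that propagated labels, after imputation, remain banded:
  its characteristic topology failures (label bleed across the
  vestigial sulcus) appear only for near-closed curls, which at this
  resolution also degrade surface-measurement fidelity. The control's
  deficit manifests here as uniformly lower Dice and larger border
  distances rather than broken topology.
- Thickness carries a +0.2–0.4 mm voxelization bias on curved regions;
  ratios and inter-sample comparisons are much less affected than
  absolute values.
- The engine is a deterministic greedy stationary-velocity scheme, not a
  symmetric time-varying one; exact equivalence with any particular
  production registration package is out of scope.
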