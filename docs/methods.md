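# Methods

This note documents the models, conventions and numerical choices behind
`palatemap`, and what the synthetic phantoms do and do not establish about
real CBCT data.

## Coordinate conventions

All geometry is in millimetres in a right-handed anatomical frame:
X+ = patient right, Y+ = anterior, Z+ = superior. The frame is built from
landmarks only (no image content): Y is the unit vector from the posterior
to the anterior nasal spine; the occlusal-plane normal (best-fit plane of
≥3 occlusal points, by SVD; the exact cross product for exactly 3) is
orthogonalized against Y and oriented toward the palate to give Z; X = Y×Z,
its sign validated against the first-molar fissures (a contradiction
raises rather than silently flipping, since it indicates mislabelled
sides). The origin is the ANS–PNS midpoint, which lies on the midsagittal
plane by construction. Tooth-level band boundaries are stored as 3D points
and acquire their meaning (Y levels) only after framing; their
anterior→posterior ordering is therefore validated at use, not at
construction.

## Segmentation

Two-sided HU thresholding with a two-pass scheme: bone 400–1500 HU, teeth
1500–2000 HU (defaults; the hard-tissue working window is 50–2000 HU).
Components smaller than `min_voxels` (default 1000 at 0.3 mm spacing) are
discarded, keeping the largest 26-connected component unconditionally.
Iso-surfaces are extracted by marching cubes **on the continuous grey
values** at the lower threshold (with excluded-tissue voxels floored below
the level when a mask is supplied), which interpolates the crossing within
each voxel and removes most staircase bias; extraction from a binary mask
(level 0.5) is used where an unbiased match to the voxel-count volume is
wanted. Meshes are cleaned of degenerate faces and oriented outward
(positive enclosed volume for watertight surfaces). No smoothing is
applied by default. CBCT grey values are treated as HU-like; calibration
is the user's responsibility.

Note that the bone-only mesh keeps root sockets and the nerve canal as
surface features — exactly as a thresholded maxilla model does — so
distance maps computed over regions containing carved structures reflect
the locally reduced bone, while the analytic truth field describes the
uncarved wall. Oracle comparisons therefore use root/canal-free phantoms;
root effects are tested through the probe and region-flag paths.

## Thickness cartography

The oral patch is the set of bone-mesh faces whose outward normal has a Z
component below −0.2 (facing the oral cavity). For each oral vertex a ray
is cast along the **anti-normal** (into the bone; selectable alternatives:
straight +Z, or unsigned closest distance) and the Euclidean distance to
the first intersection with the nasal-floor surface is recorded; no hit
within `max_ray_mm` (default 40) marks the vertex invalid. Ray–triangle
intersection is chunked, vectorized Möller–Trumbore with an AABB precull;
barycentric tolerances of 1e−9 make hits through shared mesh vertices
robust, which the analytic phantoms exploit for exact oracles.

ROI aggregation uses the barycentric one-third area rule: each valid
vertex carries one third of the area of its incident labelled triangles.
Then AA = Σw, MD = Σw·d / AA and Vol = Σw·d, so Vol ≡ AA·MD holds as an
algebraic identity and Vol is an exact surface integral of the linear
interpolant. The area-weighted (rather than vertex-uniform) mean was
chosen for exactly this integral property; the difference is exposed by
weighting with the validity mask only. Invalid vertices are excluded from
AA (not zero-filled) and the per-ROI coverage fraction reports how much
labelled area survived.

ROI definition: |x| between `min_paramedian` (default 0) and 10 mm,
split at x = 0 into right/left, with three Y bands per side at tooth
levels (first premolar, second premolar, first molar). Ties at x = 0 go to
the right; ties at a band boundary to the anterior band.

## Angulated probing

Six probe points sit at x = ±3 mm, Y at the canine–P1 contact, P1 mid and
P1–P2 contact levels, projected along −Z onto the oral patch. The 0°
insertion direction is the local surface anti-normal ("relative to the
palatal surface"); the occlusal-perpendicular convention is available as an
alternative zero reference through the frame-Z direction rule. Tilt is
purely sagittal: a rotation about the frame X axis carrying +Z toward +Y
(anterior). Thickness is always the distance to the nasal floor; a teeth-
mesh interception is a separate flag with its own depth, never a truncation
of thickness, so nasal-floor and root risks stay independently reportable.
`usable_depth` = min(thickness, root depth) is the derived planning
quantity. Corridor fit tests a cylinder of the implant diameter with 8
perimeter rays plus the axial ray (count configurable) against both
surfaces over the implant length.

## Phantoms

*Slab*: uniform bone plate between air half-spaces; truth thickness is the
constant plate thickness; a spacing coarser than thickness/3 is rejected.

*Vault*: bone shell `R ≤ √(x²+z²) ≤ R + t(y)`, z > 0, R = 15 mm, with
t(y) ramping linearly between plateaus of 3.5 mm (posterior of the M1 band
center) and 10 mm (anterior of the P1 band center), slope 0.5 mm/mm.
Radial rays stay at constant y, so the truth thickness along the inward
normal is exactly t(y). The analytic surfaces share an (α, y) parameter
grid between the inner and outer walls — a radial ray through an inner
vertex meets the outer wall at the corresponding vertex, making the
normal-ray oracle exact to float precision; oral vertex normals are
prescribed exactly radial. Root analogues are mildly tapered frusta: an
"incisor bundle" per side (axis at x = ±4, y = 17, radius 3.0→2.6 mm over
z = 14.5–25) positioned so 20°/30° rays from point 1 intercept it at
≈6.8/4.4 mm depth while 0°/10° rays and the probe point itself clear it by
≥ 1.9 mm, and a "canine rod" (x = ±7.5, y = 11, radius 1.8→1.5 mm) that
dips into the ROI-1 corridor so the per-ROI root flag trips for 1r/1l
only. A strongly tapering cone cannot satisfy the interception pattern and
the clearances simultaneously, which is why the roots are rod-like; real
root morphology is not modelled. The nerve-canal void is a vertical
cylinder (x = 2, y = −4, r = 1.2 mm) perforating the shell; it manifests
as an area deficit (hole) in ROI 3r. In the voxel phantom, roots replace
bone with teeth-level HU inside the shell only, and the canal is refilled
with soft tissue.

*Mesh pairs*: parallel slab (nasal plate padded so edge rays hit),
concentric same-topology icospheres (normal-ray separation exactly t), and
a gradient wedge whose area-weighted MD is exactly the ramp midpoint
(one-third-area weights integrate linear fields exactly).

*Cohorts*: long-format tables simulated from the same random-intercept
model the stats layer fits: per-patient sex (33.7% female), age group
(probabilities 33/42/109 ÷ 184), tooth-intrusion flag (57%), random
intercept b ~ N(0, σ_b²) with σ_b = 1.5 mm, residual σ_e = 1.0 mm, and
mm-scale fixed effects (e.g. sex −1.12 mm, ROI-3 drop −6.94 mm; an
angulated design per point subgroup with opposite-sign angle effects).
Effect sizes are plausible palatal values used as simulation conditions,
not reproduction targets — σ_b/σ_e in particular are not published
quantities and were chosen once to give intraclass correlation ≈ 0.7.
All randomness flows from one explicit seed.

What the phantoms do **not** emulate: CBCT noise, beam hardening and
scatter, partial-volume blur, anatomical shape variability, real root
morphology, mucosa. Passing oracles shows the measurement chain is
geometrically correct and well calibrated, not that segmentation
thresholds transfer to clinical scans; the manual-refinement step of a
clinical protocol is replaced by connected-component filtering.

## Statistics

`describe` reports n, mean, SD (n−1), min/max, moment-based skewness
g1 = m3/m2^1.5 and excess kurtosis g2 = m4/m2² − 3 (bias-adjusted variants
behind a flag), plus **both** printed-interval conventions, explicitly
named: `ci_mean` = mean ± 1.96·SD/√n and `range_1_96sd` = mean ± 1.96·SD.
Clinical summary tables often print "(95% CI)" for either; implementing
both, named, removes the ambiguity. 1.96 (normal 97.5% quantile, not t) is
used throughout for printed-table reproduction.

The mixed model is y = Xβ + Zb + ε with one random intercept per patient.
REML estimation profiles the variance ratio λ = σ_b²/σ_e²: for fixed λ the
GLS solution uses the Woodbury form V⁻¹ ∝ I − λ/(1+λn_i)·J per group, and
the REML criterion (N−p)·log σ̂_e² + Σ log(1+λn_i) + log|XᵀV⁻¹X| is
minimized over log λ ∈ [−15, 15] by bounded 1-D optimization (xatol
1e−10), with the λ = 0 boundary checked explicitly. Inference is Wald z
with ±1.96·SE intervals; p-values are clipped away from exact zero.
Satterthwaite/Kenward–Roger degrees of freedom are out of scope, a
documented difference from lmer-style software that matters only at small
group counts. Treatment coding uses fixed reference levels (age 4–12,
male, no-teeth, left, ROI 1, angle 0°, point 2); rank-deficient designs
raise naming the columns. Tests cross-check the fit against the balanced
one-way ANOVA closed form (σ̂_e² = MSW, σ̂_b² = (MSB−MSW)/m) and against
statsmodels MixedLM.

Rank tests enumerate the exact null distribution for combined n ≤ 12
(all C(n, n_x) group assignments for Mann–Whitney, all 2ⁿ sign patterns
for Wilcoxon), using midranks so ties are handled, with symmetric-tail
two-sided p-values; larger samples use the tie- and continuity-corrected
normal approximation (scipy). The method used is recorded in the result.
`average_dependent` collapses repeated measurements to one mean per
patient × condition before nonparametric testing, carrying patient-level
covariates through — the pseudoreplication guard.

Age trends use a cubic smoothing spline with GCV-selected smoothing
(scipy's `make_smoothing_spline`), duplicate ages pre-averaged with
multiplicity weights. Note the λ→∞ limit of a cubic smoothing spline is
the least-squares **line** (the curvature penalty vanishes on linear
functions), not the global mean; the heavy-smoothing test asserts the true
limit.

## Problem sizes and tolerances

Default test/acceptance problem sizes — slab at 0.3 mm spacing, vault at
0.5 mm (clean-oracle and full variants), sphere at 0.3 mm, cohorts of
100–200 patients, 20 recovery seeds, 200 null simulations — were chosen as
the smallest sizes at which the oracles are cleanly resolved (≥3 voxels
across the thinnest wall, Monte-Carlo error well inside the asserted
bands). Key tolerances: exact-mesh thickness 1e−6 mm; segmented thickness
2 voxels; mesh-vs-voxel volume 2%; Vol ≡ AA·MD 1e−9 relative; REML vs
closed form 1e−4; fixed-effect recovery 3 SE; Wald type-I error within
[0.02, 0.09] at α = 0.05. Distance-map computations crop the oral patch
and nasal target to the ROI strip (plus margins) — pure bounding-box
restriction, no change to any retained value.

## Known limitations

- Thickness is surface-to-surface geometry only; bone density/quality
  along the ray is not modelled.
- One random intercept; no crossed/nested random effects, no Bayesian fit.
- Probes start at the bony oral surface (the meshes carry no mucosa).
- The per-face ROI labelling is hard (no partial-face weighting at band
  boundaries); at typical mesh resolutions the boundary area is < 1% of a
  section.
- Negative (posterior) angulations are representable by the direction
  machinery but not exposed as a workflow.
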