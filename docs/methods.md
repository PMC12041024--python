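# Methods

## Constitutive model

The tissue is modelled as incompressible and hyperelastic with the
Gasser–Holzapfel–Ogden (GHO) energy: an isotropic neo-Hookean matrix of shear
modulus μ (kPa) plus two symmetric families of dispersed collagen fibers,

W(C) = μ/2 (I₁ − 3) + k₁/(2k₂) Σᵢ₌₄,₆ [exp(k₂Eᵢ²) − 1],
Eᵢ = κI₁ + (1 − 3κ)Iᵢ − 1.

Conventions fixed once and used everywhere:

- component order is (circumferential, longitudinal, radial), so the fiber
  directions are literally a₁ = (sin γ, cos γ, 0), a₂ = (−sin γ, cos γ, 0),
  with γ measured from the longitudinal duct axis;
- angles are degrees at every public interface, radians internally;
- stresses kPa, forces N, lengths mm (1 N/mm² = 1000 kPa, conversion
  centralized in `tensile_features`);
- the energy is written in total invariants rather than isochoric ones: with
  det F = 1 enforced throughout, the two coincide, and every kinematic state
  asserts |λ₁λ₂λ₃ − 1| ≤ 1e−10.

Stress is the exact derivative of the energy, σ = F(2∂W/∂C)Fᵀ − pI; a test
verifies it against central finite differences of W on 100 random
incompressible states (relative error ≤ 1e−6). The constitutive law is
implemented as written, with the fiber terms active for any Eᵢ; an optional
`fiber_tension_only` switch zeroes a family's contribution when its
pseudo-invariant Iᵢ < 1 (the classical convention that fibers do not support
compression). The default keeps the verbatim law because the two options
differ only in states with fibers under compression (e.g. the inner wall
during ring closure), and which convention the original in-house solver used
is not determinable; the switch makes the choice explicit per run.

Parameter domain: μ > 0, k₁ ≥ 0 (k₁ = 0 recovers neo-Hooke), k₂ > 0,
κ ∈ [0, 1/3] (κ = 1/3 is the isotropic dispersion limit and provably
collapses the circumferential/longitudinal distinction), γ ∈ [0°, 90°]
(swapping the loading direction is equivalent to replacing γ by 90° − γ —
a tested identity).

## Uniaxial semi-analytic solution

For a tensile specimen, C = diag(λ₁², λ₂², λ₃²) with λ₃ = 1/(λ₁λ₂) and both
lateral Cauchy stresses zero. The pressure is eliminated analytically from
σ₃ = 0 (p = λ₃²S̃₃₃ with S̃ the p-free second Piola–Kirchhoff stress), and the
remaining scalar equation σ₂(λ₂) = 0 is solved by 64 bisection steps on
log λ₂ over (10⁻³, 1.5], vectorized across the whole stretch grid. Bisection
was chosen over Newton for unconditional robustness at large stretch, where
the fiber exponential makes the equation extremely stiff; the fiber stress
factor 2k₁E·exp(k₂E²) is evaluated in log space and capped at e⁷⁰⁰ so that
extreme trial states during bracketing stay finite with the correct sign
instead of producing NaNs. 64 steps put the root at relative machine
precision; the residual lateral stresses are ≤ 1e−8·max(μ, k₁) by test.

## Curve descriptors (E₁, E₂, elbow, rupture)

Records are converted by σ₁ = Fλ₁/(w₀t₀) (incompressible area change) and
truncated at the maximum-force sample; the rupture point is the last sample
kept. The low- and high-strain moduli are slopes of terminal linear windows:
the longest prefix (suffix) whose ordinary-least-squares fit has r² ≥ 0.95
(threshold configurable). Plain r² thresholding is insensitive at a sharp
stiffness transition — the window's variance is dominated by its long linear
part, so several points beyond the kink barely dent r² while visibly biasing
the slope. The window is therefore refined deterministically: while the
interior-end point's |residual| exceeds 3× the window's median |residual|
(floored at 1e−9 of the stress scale), it is dropped and the fit repeated.
The factor 3 is chosen so that smooth curves are untouched — after a linear
fit to data with quadratic curvature, the end-to-median residual ratio is
≈ 2.6 — while points beyond a genuine slope discontinuity are expelled. On a
noiseless 100/2000 kPa bilinear fixture the rule recovers both slopes exactly
with windows meeting at the kink; with 1% multiplicative noise the slopes stay
within ~0.5%.

The elbow is the mean stress–stretch coordinate between the last point of the
E₁ window and the first point of the E₂ window. If the windows genuinely
overlap (near-linear curve) the elbow degenerates to the overlap midpoint and
the result carries a `degenerate` flag rather than failing, so that a summary
table can always report an elbow. A shared single boundary point is treated
as a clean transition, not an overlap. No smoothing is applied by default;
records are taken as measured. The E₁ window starts at the first sample (no
toe-region skipping) — initial-toe artifacts are the user's preprocessing
decision, not a hidden default.

## Parameter identification

Both directions are fitted simultaneously by bounded nonlinear least squares
on the stacked stress residuals (scipy trust-region reflective solver, a
Levenberg–Marquardt-type method that honors box bounds), equal weights for
all points and both directions. Bounds: μ ∈ (0, 500] kPa, k₁ ∈ [0, 500] kPa,
k₂ ∈ [10⁻⁶, 5], κ ∈ [0, 1/3], γ ∈ [0°, 90°]. Because k₁ and k₂ trade off
along the exponential, the solver is restarted from 16 scrambled-Sobol points
over a start box interior to the bounds (seeded, reproducible); starts stop
early once the objective falls below 10⁻¹² of the stress variance (a
numerically perfect fit cannot be improved). Goodness of fit is r² =
1 − SSres/SStot per direction; physical consistency requires λ₂(λ₁) and
λ₃(λ₁) strictly decreasing in both directions over the data grid.

Identifiability: noiseless two-direction fits recover all five constants
within 2% (γ within 0.5°) across random ground truths inside the start box —
a tested property. κ and γ are partially confounded near κ = 1/3 (where γ
drops out of the model entirely), so the identifiability suite draws
κ ≤ 0.28; fits of near-isotropic tissue should not over-interpret γ.
Group-level fits use the pointwise mean of per-specimen curves interpolated
linearly onto a common 100-point grid up to the group's smallest rupture
stretch; per-specimen fitting is available by calling `fit_gho` per record.

## Residual stress from the ring-opening test

The opened ring is taken as the stress-free reference: an open sector of
total angle 2(π − α) — the unique convention under which the mid-wall
arc-length identity R_α = π/(π − α)·R_m holds, with R_m = R₀ + t₀/2. R₀ is
interpreted as the luminal radius by default (that is what makes R₀ + t₀/2 a
mid-wall radius); a `Ro_is_external` switch supports the external reading
(R_m = R₀ − t₀/2). The open sector's inner/outer radii follow from the
mid-wall radius plus exact cross-sectional area conservation, which together
imply the open wall thickness equals the closed thickness exactly.

Closure is solved as a plane incompressible boundary-value problem at unit
axial stretch (the experimental closure imposes in-plane displacements only):
λ_θ(R) = πr/((π − α)R), λ_r = 1/λ_θ, with r(R) from area conservation given
the closed inner radius r_i. Radial equilibrium dσ_r/dr = (σ_θ − σ_r)/r is
integrated by the trapezoid rule on 400 radial stations (200 in the quick
acceptance checks), with σ_θ − σ_r = λ_θ²S̃_θθ − λ_r²S̃_rr eliminating the
pressure. The single unknown r_i is found by Brent root-finding on the
outer-surface traction, bracketed around the zero-hoop-strain radius and
expanded geometrically if needed. Both surfaces are traction-free to
≤ 1e−6 of the peak hoop stress; the three summary scalars (inner and outer
hoop stress and their difference) change ≤ 0.5% under grid doubling.

A full 3D finite-element replication (the original study used an 8,000-
hexahedron mesh with a penalty bulk modulus ≈ 10³μ) is out of scope: with
homogeneity, plane kinematics and unit axial stretch the continuum problem
reduces exactly to this one-dimensional BVP, which doubles as its own
high-resolution oracle. The published residual-stress magnitudes are embedded
in a figure and not printed, so no numeric reproduction is claimed; the
verified properties are the sign pattern (compression inside, tension
outside), surface tractions, grid stability, and monotone growth of the
residual stress with opening angle — which reproduces the treated-vs-control
ordering given the groups' opening angles (124° vs 111°).

## Histomorphometry

Quantification works on HSB (hue/saturation/brightness) thresholded masks,
hue treated circularly. The exact HSB windows of the original ImageJ
workflow are unpublished; the shipped defaults isolate the canonical stain
colors (near-black elastic, pink-red collagen with the hue interval wrapping
through 0, hematoxylin purple nuclei) and are configuration, not a
reproduction claim. The synthetic phantoms paint exactly those reference
colors, which makes the recovery tests threshold-independent. Elastic and
collagen percentages are mask areas over the ROI (media layer); a pixel
matching both windows counts as elastic (black test precedes pink). Nuclei
are 8-connected components (connectivity is not stated in histology
protocols; 8 is fixed here and documented — two disks touching diagonally at
one corner merge) with area ≥ 50 px², counted per mm² of ROI using the µm/px
calibration. Layer shares come from three annotated boundary polylines
(lumen, media/adventitia boundary, outer edge): each is resampled in polar
coordinates about the lumen centroid on 360 matched rays, and mean radial
gaps give the intima-media and adventitia fractions of the wall thickness.
Crossing boundaries and zero thickness are errors, not warnings.

## Group statistics

Summaries are mean ± SEM (SEM = sd/√n, sample sd) with two-sided 95% CIs from
the Student-t quantile at n − 1 degrees of freedom — at n = 5–6 the t
quantile (2.57–2.78) differs materially from 1.96, and the t-based CI is what
reproduces the published per-group intervals to the printed decimal. The
two-group comparison follows a fixed tree: Shapiro–Wilk on each group
(α = 0.05); both normal → two-sided F-test of variances (α = 0.05) choosing
pooled t (equal) or Welch t (unequal); otherwise two-sided Mann–Whitney U.
Significance at p ≤ 0.05, no multiple-testing correction (none was applied
in the source workflow). The tree's empirical type-I error over 2,000 seeded
null replicates at n = 6 vs 5 is ≈ 0.05 (tested to lie in [0.03, 0.08]).
One published interval (control elastic fibers, 21.0–41.5) is inconsistent
with n = 6 and its printed SEM and is documented rather than reproduced.

## Synthetic cohort

The generator emulates the study design: control n = 6, treated n = 5, with
group ground truths set to the published values — GHO rows (35, 73, 0.07,
0.27, 74.5°) and (33, 79, 0.06, 0.26, 52.5°); geometry, opening angle,
histology and rupture-stretch targets from the published means/SEMs, with
per-specimen sd = SEM·√n (inverting the SEM definition). Tensile records are
forward-model force samples F = σ₁w₀t₀/λ₁ on a uniform grip-length grid
(l₀ = 10 mm, w₀ = 4 mm rectangular strips — typical for a ~2.5 cm carotid
segment — and t₀ the specimen's thickness draw), truncated at the drawn
rupture stretch, with multiplicative Gaussian force noise (default 1%,
roughly the relative load-cell precision over the measured range; an additive
±0.1 N mode reflecting the stated cell precision is available). Histology
phantoms paint exact pixel counts of the reference colors (fiber fractions)
and non-overlapping disks ≥ 50 px² on a seeded grid (nuclei), with
sub-floor specks available for testing the particle floor; wall annotations
are concentric circles realising the drawn intima-media share. Every
artifact is reproducible from (spec, seed), and a long-format ground-truth
manifest accompanies each cohort.

What the phantoms deliberately do not emulate: staining variability, uneven
illumination, nucleus shape/clustering, real boundary roughness, toe-region
artifacts, or hysteresis. Passing recovery tests therefore demonstrate the
correctness of the measurement operators and the identifiability of the
models under the study's sampling design — not robustness to imaging or
protocol artifacts.

Sampling note: because per-specimen sd = SEM·√n is large relative to the
between-group differences (e.g. opening angle sd ≈ 37°), a single sampled
cohort's group means need not preserve the published between-group orderings;
orderings are asserted on the published group means, recoveries on the
manifest.

## Pipeline and problem sizes

`run_study` executes features → group fits → residual stress → histology with
per-stage toggles, structured logs of every decision (fit starts, test
branches), and deterministic outputs given the seeds. Degenerate comparisons
(constant groups, possible with zero-variance synthetic specs) are recorded
as `test_used = "none"` with a warning instead of aborting the stage.

Default problem sizes, chosen to keep a full study run at desk scale: 120
tensile samples per record, 100-point mean-curve grid, 16 fit starts (early
stop on perfect fits), 400 radial stations per closure solve, 160 px fiber
phantoms and 256 px nucleus phantoms at 1.6–2 µm/px. The identifiability and
noise-robustness test suites use reduced grids (25–30 points, 6–8 starts),
which does not change any conclusion — recovery there is limited by the
model's conditioning, not the grid density.
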