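# Methods

`dxafem` estimates a proximal-femur Risk of Fracture under a sideways fall
from the data a routine DXA exam already provides: a segmented gray-level
image, the three standard ROI mean areal-BMD values, Hip Structural
Analysis (HSA) geometry, and the patient's height and weight.  This note
records the model, its assumptions, the tunable parameters, and the design
choices made where the problem was genuinely open.

## Gray-level to BMD calibration

DXA scanners report mean areal BMD (aBMD, g/cm²) only over the neck,
trochanter and intertrochanter ROIs.  Assuming gray levels are affine in
aBMD, each ROI fixes one line through two anchors:

* the intercept (aBMD at gray 0) is postulated as a fraction *f* of the ROI
  mean — the unknown minimum BMD present in the region;
* the mean of the non-zero grays in the ROI maps exactly onto the reported
  mean aBMD, which fixes the slope *m = mean·(1−f)/ḡ*.

The three per-ROI lines are averaged (arithmetic mean of intercepts and of
slopes) into a single patient relation applied pixel-wise inside the femur
mask; mapped values are clamped below at zero.  Default *f* = 0.20; the
values {0.10, 0.15, 0.25, 0.30} are selectable (`calibration.fraction_f`).
Two choices were open and are fixed as follows: the intercept anchors at
gray 0 (not at the minimum observed gray), and pixels inside the femur but
outside all three ROIs use the averaged line.  By construction a single-ROI
calibration reproduces that ROI's mean aBMD exactly, and the map is
monotone and invariant to affine rescaling of the gray axis.

## Plate model and materials

The femur is idealised as a constant-thickness plane-stress plate.  The
thickness comes from the HSA narrow-neck width *w* by matching a circular
neck section of diameter *w*: matching the cross-section **area** gives
*t = πw/4*; matching the bending **inertia** about the out-of-plane axis
gives *t = 3πw/16*.  A rectangle cannot satisfy both at once, so the
default (`thickness.method = "mean"`) averages the two; both pure matches
are selectable.  Which bending axis the inertia match should use was open;
the out-of-plane axis is the one loaded by an in-plane force.

The density chain per pixel/element is

    rho_vol = aBMD / t        (g/cm³, t in cm)
    rho_app = rho_vol / 0.6   (ash fraction, configurable)
    E(MPa)  = 15010 rho_app^2.18   if rho_app <= 0.28 g/cm³
            =  6850 rho_app^1.49   otherwise

with the low branch applying at the switch point.  Moduli are grouped into
35 equal-width bins spanning the per-patient [min E, max E] (per-patient
range rather than fixed absolute limits — the second open reading), and
every element receives the **median** raw modulus of its bin, so at most 35
distinct stiffnesses enter the solver and no element moves by more than one
bin width.  Interior bin edges assign ties to the lower bin.  Poisson ratio
is not density-dependent: ν = 0.3 uniform (common cortical/trabecular FE
choice), configurable.

The mesh is a pixel-aligned structured grid of square 4-node quadrilaterals
clipped to the mask (target element size 0.5 mm, equal to the default pixel
spacing), which makes the element→pixel association exact and the mesh area
equal to the mask area.  Masks with more than one orthogonally connected
component are rejected.

## Impact force

A 1-DOF spring-mass model of the fall: effective mass 0.5·M falls from
0.51·H, giving impact speed v = √(2g·0.51·H); the trochanteric soft tissue
is a linear contact spring k = 5·10⁴ N/m.  The applied force is the peak
spring force, F = v√(k·m_eff) for the undamped default; for 0 ≤ ζ < 1 the
closed-form underdamped peak is used and a direct time integration of the
oscillator serves as an independent check (they agree to <0.1% as ζ→0).
These four constants follow the common sideways-fall convention; all are
config keys (`impact.*`).  For H = 1.6 m, M = 70 kg the default force is
5293 N.  Overdamped (ζ ≥ 1) impacts are out of scope.

## Boundary conditions and solve

* Impact force on the lateral trochanteric boundary nodes (a configurable
  arc fraction, default the whole lateral arc inside the trochanter ROI),
  inclined 30° counter-clockwise from the in-plane normal of the shaft
  axis.  The shaft axis is fitted from the distal per-row centroids of the
  mask; the medial direction (`bc.medial_direction`) flips the convention
  for mirrored scans and mirrors the rotation sign with it.
* Femoral head grounded through isotropic translational springs on its
  boundary nodes, total stiffness 10 000 N/mm split uniformly.  The source
  convention prints this figure in torque-like units; it is interpreted
  here as total translational stiffness, a config key
  (`bc.head_spring_total_n_per_mm`).  Isotropic springs keep the solution
  equivariant under rigid rotation of the whole model.
* Distal edge nodes rigidly linked (small-rotation kinematics) to a master
  point whose translations are fixed and whose rotation is free — a hinge.

Elements are bilinear plane-stress quadrilaterals with 2×2 Gauss
quadrature; constraints are eliminated through a transformation matrix so
the reduced system stays symmetric positive definite.  It is solved with
Jacobi-preconditioned conjugate gradients (rtol 10⁻¹³) and a sparse-LU
fallback; equilibrium (applied force vs. spring + hinge reactions) is
checked on every solve and sits at ~10⁻¹² relative on the phantoms.
Strains are evaluated at element centroids.

## Risk of Fracture

RF per element divides the prevailing principal strain by its yield limit:
tensile 0.0073, compressive 0.0104 (the strain-criterion limits commonly
used with this approach; both configurable).  "Prevailing" is read as the
larger of the two ratios (`max_ratio`, conservative default); taking the
larger-magnitude strain over its own limit (`max_magnitude`) is selectable.
RF^ is the maximum RF outside the head and trochanteric ROIs, whose
vicinity to the boundary conditions would otherwise dominate; ties break to
the lowest element id.  The RF^ element is labelled intracapsular when it
lies in the neck ROI, extracapsular otherwise (a heuristic).  At cohort
level the pooled per-element RF of all patients (including excluded
elements, which are eligible for pooling though not for RF^) yields the
90th/98th/99.9th percentiles with linear interpolation between order
statistics; a patient is flagged at risk when RF^ exceeds the 99.9th
percentile or reaches 1.

## HSA ranking

Collinearity is pruned by iterative VIF removal (VIF_j = 1/(1−R²_j) from
regressing variable j on the rest; highest first, alphabetical tie-break,
threshold 10 — conventional, configurable).  Every non-empty subset of the
retained predictors is then fitted by OLS against RF^ and scored with
AIC = n·ln(RSS/n) + 2(k+1); Akaike weights w = exp(−Δ/2) (normalised over
the enumerated set) are summed per variable into cumulative weights, the
ranking statistic.  Predictors are standardized before enumeration (no
effect on the ranking; better conditioning).  Plain AIC is the default;
AICc is available (`stats.use_aicc`) and is arguably more appropriate at
n ≈ 28 but changes the measured rankings only marginally.

## The phantom

Real DXA images could not be distributed, so the generator produces fully
controlled stand-ins: a parametric silhouette (shaft rectangle, neck
corridor at the requested neck-shaft angle, head disc, trochanteric
bulge), a density pattern with a denser periosteal shell, and — crucially —
an integer gray field from which the "true" BMD map is *defined* as an
exact affine function.  Storing 16-bit integer grays therefore loses
nothing, and calibration round-trips are machine-exact.  Per-ROI sidecar
means are exact mask-wise means of the truth map.  Image spacing defaults
to 0.5 mm/pixel so the default mesh is pixel-aligned; neither spacing nor
bit depth of the original scanner data is documented anywhere, so these
are free choices.

Cohorts sample the silhouette parameters around post-menopausal female
norms (NSA 125° ± 5°, neck width 32 ± 2.5 mm, HAL 100 ± 6 mm, heights
1.61 ± 0.06 m, weights 65 ± 10 kg, femur-mean aBMD 0.80 ± 0.10 g/cm² with
the T-score derived from the neck mean against a 0.858/0.120 young
reference).  Site-specific density factors (lognormal, sd 0.15) emulate
the discordance between neck and shaft BMD seen across real patients, and
the emitted HSA table carries variable-specific measurement imprecision
(widths ~1.5% CV, derived section ratios ~1.5–2.5%, CSMI ~2.5%, buckling
ratio ~12%, NSA ~1.5°): without it the within-site HSA quantities would be
deterministic functions of each other, which no scanner produces.  A
synthetic reference risk score is built from a configurable effect map
(default: NSA and narrow-neck buckling ratio, equal weights) on the
standardized HSA columns plus Gaussian noise sized for R² ≈ 0.6.

What the phantom does **not** emulate: DXA physics (beam hardening,
soft-tissue overlap, scatter), real anatomical shape variation, cortical/
trabecular compartments, or clinically calibrated strain magnitudes — the
idealised silhouette concentrates strain at the neck corridor, so phantom
RF^ values run higher than clinical ones and the at-risk rule saturates on
the default cohort.  Passing tests therefore demonstrate the correctness
of the machinery (calibration identities, mechanics against analytic
oracles, statistics against enumeration oracles, determinism), not
clinical validity.

## Identifiability of the two-driver recovery study

The ranking recovery study (50 cohorts of n = 28, risk driven by NSA and
NN_BR with R² ≈ 0.6, both expected in the top-2 cumulative weights) is
power-limited: with ~11 post-VIF predictors, even perfectly orthogonal
designs place both drivers top-2 in only ~91% of replicates under plain
AIC (~95% under AICc) at this n and R², and any realistic correlation
among HSA variables reduces that further.  The generator described above
achieves ~74–78%.  The enumeration machinery itself is verified exactly
against brute-force oracles, so the shortfall reflects small-sample
identifiability, not implementation error.

## Problem sizes and runtime choices

Default phantoms rasterise to roughly 210 × 210 pixels (~19 000 elements,
~39 000 dof), solving in ~1–2 s each; the standard study cohort is 28
patients.  The recovery study uses 50 cohorts with statistics only (no FE).
The beam verification uses a 200 × 20 element strip at the standard 0.5 mm
element size.

## Known limitations

* 2D projection: out-of-plane geometry and load paths are absent; strain
  fields near the applied boundary conditions are excluded from RF^ but
  still pollute nearby regions.
* The constant-thickness plate under-represents the head and trochanter
  volumes.
* The trochanteric load patch and the excluded "trochanteric region" share
  the same ROI; their exact anatomical extents are configurable choices.
* Linear elasticity with a strain-ratio criterion: no post-yield behaviour
  or fracture propagation.
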