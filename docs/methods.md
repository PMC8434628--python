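# Methods

`tfusim` simulates continuous-wave transcranial focused ultrasound (tFUS)
from a single-element focused bowl transducer through a parametric
skull-model plate immersed in water, and quantifies how the plate's
structural parameters (thickness T, curvature radius R, standoff distance D)
and acoustic parameters (density ρ, sound speed c, absorption α) attenuate
and shift the focus.

## Governing equation

The acoustic pressure p is advanced with the Westervelt equation,

    L(p) − (1/c²) ∂²p/∂t² + (δ/c⁴) ∂³p/∂t³ + (β/ρc⁴) ∂²p²/∂t² = 0,

with per-cell density ρ, sound speed c, sound diffusivity δ (thermoviscous
absorption), and coefficient of nonlinearity β.  Two modeling choices
deserve explanation:

**Heterogeneous-density operator.**  The spatial operator is implemented as
L(p) = ρ∇·(ρ⁻¹∇p), which reduces to the plain Laplacian inside each material
but produces the physically correct impedance-based reflection and
transmission at material boundaries (pressure transmission T = 2Z₂/(Z₁+Z₂),
Z = ρc, verified to <2% against the closed form in the test suite).  With a
plain ∇² the density map would be acoustically inert — plate density would
then influence the focus only through the tiny nonlinear term, and interface
reflections would depend on sound speed alone.

**Loss term.**  The third-time-derivative loss term is discretized in its
asymptotically equivalent form (δ/c²)·∂t L(p).  A von Neumann analysis shows
that every explicit discretization of ∂³p/∂t³ itself requires δ < c²·dt,
which is violated by orders of magnitude at skull-like absorption (δ reaches
≈ 4.5 m²/s at α = 5000 dB/m, c = 5000 m/s); the ∂t L form is bounded by the
spatial spectrum instead and remains stable under the time-step rule below.
Its exact dispersion relation is k = (ω/c)(1 − iX)^(−1/2) with X = ωδ/c².
For weak absorption Im k → α with the textbook relation δ = 2αc³/ω², but at
skull-like values that relation under-delivers absorption by 10–25%.  The
solver therefore uses a *calibrated* loss coefficient δ′ obtained by
inverting the dispersion relation in closed form,

    g = αc/ω,   u = (1 − 2g² + √(1 − 8g²))/2,   X = 2√u·g/(u + g²)²,
    δ′ = X c²/ω,

so the realized plane-wave decay equals e^(−αx) at the drive frequency (the
1-D decay test holds to ≤2% across the sweep range).  The operator's largest
realizable absorption is g = 1/(2√2) ≈ 0.354 (≈ αλ = 2.2 Np per wavelength);
the two most absorbing sweep settings (α = 5000 dB/m) sit just above this
bound, where δ′ is capped and the realized absorption saturates a few
percent below target.  Both the standard δ and δ′ are exposed on the medium
maps.

The quadratic nonlinearity uses a backward second difference of p² over the
three stored pressure levels, keeping the update explicit; a 1-D test
reproduces the pre-shock Fubini second-harmonic ratio to ≤10%.

## Discretization

* **Grid.**  Uniform, cell-centered; axisymmetric (z, r) by default because
  the scene is rotationally symmetric, with optional full-3D and 1-D modes.
  Resolution presets are expressed in points per wavelength (ppw) in water:
  `paper` = 8, `coarse` = 4 (the standard desk-scale setting used by the
  sweeps: 243×121 cells for the 100×50 mm half-plane), `ci` = 6 for
  miniature scenes.
* **Spatial stencil.**  8th-order centered coefficients per axis.  This is
  load-bearing: at 4 ppw a 2nd-order Laplacian propagates axial waves ~10%
  slow and (because the focus is an interference pattern of rays at 18–39°)
  moves the pure-water focus from ≈79.9 mm to ≈65 mm.  The 8th-order stencil
  keeps the phase-speed error below ~0.1% axially (<0.5% at 8 ppw is
  asserted by test), leaving the coarse-grid focus within ≈1 mm of the
  converged position.  The stencil half-width is clamped (8th→2nd order)
  within four cells of the outer faces; in axisymmetric mode the radial
  stencil is folded across the axis by even symmetry, so the beam axis
  retains full order and r = 0 needs no special treatment (cell centers sit
  at (j+½)dx).  The density correction ρ∇·(ρ⁻¹∇p) − ∇²p is evaluated with
  the 2nd-order conservative flux form; it vanishes identically wherever ρ
  is uniform and localizes interface handling to the cells where ρ jumps.
* **Time stepping.**  Explicit second order.  Stability of the coupled
  wave + loss update is governed by the combined condition s + 2q ≤ 4 at the
  grid Nyquist mode, with s = c²dt²·k̃²max, q = δ′dt·k̃²max and k̃²max the
  stencil eigenvalue (6.50 d/dx² for the 8th-order stencil, against the
  classical 4 d/dx²).  Enforcing the wave and loss bounds separately is not
  sufficient — intermediate (c, α) combinations then diverge.  The default
  time step solves s + 2q = 4·0.8 and is additionally capped at 20 samples
  per drive period; each sweep value gets its own stable dt.
* **Boundaries.**  First-order Mur one-way condition on every outer face
  using the local sound speed (normal-incidence amplitude reflection <1%,
  asserted by test).
* **Source.**  The bowl cap (aperture 100 mm, focal length 80 mm, central
  hole 50 mm, apex at z = 0) is rasterized one cell per transverse footprint.
  The default drive is a *transparent* source: an additive sheet forcing
  2cωp₀·sec θ/dx per cell that radiates surface amplitude p₀ both ways while
  letting returning reflections pass through.  A hard (pressure-overwriting)
  source is available but not default: it mirrors every wave the plate
  reflects back, and the resulting transducer–plate cavity modulates the
  standoff sweep by ±13% between 1-mm steps (the cavity phase period is
  λ/2 ≈ 0.8 mm) and can even invert sweep trends.  Each source cell's drive
  is phase-delayed by ω·Δz·cos θ/c to compensate its sub-cell staircase
  offset from the true cap surface; without this the ±dx/2 rasterization
  error decoheres the focus by 5–10% at 4 ppw.  The drive ramps on over 3
  periods with a cosine envelope.  Focal gain agrees with the O'Neil
  focused-radiator solution to ≤5% (asserted at 8 ppw on a miniature bowl).

## Steady state and amplitude extraction

A run lasts two domain-diagonal traversals at the slowest sound speed plus
15 drive periods, after which every multipath has settled; the per-cell
amplitude is the max |p| over the final 2 periods (harmonics included), or
optionally the sine/cosine quadrature projection at the drive frequency
(exact for a pure tone; used by verification tests).  The relative change of
the peak amplitude between the last two windows is reported as a steady-state
residual (typically <0.1%; a warning is issued above 5%).  The solve path
contains no randomness: identical scenes and settings reproduce bit-identical
fields.

## Source calibration

The experimental drive amplitude behind the published focal pressures is not
public, so absolute pressures are anchored by calibration: a linear run in
pure water is scaled so the focal peak equals 549.3 kPa (the published
pure-water focal pressure), which is exact because the linearized field is
homogeneous of degree 1 in p₀.  All acceptance quantities except the
absolute pressures themselves (positions, lengths, percent drops, dB
slopes) are invariant to this scale.

## Focal metrics

* Focus = arg-max of the amplitude field, axially refined by three-point
  parabolic interpolation; ties break toward the transducer.  For plate
  scenes the search starts 2 mm past the plate's on-axis exit face: with
  strongly absorbing plates the global maximum is the standing field
  *between* transducer and plate, not the transmitted focus.
* −6 dB focal length = contiguous on-axis extent around the focus with
  amplitude ≥ half the peak (the standard half-amplitude convention),
  endpoints linearly interpolated; an error is raised if the region touches
  the domain edge.
* Attenuation: percent drop 100(1 − p/p_ref) and dB 20·log₁₀(p_ref/p).
* Unit attenuation of a sweep: from the ordinary-least-squares line
  y = m·x + b of focal pressure vs parameter, 20·log₁₀(b/(b − |m|·step)) —
  the fitted intercept serves as the "initial" pressure.  This
  intercept-referenced convention is used consistently; see Limitations.
* Power-law fits y = a·xᵇ + c use nonlinear least squares with c₀ slightly
  below min(y), b₀ from the log–log slope of y − c₀, and b bounded to
  [−2, 2] (the decay curves are gently flattening, so a robust start
  matters).  Agreement between two fitted curves is summarized by the
  Pearson correlation of their predictions at the sweep values.

## Sweeps

Six single-parameter sweeps plus one combined sweep, all with the reference
scene (plate T8/R60/D10 fixed unless swept):

| parameter | values | plate material |
|---|---|---|
| T | 2:4:22 mm | acrylic (Table of materials) |
| R | 60:10:100 mm | acrylic |
| D | 11:1:20 mm | acrylic |
| ρ | 1700:30:2000 kg/m³ | skull model (c 3500, α 2600 dB/m fixed) |
| c | 2000:300:5000 m/s | skull model (ρ 1850, α 2600 fixed) |
| α | 200:480:5000 dB/m | skull model (ρ 1850, c 3500 fixed) |
| combined | equal-index (ρ, c, α) triples | skull model |

Sweep absorption values are interpreted as dB/m *at* the 0.9 MHz drive
frequency (1 Np = 8.686 dB).  The skull-model material keeps acrylic's
β = 4.4 (the sweeps specify only ρ, c, α).  Per-value failures are recorded
and the sweep continues.

## What the model does and does not capture

The plate is a homogeneous *fluid* spherical shell: longitudinal-wave
reflection, refraction, thermoviscous absorption, internal thickness
resonances, lens-like focal shifts and nonlinear steepening are all
represented.  Not represented: shear-wave mode conversion and elastic
resonances in the solid plate, surface roughness scattering, trabecular-bone
heterogeneity, and transducer surface non-uniformity.  Physical
plate-transmission losses measured in water tanks are typically much larger
than the fluid prediction from PMMA's bulk absorption — elastic effects
dominate there — so agreement of this model with such measurements should
only be expected for trends, not absolute attenuations (see Limitations).

## Verification summary

All quantities below are computed by the test suite, never asserted from
memory: grid/plate rasterization against closed-form volumes (≤2%); 1-D
phase speed (≤0.5% at 8 ppw); plane-wave decay e^(−αx) (≤2%); Mur
reflection (<1%); impedance-step transmission (≤2%) and lossy slab
transmission (≤3%) against closed forms; focal gain against the O'Neil
solution (≤5%) with the quadrature Rayleigh integral as an independent
cross-check of that oracle (≤0.1%); exact linearity in p₀; Fubini
second-harmonic ratio (≤10%); axisymmetric-vs-3D focal agreement (≤2%,
1 cell); grid convergence from 6 to 12 ppw (≤3%); monotone dissipation in δ.

## Limitations

* The intercept-referenced unit-attenuation convention reproduces the usual
  thickness-sweep number (0.357 dB/mm from the published fit parameters)
  and the distance number within rounding, but no single convention
  reproduces every published unit-attenuation value; the convention is
  therefore fixed and documented rather than varied per sweep.
* The loss operator cannot realize more than ≈2.2 Np of absorption per
  wavelength; the α = 5000 dB/m sweep extremes saturate slightly below
  their nominal absorption.
* At the coarse 4-ppw preset the focal position carries a ≈1 mm
  discretization bias toward the transducer (78.8 mm vs the converged
  79.5–79.7 mm; the analytic peak is at 79.7 mm).
* The −6 dB focal length of this aperture is ≈11.7 mm in linear diffraction
  theory (and ≈11.8 mm simulated); reported measurement-side values of
  ≈9.8 mm are inconsistent with that closed form and are not reproduced.
* Published plate-attenuation magnitudes (e.g. a 56% drop from the 8-mm
  acrylic plate, 81% across the thickness sweep) imply an effective acrylic
  absorption ≈5–6× the tabulated PMMA value and interface physics without
  density contrast; with the tabulated material parameters and
  impedance-correct interfaces this model yields substantially smaller
  structural-sweep drops (≈30% for the reference plate).  The
  absorption-dominated sweeps, which do not depend on that discrepancy,
  are reproduced to within ≈1 percentage point.
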