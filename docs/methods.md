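# Methods

## Physical model and assumptions

A single patent dentinal tubule is modelled as a truncated cone of length
L = 2.5 mm with diameters 1 μm at the dentin–enamel junction (DEJ, x = 0)
and 3 μm at the pulpal end (x = L), filled with stagnant dentinal fluid.
Transport is pure molecular diffusion of one dissolved agent:

* no outward dentinal fluid flow (the clinical situation after the applied
  agent is sealed with an adhesive);
* no adsorption to tubule walls, no reactions, no tubule occlusion;
* diffusion is one-dimensional — concentration is uniform over each cross
  section, so the conical shape enters only through the area profile
  A(x) = π d(x)²/4 with d(x) linear in x;
* both ends are zero-flux: the applied dose is a finite reservoir, the pulp
  is treated as sealed over the planning horizon.

The governing equation is the variable-area diffusion equation
∂C/∂t = (1/A) ∂/∂x (A·D·∂C/∂x). Because it is linear, all concentrations
scale exactly with the initial concentration; absolute units (mg/mL) are
carried but never affect the dynamics.

## Molecular properties

Diffusion coefficients are resolved with priority D > R_s > M_w:

* a registry value of D (the packaged table of eight reference agents) is
  always used verbatim — the table's literature values do not all
  back-derive from the radius relations, so recomputation never overrides
  them;
* a known Stokes radius gives D = k_B·T/(6πμR_s);
* a bare molecular weight first gives the minimal radius
  R_min = 0.066·M_w^(1/3) nm (smooth-sphere protein density), which
  substitutes for R_s.

The default solvent is water at 37 °C (T = 310.15 K) with viscosity
μ = 7.59·10⁻⁴ Pa·s. This viscosity is a deliberate calibration: it makes the
2.2 nm reference protein come out at exactly D = 1.36·10⁻¹⁰ m²/s, the value
the dosing example is built on. The handbook viscosity of water at 37 °C
(6.91·10⁻⁴ Pa·s, giving 1.49·10⁻¹⁰ m²/s for the same radius) is available as
`WATER_37C_HANDBOOK`; the two presets disagree by ~9% and the discrepancy is
inherent to the reference values, not to the implementation. Note that
R_min(50 kDa) = 2.43 nm while the reference protein is quoted at
R_s = 2.2 nm; both paths are exposed and neither is silently preferred.

## Analytic solutions

For a uniform tube with a plane source of strength M (mass per area) at the
sealed end, the field is the cosine eigenfunction series
C(x,t) = (2M/L) Σ exp(−(nπ/L)²Dt) cos(nπx/L) + M_t, with M_t = M/L the
well-mixed limit (forced by mass conservation). Truncation: terms are added
while 2·exp(−(nπ/L)²Dt) ≥ tol (default 10⁻¹⁰), with a hard cap of 10⁵ terms
(the cap binds only for t·D/L² ≲ 10⁻⁷, which raises an error rather than
returning a poorly converged sum). t = 0 is rejected — the series does not
converge pointwise at the Dirac initial instant. Small negative ringing
within tol·M_t is clipped to zero and logged.

A finite-slug variant (uniform concentration over the first fraction f of
the tube; mode amplitudes 2C₀ sin(nπf)/(nπ)) provides the exact counterpart
of the solver's initial condition and is the oracle for convergence studies.

## Finite-volume solver

Cell-centred finite volumes on a uniform grid (default 500 cells). Face
conductances D·A(x_face)/Δx make the scheme conservative by construction:
discrete mass drifts only at round-off (measured ~10⁻¹³ relative over 10⁴
steps). Cell volumes are exact frusta, so the total volume telescopes to
(πL/12)(d₁² + d₁d₂ + d₂²) for any cell count, and the initial slug is laid
down by exact partial-cell frustum volumes so the initial mass is
grid-independent.

Time integration is Crank–Nicolson with the first 50 steps replaced by
backward Euler to damp oscillations from the sharp slug front. The step size
ramps geometrically (factor 1.05 from Δt_max/200) up to a cap expressed as a
diffusion number D·Δt/Δx² ≤ 50 — for the implicit schemes accuracy, not
stability, binds. Concentrations in (−10⁻¹²·C₀, 0) are clipped to zero
(round-off); anything more negative, or non-finite, raises a solver error
naming the offending step.

Verification: on a uniform cylinder with a thin slug (1% of L) the solution
matches the plane-source series within 0.05% of M_t at t* ∈ {0.05, 0.15,
0.5, 2} with 500 cells; the observed spatial order against the exact slug
series is ≈2 (least-squares slope of log error vs log cell count over
50–400 cells). The default source slug occupies 5% of the tubule length —
the breakthrough curve is insensitive to this fraction (pulp ratio at
t* = 0.15 moves from 0.630 to 0.637 between fractions 0.02 and 0.10).

## Breakthrough correlation and its calibration

The pulpal breakthrough collapses in dimensionless time t* = Dt/L². The
correlation family is

    C/C_t = exp(a + b · ln(t*)/t*),

log-linear in u = ln(t*)/t*, fitted/evaluated on a validity range
t* ∈ [0.02, 3] and clamped at the well-mixed limit 1 (with a warning) where
the raw form exceeds it; the strictly increasing branch, on which inversion
is defined, ends at the clamp point (t* ≈ 0.67 for the default parameters).
Inversion is by Brent bisection to relative tolerance better than 10⁻⁹.

Three parameter sets coexist, with recorded provenance:

* **paper** (a = 0.21, b = 0.115): the published constants, kept as
  metadata. Under this family they give ratio(0.15) = 0.288 and
  invert(0.25) = 0.141 — the latter regenerates the published critical-time
  table several minutes (up to 7%) off, so the printed constants are not
  internally consistent with the published worked example and table.
* **anchored** (default): b = 0.115 kept, intercept calibrated in closed
  form so the curve passes exactly through the published operating point
  (t* = 0.15 ↔ ratio 0.25): a = ln(0.25) − b·ln(0.15)/0.15 ≈ 0.0682. A
  calibration gate enforces both directions of the anchor (ratio at 0.15
  within ±0.05 and invert(0.25) within ±0.005); only the anchored set passes
  it. With it the critical-time table regenerates to within ±2 min
  (21/16/7/18/9/7/112/120 vs 21/16/7/17/9/8/113/118 min — the published rows
  themselves are mutually consistent only at about this level, their implied
  t* spanning 0.145–0.161).
* **refit**: least squares of ln(ratio) on u against a solver-generated
  breakthrough curve, restricted to samples with ratio in [0.05, 0.95].
  This ties the correlation to the PDE for the actual geometry: residual RMS
  ≈ 0.02 in ratio units, and the refit-inverted critical time agrees with
  the solver's first-crossing time to ~0.1%.

The anchored and refit parameter sets answer different questions and
deliberately disagree: the 1-D slug-source solver puts the conical pulp
ratio at t* = 0.15 at 0.63, not 0.25 — the published operating point traces
to a 3-D CFD computation whose source condition is not stated, and no
slug/reservoir configuration of the 1-D model reproduces it (a maintained
constant-concentration source gives 0.136; slugs of any extent give
0.63–0.66; the value is also invariant under reversing the cone
orientation). Dose planning therefore uses the anchored set — the one
consistent with the published dosing table — while the refit path is used
for solver cross-validation. This tension is inherent to the source
material; the package records it rather than hiding it.

## Dose planning

`plan_dose` executes: resolve D → t* = Dt/L² → ratio from the correlation →
C_t = C_r/ratio → C₀ = C_t·V_t/V₀ with V_t the frustum volume and V₀ the
source-slug volume (default the 5% slug; the clinically applied volume is a
free parameter). Every plan stores all intermediates and asserts the mass
balance C₀V₀ = C_tV_t to machine precision. Critical times are
t_r = invert(ratio)·L²/D, reported in minutes rounded half-up (the
convention the published table is internally consistent with to ±1 min).
Infeasible requests (t* outside the correlation's validity) raise an error
that reports the feasible time window for the agent.

## Synthetic micro-LIF workflow

The fluorescence module reimplements the intensity→concentration workflow on
synthetic data: a linear sensor model I = slope·C + intercept (valid at the
low Rhodamine B concentrations used, where quantum yield is nearly constant)
plus additive Gaussian noise per pixel per frame, 20-frame bursts, ROI
averaging over a 300×580 μm window (floored to whole pixels), calibration on
standards at 0.05/0.025/0.00 mg/L with the zero standard pinning the
background. Recovered values above the highest calibrated standard are
flagged, not trusted.

What the generator emulates: burst averaging (noise ∝ 1/√n_frames),
calibration-slope error propagation, the 1-D character of the field (axial
profiles broadcast across the transverse direction). What it does not:
shot noise and sensor nonlinearity, illumination inhomogeneity, optical
blur, dye photobleaching, wall effects. Passing the roundtrip therefore
validates the *workflow* (calibration algebra, ROI handling, averaging), not
camera physics.

The end-to-end experiment (`run_synthetic_profile_experiment`) images a
solver-generated profile — Rhodamine B (D = 4.5·10⁻¹⁰ m²/s) in a 3 cm
capillary, dyed half, read at 4 h — at 13 axial stations 1 mm apart, one
burst per station, at noise σ = 2% of the calibration dynamic range. The
recovery error is reported as max |recovered − truth| / max(truth): the
profile decays toward zero at the far stations, where a pointwise relative
error would be ill-defined. Because the ROI mean pools ~1700 pixels × 20
frames, the recovered error is far below the 10% agreement level (~0.03%);
the error decreases monotonically with frame count, as averaged over 20
seeds.

## Problem sizes and numerical defaults

Default runs use 500 cells (solver validation), 300 cells for full
breakthrough curves (the pulp ratio at t* = 0.15 changes by <10⁻⁵ between
300 and 500 cells), and 13 stations / 20 frames / 58×30-pixel fields for the
fluorescence campaign. A full conical breakthrough to t* = 3 takes well
under a second on one core.

## Known limitations

* The correlation's published constants and the published operating point
  cannot both be honoured under any reading of the printed formula; the
  anchored calibration chooses the operating point (see above).
* The 1-D model cannot reproduce the 3-D CFD normalized breakthrough the
  published operating point came from; absolute breakthrough times from
  `simulate` and from the anchored correlation differ accordingly (the
  cross-validation invariant ties the solver only to the *refit*
  correlation).
* Outward dentinal fluid flow, tubule occlusion/permeability factors,
  multi-tubule dentin discs and agent–agent reactions are out of scope.
* The dimensionless time printed for the 2 h worked example, 0.1567,
  truncates (not rounds) to the reported two-decimal 0.15.
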