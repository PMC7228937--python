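# Methods

## Thermodynamic model

A gel phase is described by three additive pressure contributions in
kPa, all functions of the polymer volume fraction φ ∈ (0, 1)
(hydration h ≡ 1/φ):

* **Mixing** (Flory–Huggins): `Π_mix = −(RT/V₁)[ln(1−φ) + φ + χφ²]`,
  with R = 8.314 J/(mol·K), default T = 298.15 K and water molar volume
  V₁ = 18 cm³/mol. The small-φ leading term is (RT/V₁)(½−χ)φ², so good
  solvents (χ < ½) swell and the contribution changes sign through the
  theta point.
* **Elasticity** (ideal affine network): `Π_el = νRT φ₀^{2/3} φ^{1/3}`,
  ν in mol of elastic strands per cm³ of reference gel, φ₀ the volume
  fraction at network formation. The pure φ^{1/3} power form is used —
  without the `−φ/2` correction term some treatments include — so the
  log–log slope of Π_el against φ is exactly 1/3; the difference is
  absorbed into the calibration of ν.
* **Ionic** (ideal Donnan): fixed-charge concentration
  `c_f = α·f_ion·f_eff·φ/v_m` (mol/L, v_m the monomer molar volume in
  cm³/mol), degree of ionization `α = 1/(1+10^{pKa−pH})`
  (Henderson–Hasselbalch), 1:1 bath salt c_s:
  `Π_ion = RT(√(c_f²+4c_s²) − 2c_s) ≥ 0`. `f_eff` is an effective
  charge fraction that lumps counterion condensation and activity
  effects into one attenuation factor; together with the apparent pKa
  it is a calibration knob, not a measured quantity. No Manning theory
  or activity coefficients are attempted.

Free swelling solves Π_sw(φ) = 0; an applied osmotic stress P solves
Π_sw(φ) = P. Roots are found by scanning 256 geometrically spaced
compositions on φ ∈ [10⁻⁴, 0.999] for sign changes and polishing the
largest-φ one (the stable, ∂Π/∂φ > 0, branch) with Brent's method to
an effective pressure residual far below the 10⁻⁶ kPa acceptance
tolerance. The analytic derivative ∂Π/∂φ is implemented alongside for
osmotic moduli, K_os = φ∂Π/∂φ.

## Composite coupling and prestress

A composite (neutral matrix encapsulating charged filler particles,
filler fraction x_f of the total polymer, default 0.5 for a 1:1
mixture) uses the simplest volume-weighted (isostrain) closure at
shared composition:

    Π_comp(φ) = x_f·Π_f(φ) + (1−x_f)·Π_m(φ).

The prestress analysis itself is curve-level and agnostic to how the
two curves were produced: `P_el(h) = max(0, Π_f − Π_comp)`, zero at the
curve intersection, with `P_el^max` defined as `P_el` at the composite
equilibrium (where Π_comp = 0 and hence `P_el^max = Π_f(h_eq)`, equal
to the matrix tension per unit composite volume up to the phase
weights). At the unloaded equilibrium the volume-weighted phase
stresses cancel identically: x_f·Π_f + (1−x_f)·Π_m = Π_comp = 0.

**Known limitation of the additive rule.** Because
dP_el/dh = −(1−x_f)(K_f − K_m)/h, a composite that is stiffer than its
matrix at equilibrium (K_f > K_m there) necessarily has P_el
*declining* just below h_eq: with the shipped presets P_el rises
steeply (more than tenfold) from the intersection, peaks at about
0.75·h_eq, and sags by roughly 20–40% before h_eq. A micromechanical
shell-inflation model in which the filler keeps its own composition
would decouple these two features; it is deliberately out of scope.
`P_el^max` therefore always refers to the equilibrium value, not the
interior peak.

## Preset calibration

No component parameters are measured; the presets are calibrated once
against the qualitative and quantitative behaviour the package is
meant to exhibit, and regression-tested:

* matrix (χ=0.45, φ₀=0.1): ν = 4.781·10⁻⁴ mol/cm³ fixes the matrix
  free-swelling hydration at 10 (`pva1`); `pva2` (ν = 2.383·10⁻⁴)
  swells to 14, encoding only the cross-link-density ordering.
* filler (χ=0.65, φ₀=0.07, v_m=48 cm³/mol, pKa=3.5):
  ν_f = 6.084·10⁻⁴ mol/cm³ and f_eff = 0.1558 are the exact solution of
  two conditions — K_os(composite)/K_os(matrix) = 2 at the pH-7
  composite equilibrium, and filler free-swelling hydration 11 at pH 4
  (just above the matrix's 10, so pH-4 prestress is positive but
  small). The resulting pH series: filler swells to 20.4 / 11.0 / 2.8
  at pH 7 / 4 / 1 in 0.1 M salt; at pH 1 the essentially protonated
  filler never out-swells the matrix, so no intersection and no
  prestress exist.
* The stiffening target shapes the filler strongly: ideal Donnan caps
  K_ion ≤ Π_ion·(1+2c_s/√(c_f²+4c_s²)) ≤ 2Π_ion, so doubling the
  composite modulus while keeping the filler pressure modest at
  equilibrium requires the filler's elastic term (whose modulus costs
  only Π_el/3) to cancel most of its Donnan pressure — hence a filler
  network about as densely cross-linked as the matrix, and an
  effective charge fraction (0.156) below the generic polyacid default
  (0.3).
* cartilage analogs reuse the composite: `healthy` stiffens the matrix
  by 10%, `OA` halves it (a weakened collagen network), all else
  equal. This produces the expected pathology ordering — OA
  equilibrium hydration 17.9 vs 14.2, OA modulus ≈ 30% lower — and
  makes the pH-7 composite curve several times closer (RMS pressure
  difference) to the healthy analog than to the OA one. The tissue
  hydration V_total/V_C is identified with 1/φ with no conversion
  factor; absolute reproduction of measured tissue curves is not
  claimed anywhere.

## Curve analysis numerics

Curves are interpolated with a monotone shape-preserving piecewise
cubic (PCHIP): the swelling curves are strongly nonlinear but
monotone, and an overshoot-free interpolant keeps zero crossings
unique. Zeros and curve intersections are located by a 2048-point
scan plus Brent refinement; values below 10⁻¹² of the curve's pressure
scale count as zeros (interpolants do not return exact 0.0 at knots).
When several intersections exist, the largest-hydration crossing below
the composite equilibrium is reported. Equilibria are never
extrapolated: a curve whose pressure does not reach zero in range
raises an error. Curve-based K_os uses a centered finite difference on
the interpolant with step 10⁻⁴ of the hydration range; it agrees with
the analytic-model derivative to better than 0.5% on smooth inputs.

The Fung-type hyperelastic description of the prestress is the minimal
one-dimensional exponential stress law `P_el = A[exp(b(h−h₀)) − 1]`,
fitted by bounded least squares with a deterministic initialization
(h₀ from the intersection hydration, A and b from a log-linear
pre-fit). On data generated from the law itself the parameters are
recovered to machine precision; on the shipped presets, whose P_el is
concave near equilibrium, the fit is a summary description and its
RMSE is reported alongside.

## Synthetic osmotic-stress experiments

The simulator mirrors the dialysis osmotic-stress technique: the
stressing pressures are exact (set by the experimenter), the measured
quantity is the equilibrium gel composition, and the measurement error
is multiplicative on hydration — mean-one lognormal with coefficient
of variation `noise_cv` (default 0.02; the source experiments report
no error magnitudes, so this is an assumption surfaced in the design
object). All draws derive from a single integer seed through the
counter-based Philox generator, so regeneration is bit-identical
across platforms.

The default stress ladder is 12 log-spaced levels over 0.5–500 kPa,
spanning the nonlinear region of the presets. The shipped *fixture*
bundle instead uses one zero-stress (free-swelling) specimen plus 12
levels over 20–500 kPa at cv = 0.005: between 0 and ~20 kPa the
pressure–hydration curve is nearly flat (K_os/Π ≈ 500 at 0.5 kPa), so
composition noise at closely spaced low-pressure rungs would invert
the pressure ordering of neighbouring points and no noise level keeps
dense low-pressure sampling strictly monotone. Simulated curves are
therefore validated for hydration ordering always, and for strict
pressure monotonicity only when used as analysis inputs.

What the generator does *not* emulate: dialysis kinetics, membrane
effects, the stressing polymer's calibration curve, inter-sample
variability in gel preparation, and any systematic (non-multiplicative)
error. Passing tests on synthetic data show the estimators and
analysis are correct under the stated noise model, not that real
measurements satisfy it.

## Parameter recovery and its information limit

`recover_parameters` fits χ and ν (plus pKa and f_eff for charged
gels) by bounded least squares on log hydration: for each known
stressing pressure the model's equilibrium hydration is compared with
the measured one. Under the lognormal hydration noise this residual is
the maximum-likelihood objective, and it is well behaved near free
swelling where a log-pressure residual diverges. Noiseless data are
recovered to ~10⁻¹⁵ relative error; bias vanishes as cv → 0 and
estimator scatter shrinks with replication.

At cv = 0.05 with 20 points, χ is recovered to a few percent but ν
carries an irreducible uncertainty of ~15% (standard deviation of the
relative error) for the default design: the sensitivity
∂ln h/∂ln ν = Π_el/K_os is bounded near 0.5 for this model family and
is nearly collinear with the χ sensitivity, and a linearized
Cramér–Rao computation shows no 20-point design over any stress range
brings σ_ν/ν below ~0.10. A joint "both parameters within 10%"
success criterion therefore plateaus near 50% at this noise level —
a property of the experiment's information content, not of the
optimizer.

## Problem sizes

Default analyses use 160–400-point hydration grids, 2048-point root
scans with Brent polish, 100-seed recovery studies, and 10⁴-replicate
Monte-Carlo noise checks; the full test suite and the acceptance
script each run in well under a minute on one CPU.
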