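# Methods

## Model structure

The gut is treated as two ideal reactors in series: a continuous
stirred-tank stomach that only stores and delivers the meal, and a
plug-flow small intestine with no axial mixing, constant mean velocity
ū and constant luminal properties.  The meal is a liquid; solids,
gastric disintegration, secretion dilution and nutrient feedback on
emptying are outside the model.

**Gastric emptying** is first-order: the stomach mass follows
M(t) = M₀ e^(−γt) with γ = ln2/t½ (no lag phase).  Starch and glucose
co-present in a meal empty with the same γ.

**Luminal transport** is a 1-D advection–reaction equation.  Glucose is
absorbed at the wall at the first-order volumetric rate
k_a = (2f/r_m)·K: 2/r_m is the surface-to-volume ratio of the luminal
cylinder, f the mucosal amplification of the absorptive area, and K
the overall luminal mass-transfer coefficient from the laminar-tube
Sherwood correlation Sh = 1.62 (Re Sc d/L)^(1/3), i.e.
K = 1.62 (ū D²/(L d))^(1/3).  The diffusivity is Stokes–Einstein,
D = k_B T/(6π μ r₀), so K ∝ μ^(−2/3): luminal viscosity is the single
food property that moves the absorption rate.  Wall/epithelial/blood
resistances are assumed fast (bioaccessibility-limited view), and the
laminar correlation ignores segmentation/peristaltic mixing, so K is
a lower bound at low viscosity.

**Starch hydrolysis** (model 3) is Michaelis–Menten,
rate = V_max S/(K_m + S), with amylase in excess and glucose produced
1:1 by mass (water-of-hydrolysis gain ignored).  The concentration
entering the kinetics is luminal mass per cell volume (chyme fills the
cross-section), converted to molarity with a 180 g/mol monomer mass.

## Parameters

| quantity | default | unit | note |
|---|---|---|---|
| intestine length L | 2.85 | m | |
| intestine radius r_m | 0.018 | m | |
| correlation diameter d | 2·r_m = 0.036 | m | independently overridable, see below |
| surface amplification f | 12 | – | plicae × villi × active fraction |
| mean velocity ū | 1.7×10⁻⁴ | m/s | residence time L/ū ≈ 4.66 h |
| viscosity μ | 10⁻³–10 | Pa s | supported range 10⁻⁴–10² |
| temperature T | 310 | K | |
| glucose Stokes radius r₀ | 0.38 | nm | |
| meal mass | 50 | g | |
| meal volume | 0.5 | L | sets l₀ and the reference concentration |
| entry position l₀ | (3V/4π)^(1/3) ≈ 4.9 | cm | bolus sphere radius |
| half-time t½ | 2 min – 2 h | | |
| V_max | 1–25 | mM/min | K_m = 9 mM |
| energy density | 4 | kcal/g glucose | |

The Boltzmann constant is CODATA 2018 (1.380649×10⁻²³ J/K).  All
internal computation is SI; constructors accept mPa s, mM, mM/min and
min/h half-times and convert on ingest.

**Diameter ambiguity.**  With d = 2·r_m = 0.036 m the defaults give
Re ≈ 6.1 and τ_transfer ≈ 3.04 at 1 mPa s; taking d = r_m = 0.018 m
instead gives Re ≈ 3.1 and τ_transfer ≈ 3.83.  Literature values for
this model family (Re ∼ 3, τ_transfer ≈ 3.4) fall between the two
conventions, so the diameter is exposed as an independent `Geometry`
field rather than silently tuned; the package default reads the
geometry table literally (d = 2·r_m).

## Dimensionless form

With ξ = z/L and τ = t·ū/L the model is governed by
τ_transfer = k_a·L/ū, τ_emptying = γ·L/ū, τ_R = (L/ū)·V_max/G_s0 and
K_m″ = K_m/G_s0.  The reference concentration G_s0 is the meal molar
concentration M₀/(molar mass × meal volume) — the only choice that
makes K_m″ dimensionless against a K_m quoted in mM (50 g in 0.5 L
gives 556 mM, so K_m″ = 0.0162).

The dimensionless solver integrates the mass-fraction density (the
luminal variable that integrates to the fraction of input in the gut).
For model 3 this leaves one free constant: the luminal concentration
seen by the kinetics is the density times `loading` = V_meal/(A·L),
the meal-to-gut volume ratio (0.172 by default).  With that factor the
dimensionless run is exactly the nondimensionalised dimensional run;
the equivalence tests exploit this.  Published dimensionless forms of
this model omit the constant, which is why mapping literature V_max
values onto τ_R is convention-dependent; the convention is explicit
here rather than resolved.

Regime maps evaluate the fraction absorbed at τ = 1 (one residence
time) on log-log (τ_emptying, τ_transfer) grids; dimensional scenario
runs use the 3 h horizon of glycaemic-index practice.  Both horizons
are explicit arguments.

## Numerics

Space: finite-volume first-order upwind on a uniform grid
(default 500 cells), zero advective inflow at z = 0, free outflow at
z = L booked to an `exited` account.  The gastric source enters the
single cell containing l₀ (a discrete delta that conserves mass for
any Δz).  Time: adaptive LSODA with rtol 10⁻⁸, atol 10⁻¹², output
every 60 s.  Cumulative absorbed and exited masses are integrated as
extra state variables, so stomach + lumen + absorbed + exited = input
holds to integrator tolerance (residuals ~10⁻¹⁵ in practice, audited
by `mass_balance_report`).  Small negative concentrations from the
integrator are clipped with a logged count; a run aborts if any value
falls below −10⁻⁶ of the peak concentration (an absolute threshold is
meaningless when concentrations span 10⁶ g/m³).

The upwind scheme's numerical diffusion is accepted as part of the
reference behaviour.  For the linear models it is immaterial while the
slug is inside the tube (absorption there depends only on total
luminal mass), so the solver tracks the closed forms to ~10⁻¹⁴.

**Verification.**  Every model is checked against an independent
grid-free oracle sharing no discretisation code: a piecewise closed
form (model 1), entry-time quadrature with a closed form while no
parcel has exited (model 2), and a mass-weighted ensemble of
per-parcel ODEs along characteristics, each parcel entering at the
plug-flow inlet concentration γM(s)/(ūA) (model 3, 500 parcels at
emptied-mass quantiles).  Agreement gates: 1% (models 1–2), 2%
(model 3) at the default grid.

## Design choices

- The initial bolus occupies z ∈ [0, l₀] at uniform concentration
  mass/(A·l₀); l₀ defaults to the sphere radius of the meal volume.
  The linear models are invariant to l₀ and to meal mass (tested);
  model 3 is not, because concentration enters the kinetics.
- `verify`'s model-3 tolerance is applied at the package's reference
  scenario (30-min half-time, V_max = 9 mM/min); harder scenarios are
  reported truthfully and may exceed it (below).
- A `seed` config key is accepted and echoed for interface uniformity;
  the model contains no randomness and every artifact is reproducible
  bit-for-bit from its JSON sidecar.
- The literature-meals table ships as a small CSV (labels, half-times,
  kcal, viscosity class, measurement method) for regime-map overlays;
  viscosity classes are mapped to representative viscosities
  (LV → 1 mPa s, HV → 0.1 Pa s) only for plotting placement.

## Known limitations

- Model-3 accuracy at the default grid degrades for slow kinetics and
  fast emptying: numerical diffusion spreads the starch slug over more
  saturated-kinetics volume and inflates hydrolysis.  Measured against
  the characteristics oracle (15-min checkpoints, n = 500): 1.2% at
  t½ = 30 min / V_max = 9 mM/min, 2.7% at t½ = 20 min, 5.9% at
  t½ = 20 min / V_max = 4 mM/min; the error falls roughly first-order
  in Δz.  Use a finer grid for slow-kinetics studies.
- Constant viscosity in space and time (secretions ignored), constant
  ū, laminar mass transfer with no segmentation enhancement, single
  nutrient, no glucose inhibition of amylase, no epithelial or blood
  side resistance, no solid-phase behaviour.
- The regime maps inherit the loading convention above; comparisons of
  absolute τ_R values across publications require knowing their
  reference concentration.
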