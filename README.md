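# gutsim

Mechanistic simulation of glucose release and absorption in the human
gut: a perfectly mixed stomach (CSTR) empties a liquid meal
exponentially into a plug-flow small intestine, where starch is
hydrolysed by α-amylase (Michaelis–Menten kinetics) and glucose is
absorbed through the wall at a rate set by luminal viscosity.  The
package is for food/digestion modellers who want to compare the three
candidate rate-limiting steps — gastric emptying, luminal mass transfer,
and starch hydrolysis — on a common dimensionless footing.

## Model

The luminal glucose concentration G(z, t) obeys a 1-D
advection–reaction equation along the intestine (length L, mean
velocity ū, radius r_m, mucosal surface amplification f = 12):

    ∂G/∂t = −ū ∂G/∂z − (2f/r_m) K G

The overall mass-transfer coefficient K comes from the laminar-tube
Sherwood correlation Sh = 1.62 (Re Sc d/L)^(1/3), i.e.
K = 1.62 (ū D²/(L d))^(1/3), with the diffusivity D = k_B T/(6π μ r₀)
from the Stokes–Einstein relation — so K ∝ μ^(−2/3) and viscosity is
the food property that controls absorption.  Three model variants:

1. **Bolus** — glucose starts in the first l₀ metres of the intestine;
2. **Stomach-fed** — the intestine starts empty and receives the
   gastric flux γ G_S(t), γ = ln2/t½;
3. **Starch** — the stomach delivers starch, hydrolysed in the lumen at
   V_max S/(K_m + S) before the product glucose is absorbed.

Nondimensionalising by the residence time L/ū yields the groups
τ_transfer = (2fK/r_m)(L/ū), τ_emptying = γL/ū,
τ_R = (L/ū)V_max/G_s0 and K_m″ = K_m/G_s0, which index the regime maps
produced by `gutsim.scenarios`.  Each PDE solution is verified against
an independent grid-free oracle (method of characteristics /
entry-time quadrature) and a full mass audit
(stomach + lumen + absorbed + exited = input).

## Worked example

```python
import gutsim as g

# watery chyme (1 mPa s): the property chain
water = g.FluidProperties(viscosity=1e-3)
K = g.mass_transfer_coefficient(g.Geometry(), water, g.SoluteProperties())
print(f"K = {K:.3e} m/s")          # K = 1.360e-07 m/s

# 50 g glucose bolus, 3 h
res = g.simulate_model1(50.0, fluid=water)
print(f"absorbed at 3 h: {res.fraction_absorbed[-1]:.3f}")   # 0.859

# honey-like chyme is mass-transfer limited
thick = g.simulate_model1(50.0, fluid=g.FluidProperties(viscosity=0.2))
print(f"absorbed at 3 h: {thick.fraction_absorbed[-1]:.3f}")  # 0.056

# stomach-fed run, 30 min emptying half-time
fed = g.simulate_model2(50.0, g.EmptyingParams(half_time=1800.0))
print(f"absorbed at 3 h: {fed.fraction_absorbed[-1]:.3f}")    # 0.747
```

A watery meal loses about half its glucose in the first hour and ~86%
over three hours; at 0.2 Pa s the wall flux collapses (~6% absorbed),
and feeding through a 30-minute-half-time stomach interpolates between
the two (75%).  The same runs are available from the shell:

```sh
gutsim props --viscosity "1 mPa.s"
gutsim simulate --model 2 --half-time "30 min" --out-dir out/
gutsim regime-map --n-grid 9 --overlay --out-dir out/
gutsim verify --model 3 --half-time "20 min"
```

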