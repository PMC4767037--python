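"""Physical properties and dimensionless groups of the gut transport model.

The absorption side of the model is a chain of three closures evaluated
here: luminal viscosity fixes the glucose diffusivity through the
Stokes–Einstein relation,

    D = k_B T / (6 pi mu r0),

the diffusivity feeds the laminar-tube Sherwood correlation
Sh = 1.62 (Re Sc d/L)^(1/3), which rearranges to an overall luminal
mass-transfer coefficient

    K = 1.62 (u_bar D^2 / (L d))^(1/3),

and K combines with the amplified wall surface (cylinder surface-to-volume
2/r_m times the fold/villi factor f) and the residence time L/u_bar into
the characteristic absorption time tau_transfer = (2 f K / r_m) (L/u_bar).
Because D ∝ 1/mu, K ∝ mu^(-2/3): viscosity is the single food property
that controls wall mass transfer in this model.

All computation is in SI units (m, s, kg, mol, K).  Constructors accept
the units customary in the digestion literature (mPa s, mM, mM/min,
minutes/hours for half-times) and convert on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .exceptions import ConfigurationError, DomainError

#: Boltzmann constant, J/K (CODATA 2018).
BOLTZMANN = 1.380649e-23

#: Molar mass used for the starch-monomer/glucose concentration basis, g/mol.
GLUCOSE_MOLAR_MASS = 180.0

#: Caloric density of glucose, kcal per gram.
KCAL_PER_GRAM_GLUCOSE = 4.0


def _require_positive(name: str, value: float) -> float:
    if not (value > 0.0) or not math.isfinite(value):
        raise DomainError(f"{name} must be strictly positive and finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class Geometry:
    """Small-intestine geometry.

    Parameters
    ----------
    length : float
        Length L of the small intestine, m.
    radius : float
        Mean luminal radius r_m, m.
    diameter : float, optional
        Diameter d used by the Sherwood correlation, m.  Defaults to
        ``2 * radius``; independently overridable because literature
        correlations are ambiguous about whether d or r_m is the
        relevant length scale.
    surface_factor : float
        Dimensionless amplification f of the absorptive surface over a
        smooth cylinder (plicae circulares x villi x active fraction).
    mean_velocity : float
        Mean axial chyme velocity u_bar, m/s.
    """

    length: float = 2.85
    radius: float = 0.018
    diameter: float | None = None
    surface_factor: float = 12.0
    mean_velocity: float = 1.7e-4

    def __post_init__(self) -> None:
        _require_positive("length", self.length)
        _require_positive("radius", self.radius)
        _require_positive("surface_factor", self.surface_factor)
        _require_positive("mean_velocity", self.mean_velocity)
        if self.diameter is None:
            object.__setattr__(self, "diameter", 2.0 * self.radius)
        else:
            _require_positive("diameter", self.diameter)

    @property
    def residence_time(self) -> float:
        """Mean transit time L / u_bar of the small intestine, s."""
        return self.length / self.mean_velocity

    @property
    def cross_section(self) -> float:
        """Luminal cross-sectional area pi r_m^2, m^2."""
        return math.pi * self.radius ** 2

    def with_diameter(self, diameter: float) -> "Geometry":
        return replace(self, diameter=diameter)


@dataclass(frozen=True)
class FluidProperties:
    """Bulk properties of the luminal chyme.

    viscosity in Pa s (supported regime 1e-4 .. 1e2), density in kg/m^3,
    temperature in K (default body temperature, 310 K).
    """

    viscosity: float = 1e-3
    density: float = 1000.0
    temperature: float = 310.0

    def __post_init__(self) -> None:
        _require_positive("viscosity", self.viscosity)
        _require_positive("density", self.density)
        _require_positive("temperature", self.temperature)
        if not (1e-4 <= self.viscosity <= 1e2):
            raise DomainError(
                "viscosity outside the supported regime [1e-4, 1e2] Pa s, "
                f"got {self.viscosity!r}"
            )


@dataclass(frozen=True)
class SoluteProperties:
    """Diffusing solute (glucose by default).

    molecular_radius in m (Stokes radius; must lie in (0, 1e-8) m),
    molar_mass in g/mol, kcal_per_gram in kcal/g.
    """

    molecular_radius: float = 0.38e-9
    molar_mass: float = GLUCOSE_MOLAR_MASS
    kcal_per_gram: float = KCAL_PER_GRAM_GLUCOSE

    def __post_init__(self) -> None:
        _require_positive("molecular_radius", self.molecular_radius)
        _require_positive("molar_mass", self.molar_mass)
        if self.molecular_radius >= 1e-8:
            raise DomainError(
                "molecular_radius must be below 1e-8 m (small-molecule regime), "
                f"got {self.molecular_radius!r}"
            )
        if self.kcal_per_gram < 0:
            raise DomainError(f"kcal_per_gram must be non-negative, got {self.kcal_per_gram!r}")


def gamma_from_half_time(half_time: float) -> float:
    """First-order gastric emptying constant gamma = ln 2 / t_half, 1/s."""
    _require_positive("half_time", half_time)
    return math.log(2.0) / half_time


def half_time_from_gamma(gamma: float) -> float:
    """Inverse of :func:`gamma_from_half_time`."""
    _require_positive("gamma", gamma)
    return math.log(2.0) / gamma


@dataclass(frozen=True)
class EmptyingParams:
    """Exponential gastric emptying: rate constant gamma (1/s) and the
    equivalent half-time t_half = ln2/gamma (s).

    gamma = 0 (no emptying) is allowed; then half_time is infinite.
    """

    gamma: float | None = None
    half_time: float | None = None

    def __post_init__(self) -> None:
        if self.gamma is None and self.half_time is None:
            raise DomainError("EmptyingParams needs gamma or half_time, got neither")
        if self.gamma is None:
            object.__setattr__(self, "gamma", gamma_from_half_time(self.half_time))
        elif self.half_time is None:
            if self.gamma < 0:
                raise DomainError(f"gamma must be non-negative, got {self.gamma!r}")
            ht = math.inf if self.gamma == 0 else half_time_from_gamma(self.gamma)
            object.__setattr__(self, "half_time", ht)
        else:
            if not math.isclose(self.gamma, gamma_from_half_time(self.half_time), rel_tol=1e-9):
                raise DomainError(
                    "gamma and half_time are inconsistent: "
                    f"gamma={self.gamma!r} but ln2/half_time={gamma_from_half_time(self.half_time)!r}"
                )

    @classmethod
    def from_half_time(cls, half_time: float) -> "EmptyingParams":
        return cls(half_time=half_time)

    @classmethod
    def from_gamma(cls, gamma: float) -> "EmptyingParams":
        return cls(gamma=gamma)


@dataclass(frozen=True)
class KineticsParams:
    """Michaelis–Menten kinetics of luminal starch hydrolysis by alpha-amylase.

    Stored in SI-adjacent molar units: vmax in mol L^-1 s^-1, km in mol/L.
    Use :meth:`from_mM` for the customary mM/min and mM.
    """

    vmax: float
    km: float

    def __post_init__(self) -> None:
        _require_positive("vmax", self.vmax)
        _require_positive("km", self.km)

    @classmethod
    def from_mM(cls, vmax_mM_per_min: float, km_mM: float) -> "KineticsParams":
        return cls(vmax=vmax_mM_per_min * 1e-3 / 60.0, km=km_mM * 1e-3)

    @property
    def vmax_mM_per_min(self) -> float:
        return self.vmax * 60.0 * 1e3

    @property
    def km_mM(self) -> float:
        return self.km * 1e3


@dataclass(frozen=True)
class DimensionlessGroups:
    """Dimensionless characterisation of one run.

    tau_transfer compares wall absorption to transit, tau_emptying compares
    gastric emptying to transit, tau_reaction compares hydrolysis capacity
    to transit, and km_scaled is the Michaelis constant normalised with the
    reference (meal) concentration.
    """

    reynolds: float | None = None
    schmidt: float | None = None
    sherwood: float | None = None
    tau_transfer: float | None = None
    tau_emptying: float | None = None
    tau_reaction: float | None = None
    km_scaled: float | None = None

    def __post_init__(self) -> None:
        for name in ("reynolds", "schmidt", "sherwood", "tau_transfer",
                     "tau_emptying", "tau_reaction", "km_scaled"):
            value = getattr(self, name)
            if value is not None and (value < 0 or not math.isfinite(value)):
                raise DomainError(f"{name} must be non-negative and finite, got {value!r}")


def diffusivity(fluid: FluidProperties, solute: SoluteProperties) -> float:
    """Stokes–Einstein diffusivity D = k_B T / (6 pi mu r0), m^2/s."""
    return BOLTZMANN * fluid.temperature / (
        6.0 * math.pi * fluid.viscosity * solute.molecular_radius
    )


def mass_transfer_coefficient(
    geometry: Geometry, fluid: FluidProperties, solute: SoluteProperties
) -> float:
    """Overall luminal mass-transfer coefficient K, m/s.

    Laminar-tube (Leveque-type) correlation Sh = 1.62 (Re Sc d/L)^(1/3)
    rearranged to K = 1.62 (u_bar D^2 / (L d))^(1/3).
    """
    D = diffusivity(fluid, solute)
    return 1.62 * (geometry.mean_velocity * D * D / (geometry.length * geometry.diameter)) ** (1.0 / 3.0)


def reynolds(geometry: Geometry, fluid: FluidProperties) -> float:
    """Tube Reynolds number Re = rho u_bar d / mu."""
    return fluid.density * geometry.mean_velocity * geometry.diameter / fluid.viscosity


def schmidt(fluid: FluidProperties, solute: SoluteProperties) -> float:
    """Schmidt number Sc = mu / (rho D)."""
    return fluid.viscosity / (fluid.density * diffusivity(fluid, solute))


def sherwood(geometry: Geometry, fluid: FluidProperties, solute: SoluteProperties) -> float:
    """Sherwood number Sh = 1.62 (Re Sc d/L)^(1/3); satisfies Sh D / d = K."""
    Re = reynolds(geometry, fluid)
    Sc = schmidt(fluid, solute)
    return 1.62 * (Re * Sc * geometry.diameter / geometry.length) ** (1.0 / 3.0)


def absorption_rate_constant(
    geometry: Geometry, fluid: FluidProperties, solute: SoluteProperties
) -> float:
    """First-order wall absorption rate k_a = 2 f K / r_m, 1/s.

    2/r_m is the surface-to-volume ratio of the luminal cylinder and f
    the mucosal surface amplification.
    """
    K = mass_transfer_coefficient(geometry, fluid, solute)
    return 2.0 * geometry.surface_factor * K / geometry.radius


def reference_concentration(
    mass_g: float, meal_volume_l: float = 0.5, solute: SoluteProperties | None = None
) -> float:
    """Reference molar concentration of the meal, mol/L.

    The meal mass dissolved in the swallowed volume (default 0.5 L, a
    typical liquid test meal); used to normalise tau_reaction and K_m.
    """
    _require_positive("mass_g", mass_g)
    _require_positive("meal_volume_l", meal_volume_l)
    solute = solute or SoluteProperties()
    return mass_g / (solute.molar_mass * meal_volume_l)


def characteristic_times(
    geometry: Geometry,
    fluid: FluidProperties,
    solute: SoluteProperties,
    emptying: EmptyingParams | None = None,
    kinetics: KineticsParams | None = None,
    ref_conc: float | None = None,
) -> DimensionlessGroups:
    """Assemble all dimensionless groups for one parameter set.

    tau_transfer = (2 f K / r_m) (L / u_bar)
    tau_emptying = gamma L / u_bar              (requires `emptying`)
    tau_reaction = (L / u_bar) V_max / G_ref    (requires `kinetics` + `ref_conc`)
    km_scaled    = K_m / G_ref

    `ref_conc` is the reference (meal) molar concentration in mol/L,
    e.g. from :func:`reference_concentration`.
    """
    residence = geometry.residence_time
    tau_transfer = absorption_rate_constant(geometry, fluid, solute) * residence
    tau_emptying = None if emptying is None else emptying.gamma * residence
    tau_reaction = None
    km_scaled = None
    if kinetics is not None:
        if ref_conc is None:
            raise DomainError("ref_conc must be given alongside kinetics (mol/L)")
        _require_positive("ref_conc", ref_conc)
        tau_reaction = residence * kinetics.vmax / ref_conc
        km_scaled = kinetics.km / ref_conc
    return DimensionlessGroups(
        reynolds=reynolds(geometry, fluid),
        schmidt=schmidt(fluid, solute),
        sherwood=sherwood(geometry, fluid, solute),
        tau_transfer=tau_transfer,
        tau_emptying=tau_emptying,
        tau_reaction=tau_reaction,
        km_scaled=km_scaled,
    )
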