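"""Run configuration: schema, unit-aware parsing, validation.

Configurations are YAML or JSON mappings with snake_case keys.  Numeric
fields accept either a plain number (interpreted in the field's
canonical unit) or a string with an explicit unit drawn from the
whitelist customary in the digestion literature: Pa s / mPa s for
viscosity, s / min / h for times, m / cm / mm / nm for lengths,
g / kg for masses, mM for concentrations and mM/min for V_max.
Unknown keys are rejected.  All quantities are converted to SI on
ingest; derived quantities (D, K, gamma, dimensionless groups) are
logged at startup by the CLI.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .exceptions import ConfigurationError
from .properties import (
    EmptyingParams,
    FluidProperties,
    Geometry,
    KineticsParams,
    SoluteProperties,
)
from .solver import DEFAULT_MEAL_VOLUME_L, GridSpec

logger = logging.getLogger(__name__)

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")

# unit -> factor to the canonical unit of each kind
_UNITS = {
    "viscosity_Pa_s": {"": 1.0, "pas": 1.0, "pa.s": 1.0, "mpas": 1e-3, "mpa.s": 1e-3},
    "time_s": {"": 1.0, "s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0},
    "length_m": {"": 1.0, "m": 1.0, "cm": 1e-2, "mm": 1e-3, "nm": 1e-9},
    "mass_g": {"": 1.0, "g": 1.0, "kg": 1e3},
    "velocity_m_s": {"": 1.0, "m/s": 1.0},
    "conc_mM": {"": 1.0, "mm": 1.0},
    "conc_rate_mM_min": {"": 1.0, "mm/min": 1.0},
    "temperature_K": {"": 1.0, "k": 1.0},
    "density_kg_m3": {"": 1.0, "kg/m3": 1.0, "kg/m^3": 1.0},
    "volume_L": {"": 1.0, "l": 1.0, "ml": 1e-3},
    "rate_per_s": {"": 1.0, "1/s": 1.0, "/s": 1.0},
    "dimensionless": {"": 1.0},
}


def parse_quantity(value: Any, kind: str) -> float:
    """Parse a number or a "value unit" string to the canonical unit of `kind`."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if not isinstance(value, str):
        raise ConfigurationError(f"cannot parse quantity from {value!r} (kind {kind})")
    m = _QUANTITY_RE.match(value)
    if not m:
        raise ConfigurationError(f"malformed quantity {value!r} (kind {kind})")
    number, unit = m.groups()
    unit_key = unit.replace("·", ".").replace(" ", "").lower()
    table = _UNITS[kind]
    if unit_key not in table:
        raise ConfigurationError(
            f"unit {unit!r} not allowed for {kind}; expected one of "
            f"{sorted(u for u in table if u)}, received {value!r}"
        )
    try:
        return float(number) * table[unit_key]
    except ValueError as err:
        raise ConfigurationError(f"malformed number in {value!r}: {err}") from err


def _q(kind: str):
    """Pydantic before-validator converting unit strings for `kind`."""

    def validate(value):
        if value is None:
            return None
        return parse_quantity(value, kind)

    return validate


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Block):
    length: float = 2.85
    radius: float = 0.018
    diameter: Optional[float] = None
    surface_factor: float = 12.0
    mean_velocity: float = 1.7e-4

    _len = field_validator("length", "radius", "diameter", mode="before")(_q("length_m"))
    _vel = field_validator("mean_velocity", mode="before")(_q("velocity_m_s"))

    def build(self) -> Geometry:
        return Geometry(length=self.length, radius=self.radius, diameter=self.diameter,
                        surface_factor=self.surface_factor, mean_velocity=self.mean_velocity)


class FluidConfig(_Block):
    viscosity: float = 1e-3
    density: float = 1000.0
    temperature: float = 310.0

    _mu = field_validator("viscosity", mode="before")(_q("viscosity_Pa_s"))
    _rho = field_validator("density", mode="before")(_q("density_kg_m3"))
    _T = field_validator("temperature", mode="before")(_q("temperature_K"))

    def build(self) -> FluidProperties:
        return FluidProperties(viscosity=self.viscosity, density=self.density,
                               temperature=self.temperature)


class SoluteConfig(_Block):
    molecular_radius: float = 0.38e-9
    molar_mass: float = 180.0
    kcal_per_gram: float = 4.0

    _r = field_validator("molecular_radius", mode="before")(_q("length_m"))

    def build(self) -> SoluteProperties:
        return SoluteProperties(molecular_radius=self.molecular_radius,
                                molar_mass=self.molar_mass,
                                kcal_per_gram=self.kcal_per_gram)


class EmptyingConfig(_Block):
    half_time: Optional[float] = None
    gamma: Optional[float] = None

    _t = field_validator("half_time", mode="before")(_q("time_s"))
    _g = field_validator("gamma", mode="before")(_q("rate_per_s"))

    def build(self) -> EmptyingParams:
        return EmptyingParams(gamma=self.gamma, half_time=self.half_time)


class KineticsConfig(_Block):
    vmax: float = 9.0  # mM/min
    km: float = 9.0  # mM

    _v = field_validator("vmax", mode="before")(_q("conc_rate_mM_min"))
    _k = field_validator("km", mode="before")(_q("conc_mM"))

    def build(self) -> KineticsParams:
        return KineticsParams.from_mM(self.vmax, self.km)


class MealConfig(_Block):
    mass: float = 50.0  # g
    volume: float = DEFAULT_MEAL_VOLUME_L  # L
    l0: Optional[float] = None  # m; defaults to the bolus sphere radius

    _m = field_validator("mass", mode="before")(_q("mass_g"))
    _v = field_validator("volume", mode="before")(_q("volume_L"))
    _l = field_validator("l0", mode="before")(_q("length_m"))


class GridConfig(_Block):
    n_cells: int = 500
    scheme: str = "first_order_upwind"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12

    def build(self) -> GridSpec:
        return GridSpec(n_cells=self.n_cells, scheme=self.scheme,
                        rel_tol=self.rel_tol, abs_tol=self.abs_tol)


class RunConfig(_Block):
    """Fully validated run configuration with Table-2-style defaults."""

    model: int = 1
    geometry: GeometryConfig = GeometryConfig()
    fluid: FluidConfig = FluidConfig()
    solute: SoluteConfig = SoluteConfig()
    emptying: Optional[EmptyingConfig] = None
    kinetics: Optional[KineticsConfig] = None
    meal: MealConfig = MealConfig()
    grid: GridConfig = GridConfig()
    horizon: float = 10800.0  # s
    output_interval: float = 60.0  # s
    out_dir: Optional[str] = None
    log_level: str = "INFO"
    seed: Optional[int] = None  # recorded for interface uniformity; unused

    _h = field_validator("horizon", "output_interval", mode="before")(_q("time_s"))

    @field_validator("model")
    @classmethod
    def _check_model(cls, v):
        if v not in (1, 2, 3):
            raise ValueError(f"model must be 1, 2 or 3, got {v!r}")
        return v

    def require_emptying(self) -> EmptyingParams:
        if self.emptying is None:
            raise ConfigurationError(
                f"model {self.model} requires an 'emptying' block (half_time or gamma)"
            )
        return self.emptying.build()

    def require_kinetics(self) -> KineticsParams:
        if self.kinetics is None:
            raise ConfigurationError(
                "model 3 requires a 'kinetics' block (vmax in mM/min, km in mM)"
            )
        return self.kinetics.build()


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config file, applying flat overrides.

    `overrides` is a mapping of dotted keys (e.g. ``fluid.viscosity``) to
    values; None values are ignored.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as err:
            raise ConfigurationError(f"cannot parse config {path}: {err}") from err
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} must be a mapping")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        target = raw
        parts = key.split(".")
        for part in parts[:-1]:
            target = target.setdefault(part, {})
            if not isinstance(target, dict):
                raise ConfigurationError(f"cannot override {key!r}: {part!r} is not a block")
        target[parts[-1]] = value
    try:
        return RunConfig(**raw)
    except ValidationError as err:
        raise ConfigurationError(str(err)) from err


def startup_report(config: RunConfig) -> dict:
    """Derived quantities for logging at startup (D, K, groups, gamma)."""
    from .properties import characteristic_times, reference_concentration
    from .properties import diffusivity, mass_transfer_coefficient

    geometry = config.geometry.build()
    fluid = config.fluid.build()
    solute = config.solute.build()
    emptying = config.emptying.build() if config.emptying else None
    kinetics = config.kinetics.build() if config.kinetics else None
    ref = (
        reference_concentration(config.meal.mass, config.meal.volume, solute)
        if kinetics
        else None
    )
    groups = characteristic_times(geometry, fluid, solute, emptying, kinetics, ref)
    report = {
        "diffusivity_m2_s": diffusivity(fluid, solute),
        "mass_transfer_K_m_s": mass_transfer_coefficient(geometry, fluid, solute),
        "reynolds": groups.reynolds,
        "schmidt": groups.schmidt,
        "sherwood": groups.sherwood,
        "tau_transfer": groups.tau_transfer,
        "tau_emptying": groups.tau_emptying,
        "tau_reaction": groups.tau_reaction,
        "km_scaled": groups.km_scaled,
        "gamma_per_s": emptying.gamma if emptying else None,
    }
    for key, value in report.items():
        if value is not None:
            logger.info("%s = %.6g", key, value)
    return report
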