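"""Method-of-lines solver for luminal transport, hydrolysis and absorption.

The small intestine is a plug-flow tube of length L carrying chyme at a
constant mean velocity u_bar.  Concentrations obey a 1-D
advection–reaction equation; three model variants of increasing
complexity are solved on the same first-order upwind ("backward finite
difference") spatial discretisation:

* model 1 — a glucose bolus placed in the first l0 metres of the tube is
  advected and absorbed through the wall at the first-order rate
  k_a = 2 f K / r_m (viscosity enters through K);
* model 2 — the intestine starts empty and is fed by the exponentially
  emptying stomach, the gastric flux entering the cell that contains l0;
* model 3 — the stomach delivers starch, which is hydrolysed to glucose
  at a Michaelis–Menten rate before the glucose is absorbed as in
  model 2 (1:1 conversion by mass).

All three are also available in dimensionless form on xi = z/L,
tau = t u_bar / L, which is what the regime maps sweep.

The state vector carries, besides the gridded concentrations, the
stomach mass and the cumulative absorbed and exited masses, so that
`stomach + luminal + absorbed + exited = input` holds to integrator
tolerance at every output time and is audited by
:func:`mass_balance_report`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, DomainError, SolverError
from .properties import (
    EmptyingParams,
    FluidProperties,
    Geometry,
    KineticsParams,
    SoluteProperties,
    absorption_rate_constant,
    characteristic_times,
    reference_concentration,
)

logger = logging.getLogger(__name__)

#: Default liquid meal volume, L.
DEFAULT_MEAL_VOLUME_L = 0.5

#: Fraction of the peak historical concentration below which (negatively)
#: the run is aborted instead of clipped.  Small integrator undershoots
#: above this are clipped with a logged count.
NEGATIVE_ABORT_FRACTION = 1e-6


def bolus_entry_length(meal_volume_l: float = DEFAULT_MEAL_VOLUME_L) -> float:
    """Entry position l0 = radius of a sphere of the meal volume, m."""
    if meal_volume_l <= 0:
        raise DomainError(f"meal_volume_l must be positive, got {meal_volume_l!r}")
    return (3.0 * meal_volume_l * 1e-3 / (4.0 * math.pi)) ** (1.0 / 3.0)


DEFAULT_L0 = bolus_entry_length()


@dataclass(frozen=True)
class GridSpec:
    """Spatial/temporal discretisation controls."""

    n_cells: int = 500
    scheme: str = "first_order_upwind"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_cells < 50:
            raise ConfigurationError(f"n_cells must be >= 50, got {self.n_cells!r}")
        if self.scheme != "first_order_upwind":
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        for name in ("rel_tol", "abs_tol"):
            v = getattr(self, name)
            if not (0.0 < v < 1e-2):
                raise ConfigurationError(f"{name} must lie in (0, 1e-2), got {v!r}")


@dataclass(frozen=True)
class Grid:
    """Uniform finite-volume grid over [0, L] with attached cross-section."""

    centers: np.ndarray
    dz: float
    length: float
    area: float

    @property
    def n_cells(self) -> int:
        return self.centers.size

    @property
    def cell_volume(self) -> float:
        return self.area * self.dz

    @property
    def total_volume(self) -> float:
        return self.area * self.length


def build_grid(geometry: Geometry, spec: GridSpec) -> Grid:
    """Uniform cells covering [0, L]; area = pi r_m^2 for mass <-> conc."""
    n = spec.n_cells
    dz = geometry.length / n
    centers = (np.arange(n) + 0.5) * dz
    return Grid(centers=centers, dz=dz, length=geometry.length, area=geometry.cross_section)


@dataclass
class LuminalState:
    """Gridded concentration profiles (g/m^3) plus cumulative bookkeeping (g)."""

    cell_centers: np.ndarray
    glucose_conc: np.ndarray
    starch_conc: np.ndarray
    absorbed_mass: float = 0.0
    exited_mass: float = 0.0


def initial_bolus(mass: float, l0: float, grid: Grid) -> LuminalState:
    """Uniform slug of `mass` grams in z in [0, l0] (partial cells weighted)."""
    if mass < 0:
        raise DomainError(f"mass must be non-negative, got {mass!r}")
    if not (0.0 < l0 < grid.length):
        raise DomainError(f"l0 must lie strictly inside (0, {grid.length}), got {l0!r}")
    left_edges = grid.centers - 0.5 * grid.dz
    overlap = np.clip(l0 - left_edges, 0.0, grid.dz)
    conc = (mass / (grid.area * l0)) * (overlap / grid.dz)
    return LuminalState(
        cell_centers=grid.centers,
        glucose_conc=conc,
        starch_conc=np.zeros_like(conc),
    )


def michaelis_menten_rate(starch_conc, kinetics: KineticsParams, abs_tol: float = 1e-12):
    """Hydrolysis rate V_max S/(K_m + S) in mol L^-1 s^-1 for S in mol/L.

    Small negative concentrations (solver undershoot) are clipped to zero
    with a logged warning; values below -abs_tol raise.
    """
    S = np.asarray(starch_conc, dtype=float)
    if np.any(S < -abs_tol):
        raise DomainError(
            f"starch_conc below -abs_tol ({-abs_tol}): min {S.min()!r}"
        )
    n_neg = int(np.count_nonzero(S < 0))
    if n_neg:
        logger.warning("clipped %d negative starch concentration(s) to zero", n_neg)
        S = np.maximum(S, 0.0)
    out = kinetics.vmax * S / (kinetics.km + S)
    return out if out.ndim else float(out)


@dataclass
class SimulationResult:
    """Time series of one run (all masses in the run's mass unit, grams
    for dimensional runs, fraction of input for dimensionless ones)."""

    times: np.ndarray
    stomach_glucose: np.ndarray
    stomach_starch: np.ndarray
    luminal_glucose: np.ndarray
    luminal_starch: np.ndarray
    absorbed: np.ndarray
    exited: np.ndarray
    fraction_absorbed: np.ndarray
    absorbed_kcal_rate: Optional[np.ndarray]
    params_echo: dict
    input_mass: float
    exited_glucose: np.ndarray = None
    exited_starch: np.ndarray = None
    glucose_profiles: Optional[np.ndarray] = None
    starch_profiles: Optional[np.ndarray] = None
    grid: Optional[Grid] = None

    def mass_balance_residuals(self) -> np.ndarray:
        """|input - (stomach + luminal + absorbed + exited)| / input per time."""
        if self.input_mass == 0:
            return np.zeros_like(self.times)
        total = (
            self.stomach_glucose
            + self.stomach_starch
            + self.luminal_glucose
            + self.luminal_starch
            + self.absorbed
            + self.exited
        )
        return np.abs(self.input_mass - total) / self.input_mass

    def to_dataframe(self):
        import pandas as pd

        data = {
            "time_s": self.times,
            "stomach_g": self.stomach_glucose + self.stomach_starch,
            "luminal_g": self.luminal_glucose + self.luminal_starch,
            "absorbed_g": self.absorbed,
            "exited_g": self.exited,
            "fraction_absorbed": self.fraction_absorbed,
        }
        if self.absorbed_kcal_rate is not None:
            data["kcal_per_min"] = self.absorbed_kcal_rate
        return pd.DataFrame(data)


@dataclass
class MassBalanceReport:
    residuals: np.ndarray
    max_residual: float


def mass_balance_report(result: SimulationResult) -> MassBalanceReport:
    """Per-timepoint relative conservation residuals and their maximum."""
    r = result.mass_balance_residuals()
    return MassBalanceReport(residuals=r, max_residual=float(r.max()) if r.size else 0.0)


def _t_eval(horizon: float, interval: float) -> np.ndarray:
    t = np.arange(0.0, horizon, interval)
    return np.append(t, horizon)


def _src_cell(l0: float, grid: Grid) -> int:
    idx = int(l0 / grid.dz)
    return min(idx, grid.n_cells - 1)


def _integrate(
    *,
    grid: Grid,
    u: float,
    k_a: float,
    horizon: float,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
    glucose0: np.ndarray | None = None,
    stomach_glucose0: float = 0.0,
    stomach_starch0: float = 0.0,
    gamma: float = 0.0,
    src_cell: int = 0,
    vmax_c: float = 0.0,
    km_c: float = 0.0,
):
    """Shared method-of-lines core.

    Concentrations in mass per volume of the grid's units; `vmax_c`/`km_c`
    already converted to those units (zero vmax_c disables the starch
    species for models 1-2).
    """
    n = grid.n_cells
    dz, area = grid.dz, grid.area
    cell_vol = grid.cell_volume
    has_starch = vmax_c > 0.0 or stomach_starch0 > 0.0
    uodz = u / dz

    if glucose0 is None:
        glucose0 = np.zeros(n)

    if not has_starch:
        # y = [G(n), stomach_glucose, absorbed, exited_glucose]
        y0 = np.concatenate([glucose0, [stomach_glucose0, 0.0, 0.0]])

        def rhs(t, y):
            G = y[:n]
            Ms = y[n]
            Gpos = np.maximum(G, 0.0)
            dy = np.empty_like(y)
            dG = dy[:n]
            dG[0] = -uodz * G[0]
            dG[1:] = -uodz * (G[1:] - G[:-1])
            dG -= k_a * Gpos
            if gamma > 0.0:
                dG[src_cell] += gamma * Ms / cell_vol
            dy[n] = -gamma * Ms
            dy[n + 1] = k_a * Gpos.sum() * cell_vol
            dy[n + 2] = u * G[n - 1] * area
            return dy

    else:
        # y = [G(n), S(n), stomach_starch, absorbed, exited_G, exited_S]
        y0 = np.concatenate([glucose0, np.zeros(n), [stomach_starch0, 0.0, 0.0, 0.0]])

        def rhs(t, y):
            G = y[:n]
            S = y[n : 2 * n]
            Ms = y[2 * n]
            Gpos = np.maximum(G, 0.0)
            Spos = np.maximum(S, 0.0)
            hyd = vmax_c * Spos / (km_c + Spos) if vmax_c > 0.0 else 0.0
            dy = np.empty_like(y)
            dG = dy[:n]
            dS = dy[n : 2 * n]
            dG[0] = -uodz * G[0]
            dG[1:] = -uodz * (G[1:] - G[:-1])
            dS[0] = -uodz * S[0]
            dS[1:] = -uodz * (S[1:] - S[:-1])
            dG += hyd - k_a * Gpos
            dS -= hyd
            if gamma > 0.0:
                dS[src_cell] += gamma * Ms / cell_vol
            dy[2 * n] = -gamma * Ms
            dy[2 * n + 1] = k_a * Gpos.sum() * cell_vol
            dy[2 * n + 2] = u * G[n - 1] * area
            dy[2 * n + 3] = u * S[n - 1] * area
            return dy

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(
            f"time integration failed: {sol.message}",
            last_state=sol.y[:, -1] if sol.y.size else None,
            diagnostics={"message": sol.message, "nfev": sol.nfev},
        )

    G_prof = sol.y[:n].T
    if has_starch:
        S_prof = sol.y[n : 2 * n].T
        stomach = sol.y[2 * n]
        absorbed = sol.y[2 * n + 1]
        exited_g = sol.y[2 * n + 2]
        exited_s = sol.y[2 * n + 3]
    else:
        S_prof = np.zeros_like(G_prof)
        stomach = sol.y[n]
        absorbed = sol.y[n + 1]
        exited_g = sol.y[n + 2]
        exited_s = np.zeros_like(exited_g)

    all_conc = np.concatenate([G_prof.ravel(), S_prof.ravel()])
    peak = float(np.max(all_conc)) if all_conc.size else 0.0
    worst = float(np.min(all_conc)) if all_conc.size else 0.0
    if peak > 0 and worst < -NEGATIVE_ABORT_FRACTION * peak:
        raise SolverError(
            f"negative concentration {worst:.3e} below abort threshold "
            f"({-NEGATIVE_ABORT_FRACTION * peak:.3e})",
            last_state=sol.y[:, -1],
        )
    n_clipped = int(np.count_nonzero(G_prof < 0) + np.count_nonzero(S_prof < 0))
    if n_clipped:
        logger.info("clipped %d small negative concentration values in output", n_clipped)
        G_prof = np.maximum(G_prof, 0.0)
        S_prof = np.maximum(S_prof, 0.0)

    return sol.t, G_prof, S_prof, stomach, absorbed, exited_g, exited_s, has_starch


def _package_result(
    t,
    G_prof,
    S_prof,
    stomach,
    absorbed,
    exited_g,
    exited_s,
    *,
    grid: Grid,
    input_mass: float,
    k_a: float,
    kcal_per_gram: float | None,
    params: dict,
    stomach_is_starch: bool,
) -> SimulationResult:
    cell_vol = grid.cell_volume
    luminal_glucose = G_prof.sum(axis=1) * cell_vol
    luminal_starch = S_prof.sum(axis=1) * cell_vol
    frac = absorbed / input_mass if input_mass > 0 else np.zeros_like(absorbed)
    kcal_rate = None
    if kcal_per_gram is not None:
        # instantaneous absorption rate k_a * luminal glucose mass, g/s
        kcal_rate = k_a * luminal_glucose * 60.0 * kcal_per_gram
    zeros = np.zeros_like(stomach)
    return SimulationResult(
        times=t,
        stomach_glucose=zeros if stomach_is_starch else stomach,
        stomach_starch=stomach if stomach_is_starch else zeros,
        luminal_glucose=luminal_glucose,
        luminal_starch=luminal_starch,
        absorbed=absorbed,
        exited=exited_g + exited_s,
        exited_glucose=exited_g,
        exited_starch=exited_s,
        fraction_absorbed=frac,
        absorbed_kcal_rate=kcal_rate,
        params_echo=params,
        input_mass=input_mass,
        glucose_profiles=G_prof,
        starch_profiles=S_prof,
        grid=grid,
    )


def _common_params(geometry, fluid, solute, grid_spec, horizon, l0, extra):
    p = {
        "geometry": {
            "length_m": geometry.length,
            "radius_m": geometry.radius,
            "diameter_m": geometry.diameter,
            "surface_factor": geometry.surface_factor,
            "mean_velocity_m_per_s": geometry.mean_velocity,
        },
        "fluid": {
            "viscosity_Pa_s": fluid.viscosity,
            "density_kg_per_m3": fluid.density,
            "temperature_K": fluid.temperature,
        },
        "solute": {
            "molecular_radius_m": solute.molecular_radius,
            "molar_mass_g_per_mol": solute.molar_mass,
            "kcal_per_gram": solute.kcal_per_gram,
        },
        "grid": {
            "n_cells": grid_spec.n_cells,
            "scheme": grid_spec.scheme,
            "rel_tol": grid_spec.rel_tol,
            "abs_tol": grid_spec.abs_tol,
        },
        "horizon_s": horizon,
        "l0_m": l0,
    }
    p.update(extra)
    return p


def simulate_model1(
    mass: float,
    geometry: Geometry | None = None,
    fluid: FluidProperties | None = None,
    solute: SoluteProperties | None = None,
    grid_spec: GridSpec | None = None,
    horizon: float = 10800.0,
    l0: float | None = None,
    output_interval: float = 60.0,
) -> SimulationResult:
    """Glucose bolus placed directly in the intestine, advected and absorbed."""
    geometry = geometry or Geometry()
    fluid = fluid or FluidProperties()
    solute = solute or SoluteProperties()
    grid_spec = grid_spec or GridSpec()
    if horizon <= 0:
        raise DomainError(f"horizon must be positive, got {horizon!r}")
    l0 = DEFAULT_L0 if l0 is None else l0
    grid = build_grid(geometry, grid_spec)
    state0 = initial_bolus(mass, l0, grid)
    k_a = absorption_rate_constant(geometry, fluid, solute)
    out = _integrate(
        grid=grid,
        u=geometry.mean_velocity,
        k_a=k_a,
        horizon=horizon,
        t_eval=_t_eval(horizon, output_interval),
        rtol=grid_spec.rel_tol,
        atol=grid_spec.abs_tol,
        glucose0=state0.glucose_conc,
    )
    params = _common_params(
        geometry, fluid, solute, grid_spec, horizon, l0,
        {"model": 1, "mass_g": mass, "k_a_per_s": k_a},
    )
    return _package_result(
        *out[:7], grid=grid, input_mass=mass, k_a=k_a,
        kcal_per_gram=solute.kcal_per_gram, params=params, stomach_is_starch=False,
    )


def simulate_model2(
    mass: float,
    emptying: EmptyingParams,
    geometry: Geometry | None = None,
    fluid: FluidProperties | None = None,
    solute: SoluteProperties | None = None,
    grid_spec: GridSpec | None = None,
    horizon: float = 10800.0,
    l0: float | None = None,
    output_interval: float = 60.0,
) -> SimulationResult:
    """Stomach-fed glucose: exponential gastric emptying into an initially
    empty intestine, with the gastric flux entering the cell containing l0."""
    geometry = geometry or Geometry()
    fluid = fluid or FluidProperties()
    solute = solute or SoluteProperties()
    grid_spec = grid_spec or GridSpec()
    if horizon <= 0:
        raise DomainError(f"horizon must be positive, got {horizon!r}")
    l0 = DEFAULT_L0 if l0 is None else l0
    grid = build_grid(geometry, grid_spec)
    if not (0.0 < l0 < grid.length):
        raise DomainError(f"l0 must lie strictly inside (0, {grid.length}), got {l0!r}")
    k_a = absorption_rate_constant(geometry, fluid, solute)
    out = _integrate(
        grid=grid,
        u=geometry.mean_velocity,
        k_a=k_a,
        horizon=horizon,
        t_eval=_t_eval(horizon, output_interval),
        rtol=grid_spec.rel_tol,
        atol=grid_spec.abs_tol,
        stomach_glucose0=mass,
        gamma=emptying.gamma,
        src_cell=_src_cell(l0, grid),
    )
    params = _common_params(
        geometry, fluid, solute, grid_spec, horizon, l0,
        {"model": 2, "mass_g": mass, "k_a_per_s": k_a,
         "emptying": {"gamma_per_s": emptying.gamma, "half_time_s": emptying.half_time}},
    )
    return _package_result(
        *out[:7], grid=grid, input_mass=mass, k_a=k_a,
        kcal_per_gram=solute.kcal_per_gram, params=params, stomach_is_starch=False,
    )


def simulate_model3(
    starch_mass: float,
    emptying: EmptyingParams,
    kinetics: KineticsParams,
    meal_volume_l: float = DEFAULT_MEAL_VOLUME_L,
    geometry: Geometry | None = None,
    fluid: FluidProperties | None = None,
    solute: SoluteProperties | None = None,
    grid_spec: GridSpec | None = None,
    horizon: float = 10800.0,
    l0: float | None = None,
    output_interval: float = 60.0,
) -> SimulationResult:
    """Stomach-fed starch, hydrolysed to glucose in the lumen, then absorbed.

    The Michaelis–Menten concentration basis is luminal chyme filling the
    cross-section: cell mass / (A dz), converted to molarity with the
    solute molar mass; starch -> glucose is 1:1 by mass.
    """
    geometry = geometry or Geometry()
    fluid = fluid or FluidProperties()
    solute = solute or SoluteProperties()
    grid_spec = grid_spec or GridSpec()
    if horizon <= 0:
        raise DomainError(f"horizon must be positive, got {horizon!r}")
    l0 = bolus_entry_length(meal_volume_l) if l0 is None else l0
    grid = build_grid(geometry, grid_spec)
    if not (0.0 < l0 < grid.length):
        raise DomainError(f"l0 must lie strictly inside (0, {grid.length}), got {l0!r}")
    k_a = absorption_rate_constant(geometry, fluid, solute)
    # mol/L -> g/m^3: x molar_mass (g/mol) x 1000 (L/m^3)
    to_gm3 = solute.molar_mass * 1000.0
    out = _integrate(
        grid=grid,
        u=geometry.mean_velocity,
        k_a=k_a,
        horizon=horizon,
        t_eval=_t_eval(horizon, output_interval),
        rtol=grid_spec.rel_tol,
        atol=grid_spec.abs_tol,
        stomach_starch0=starch_mass,
        gamma=emptying.gamma,
        src_cell=_src_cell(l0, grid),
        vmax_c=kinetics.vmax * to_gm3,
        km_c=kinetics.km * to_gm3,
    )
    groups = characteristic_times(
        geometry, fluid, solute, emptying, kinetics,
        ref_conc=reference_concentration(starch_mass, meal_volume_l, solute),
    )
    params = _common_params(
        geometry, fluid, solute, grid_spec, horizon, l0,
        {"model": 3, "mass_g": starch_mass, "k_a_per_s": k_a,
         "meal_volume_l": meal_volume_l,
         "emptying": {"gamma_per_s": emptying.gamma, "half_time_s": emptying.half_time},
         "kinetics": {"vmax_mM_per_min": kinetics.vmax_mM_per_min, "km_mM": kinetics.km_mM},
         "groups": {"tau_transfer": groups.tau_transfer,
                    "tau_emptying": groups.tau_emptying,
                    "tau_reaction": groups.tau_reaction,
                    "km_scaled": groups.km_scaled}},
    )
    return _package_result(
        *out[:7], grid=grid, input_mass=starch_mass, k_a=k_a,
        kcal_per_gram=solute.kcal_per_gram, params=params, stomach_is_starch=True,
    )


#: Default ratio of meal volume to intestinal volume; sets the scale of
#: the luminal concentration entering Michaelis-Menten in the
#: dimensionless model 3 (see docs/methods.md).
DEFAULT_LOADING = DEFAULT_MEAL_VOLUME_L * 1e-3 / (Geometry().cross_section * Geometry().length)

DEFAULT_L0_FRACTION = DEFAULT_L0 / Geometry().length


def simulate_dimensionless(
    model: int,
    groups,
    grid_spec: GridSpec | None = None,
    horizon_tau: float = 1.0,
    l0_fraction: float | None = None,
    loading: float = DEFAULT_LOADING,
    n_outputs: int = 181,
) -> SimulationResult:
    """Integrate the dimensionless equations on xi in [0, 1], tau in [0, horizon_tau].

    The luminal variable is the mass-fraction density (integrates to the
    fraction of input currently in the gut).  For model 3 the
    concentration entering Michaelis–Menten is that density times
    `loading` = V_meal/(A L), the ratio of meal volume to intestinal
    volume, so that `tau_reaction`/`km_scaled` keep the meal-concentration
    normalisation used by :func:`gutsim.properties.characteristic_times`.
    """
    if model not in (1, 2, 3):
        raise ConfigurationError(f"model must be 1, 2 or 3, got {model!r}")
    grid_spec = grid_spec or GridSpec()
    if horizon_tau <= 0:
        raise DomainError(f"horizon_tau must be positive, got {horizon_tau!r}")
    l0_fraction = DEFAULT_L0_FRACTION if l0_fraction is None else l0_fraction
    if not (0.0 < l0_fraction < 1.0):
        raise DomainError(f"l0_fraction must lie in (0, 1), got {l0_fraction!r}")

    tau_t = getattr(groups, "tau_transfer", None)
    if tau_t is None:
        raise ConfigurationError("groups.tau_transfer is required")
    tau_e = getattr(groups, "tau_emptying", None)
    tau_r = getattr(groups, "tau_reaction", None)
    km_sc = getattr(groups, "km_scaled", None)
    if model in (2, 3) and tau_e is None:
        raise ConfigurationError("groups.tau_emptying is required for models 2 and 3")
    if model == 3 and (tau_r is None or km_sc is None):
        raise ConfigurationError(
            "groups.tau_reaction and groups.km_scaled are required for model 3"
        )
    if loading <= 0:
        raise DomainError(f"loading must be positive, got {loading!r}")

    grid = Grid(
        centers=(np.arange(grid_spec.n_cells) + 0.5) / grid_spec.n_cells,
        dz=1.0 / grid_spec.n_cells,
        length=1.0,
        area=1.0,
    )
    t_eval = np.linspace(0.0, horizon_tau, n_outputs)
    kwargs = dict(
        grid=grid,
        u=1.0,
        k_a=tau_t,
        horizon=horizon_tau,
        t_eval=t_eval,
        rtol=grid_spec.rel_tol,
        atol=grid_spec.abs_tol,
    )
    if model == 1:
        state0 = initial_bolus(1.0, l0_fraction, grid)
        kwargs["glucose0"] = state0.glucose_conc
    elif model == 2:
        kwargs.update(stomach_glucose0=1.0, gamma=tau_e, src_cell=_src_cell(l0_fraction, grid))
    else:
        kwargs.update(
            stomach_starch0=1.0,
            gamma=tau_e,
            src_cell=_src_cell(l0_fraction, grid),
            vmax_c=tau_r / loading,
            km_c=km_sc / loading,
        )
    out = _integrate(**kwargs)
    params = {
        "model": model,
        "dimensionless": True,
        "tau_transfer": tau_t,
        "tau_emptying": tau_e,
        "tau_reaction": tau_r,
        "km_scaled": km_sc,
        "loading": loading,
        "l0_fraction": l0_fraction,
        "horizon_tau": horizon_tau,
        "grid": {"n_cells": grid_spec.n_cells, "scheme": grid_spec.scheme,
                 "rel_tol": grid_spec.rel_tol, "abs_tol": grid_spec.abs_tol},
    }
    return _package_result(
        *out[:7], grid=grid, input_mass=1.0, k_a=tau_t,
        kcal_per_gram=None, params=params, stomach_is_starch=(model == 3),
    )
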