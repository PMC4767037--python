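"""Parameter-sweep drivers that regenerate the model's result surfaces.

Four sweeps cover the standard presentation of this model family:
absorption versus viscosity (bolus model), absorption versus gastric
half-time (stomach-fed model), the (tau_emptying, tau_transfer) regime
map of the dimensionless stomach-fed model evaluated after one
residence time, and the same map sliced over the characteristic
reaction time tau_R of starch hydrolysis.  A packaged table of
literature liquid meals (half-times, kcal) supports overlaying real
meals on the regime map.

Sweeps are deterministic; every result embeds the configuration needed
to reproduce it.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DomainError, SolverError
from .properties import (
    DimensionlessGroups,
    EmptyingParams,
    FluidProperties,
    Geometry,
    KineticsParams,
    SoluteProperties,
    characteristic_times,
    gamma_from_half_time,
)
from .solver import (
    DEFAULT_LOADING,
    GridSpec,
    simulate_dimensionless,
    simulate_model1,
    simulate_model2,
    simulate_model3,
)

#: The one fully specified starch run of the reference analysis:
#: 20 min emptying half-time, water-like viscosity, V_max swept over
#: 4/9/16 mM/min at K_m = 9 mM for a 50 g meal.
REFERENCE_HYDROLYSIS_SCENARIO = {
    "mass_g": 50.0,
    "half_time_s": 1200.0,
    "viscosity_Pa_s": 1e-3,
    "vmax_mM_per_min": (4.0, 9.0, 16.0),
    "km_mM": 9.0,
}


@dataclass
class SweepResult:
    """Response surface of one sweep.

    `axes` maps axis name to the swept values; `response` has the shape
    of the outer product of the axes and holds fraction absorbed at
    `evaluation_time`; `metadata` echoes the configuration; `curves`
    optionally carries full time series per sweep point.
    """

    axes: dict
    response: np.ndarray
    evaluation_time: float
    metadata: dict
    curves: dict | None = None

    def __post_init__(self) -> None:
        expected = tuple(len(v) for v in self.axes.values())
        if tuple(self.response.shape) != expected:
            raise DomainError(
                f"response shape {self.response.shape} does not match axes {expected}"
            )

    def to_long_dataframe(self) -> pd.DataFrame:
        names = list(self.axes)
        grids = np.meshgrid(*self.axes.values(), indexing="ij")
        data = {n: g.ravel() for n, g in zip(names, grids)}
        data["fraction_absorbed"] = self.response.ravel()
        return pd.DataFrame(data)

    def to_matrix_dataframe(self) -> pd.DataFrame:
        if len(self.axes) != 2:
            raise DomainError("matrix layout needs exactly two axes")
        (rname, rvals), (cname, cvals) = self.axes.items()
        return pd.DataFrame(self.response, index=pd.Index(rvals, name=rname),
                            columns=pd.Index(cvals, name=cname))


def kcal_conversion(mass_rate_g_per_s: float, solute: SoluteProperties | None = None):
    """Convert a glucose mass rate (g/s) to a caloric rate (kcal/min)."""
    rate = np.asarray(mass_rate_g_per_s, dtype=float)
    if np.any(rate < 0):
        raise DomainError(f"mass_rate must be non-negative, got {mass_rate_g_per_s!r}")
    solute = solute or SoluteProperties()
    out = rate * 60.0 * solute.kcal_per_gram
    return out if out.ndim else float(out)


def viscosity_sweep(
    n_points: int = 20,
    mu_range: tuple = (1e-3, 10.0),
    horizon: float = 10800.0,
    mass: float = 50.0,
    geometry: Geometry | None = None,
    solute: SoluteProperties | None = None,
    grid_spec: GridSpec | None = None,
) -> SweepResult:
    """Bolus-model absorption across log-spaced luminal viscosities.

    Returns absorbed fraction at `horizon` per viscosity; `curves` holds
    the absorbed-vs-time and kcal/min series and the tau_transfer of
    each viscosity for the dimensionless presentation.
    """
    geometry = geometry or Geometry()
    solute = solute or SoluteProperties()
    mus = np.logspace(np.log10(mu_range[0]), np.log10(mu_range[1]), n_points)
    fracs = np.empty(n_points)
    tau_ts = np.empty(n_points)
    absorbed_curves, kcal_curves, times = [], [], None
    for i, mu in enumerate(mus):
        fluid = FluidProperties(viscosity=float(mu))
        try:
            res = simulate_model1(mass, geometry, fluid, solute, grid_spec, horizon)
        except SolverError as err:
            raise SolverError(f"viscosity sweep failed at mu={mu:.4g} Pa s: {err}") from err
        fracs[i] = res.fraction_absorbed[-1]
        tau_ts[i] = characteristic_times(geometry, fluid, solute).tau_transfer
        times = res.times
        absorbed_curves.append(res.absorbed)
        kcal_curves.append(res.absorbed_kcal_rate)
    return SweepResult(
        axes={"viscosity_Pa_s": mus},
        response=fracs,
        evaluation_time=horizon,
        metadata={"mass_g": mass, "horizon_s": horizon, "model": 1,
                  "n_points": n_points, "mu_range_Pa_s": list(mu_range)},
        curves={"times_s": times, "absorbed_g": np.array(absorbed_curves),
                "kcal_per_min": np.array(kcal_curves), "tau_transfer": tau_ts},
    )


def emptying_sweep(
    half_times: tuple = (900.0, 1800.0, 3600.0),
    mu: float = 1e-3,
    horizon: float = 10800.0,
    mass: float = 50.0,
    geometry: Geometry | None = None,
    solute: SoluteProperties | None = None,
    grid_spec: GridSpec | None = None,
) -> SweepResult:
    """Stomach-fed model across gastric half-times at fixed viscosity."""
    geometry = geometry or Geometry()
    solute = solute or SoluteProperties()
    fluid = FluidProperties(viscosity=mu)
    half_times = np.asarray(half_times, dtype=float)
    if np.any(half_times <= 0):
        raise DomainError(f"half_times must be positive, got {half_times!r}")
    fracs = np.empty(half_times.size)
    stomach_curves, absorbed_curves, times = [], [], None
    for i, ht in enumerate(half_times):
        res = simulate_model2(mass, EmptyingParams(half_time=float(ht)),
                              geometry, fluid, solute, grid_spec, horizon)
        fracs[i] = res.fraction_absorbed[-1]
        times = res.times
        stomach_curves.append(res.stomach_glucose)
        absorbed_curves.append(res.absorbed)
    return SweepResult(
        axes={"half_time_s": half_times},
        response=fracs,
        evaluation_time=horizon,
        metadata={"mass_g": mass, "viscosity_Pa_s": mu, "horizon_s": horizon, "model": 2},
        curves={"times_s": times, "stomach_g": np.array(stomach_curves),
                "absorbed_g": np.array(absorbed_curves)},
    )


def _log_axis(rng, n):
    return np.logspace(np.log10(rng[0]), np.log10(rng[1]), n)


def regime_map(
    tau_emptying_range: tuple = (0.5, 100.0),
    tau_transfer_range: tuple = (0.1, 100.0),
    n_grid: int = 5,
    horizon_tau: float = 1.0,
    grid_spec: GridSpec | None = None,
) -> SweepResult:
    """Fraction absorbed at tau = horizon_tau on a log-log
    (tau_emptying, tau_transfer) grid of the dimensionless stomach-fed model."""
    if n_grid < 5:
        raise DomainError(f"n_grid must be >= 5, got {n_grid!r}")
    if min(*tau_emptying_range, *tau_transfer_range) <= 0:
        raise DomainError("regime map ranges must be positive")
    tau_e = _log_axis(tau_emptying_range, n_grid)
    tau_t = _log_axis(tau_transfer_range, n_grid)
    resp = np.empty((n_grid, n_grid))
    for i, te in enumerate(tau_e):
        for j, tt in enumerate(tau_t):
            groups = DimensionlessGroups(tau_transfer=float(tt), tau_emptying=float(te))
            try:
                res = simulate_dimensionless(2, groups, grid_spec, horizon_tau)
            except SolverError as err:
                raise SolverError(
                    f"regime map failed at tau_e={te:.4g}, tau_t={tt:.4g}: {err}"
                ) from err
            resp[i, j] = res.fraction_absorbed[-1]
    return SweepResult(
        axes={"tau_emptying": tau_e, "tau_transfer": tau_t},
        response=resp,
        evaluation_time=horizon_tau,
        metadata={"model": 2, "dimensionless": True, "horizon_tau": horizon_tau,
                  "n_grid": n_grid},
    )


def reaction_regime_map(
    tau_R_values: tuple = (1.0, 5.0, 25.0),
    tau_emptying_range: tuple = (0.5, 100.0),
    tau_transfer_range: tuple = (0.1, 100.0),
    n_grid: int = 5,
    horizon_tau: float = 1.0,
    km_scaled: float = 0.0162,
    loading: float = DEFAULT_LOADING,
    grid_spec: GridSpec | None = None,
) -> SweepResult:
    """Starch-model regime maps, one (tau_emptying, tau_transfer) slice
    per characteristic reaction time tau_R."""
    tau_R_values = np.asarray(tau_R_values, dtype=float)
    if np.any(tau_R_values <= 0):
        raise DomainError(f"tau_R_values must be positive, got {tau_R_values!r}")
    tau_e = _log_axis(tau_emptying_range, n_grid)
    tau_t = _log_axis(tau_transfer_range, n_grid)
    resp = np.empty((tau_R_values.size, n_grid, n_grid))
    for k, tr in enumerate(tau_R_values):
        for i, te in enumerate(tau_e):
            for j, tt in enumerate(tau_t):
                groups = DimensionlessGroups(
                    tau_transfer=float(tt), tau_emptying=float(te),
                    tau_reaction=float(tr), km_scaled=km_scaled,
                )
                res = simulate_dimensionless(3, groups, grid_spec, horizon_tau,
                                             loading=loading)
                resp[k, i, j] = res.fraction_absorbed[-1]
    return SweepResult(
        axes={"tau_reaction": tau_R_values, "tau_emptying": tau_e, "tau_transfer": tau_t},
        response=resp,
        evaluation_time=horizon_tau,
        metadata={"model": 3, "dimensionless": True, "horizon_tau": horizon_tau,
                  "km_scaled": km_scaled, "loading": loading, "n_grid": n_grid},
    )


def hydrolysis_rate_sweep(
    vmax_mM_per_min: tuple | None = None,
    km_mM: float | None = None,
    mass: float | None = None,
    half_time: float | None = None,
    mu: float | None = None,
    horizon: float = 10800.0,
    grid_spec: GridSpec | None = None,
) -> SweepResult:
    """Dimensional starch runs across hydrolysis V_max values.

    Defaults to :data:`REFERENCE_HYDROLYSIS_SCENARIO`.
    """
    ref = REFERENCE_HYDROLYSIS_SCENARIO
    vmaxes = np.asarray(vmax_mM_per_min or ref["vmax_mM_per_min"], dtype=float)
    km = km_mM if km_mM is not None else ref["km_mM"]
    mass = mass if mass is not None else ref["mass_g"]
    half_time = half_time if half_time is not None else ref["half_time_s"]
    mu = mu if mu is not None else ref["viscosity_Pa_s"]
    fluid = FluidProperties(viscosity=mu)
    emptying = EmptyingParams(half_time=half_time)
    fracs = np.empty(vmaxes.size)
    absorbed_curves, times = [], None
    for i, vm in enumerate(vmaxes):
        res = simulate_model3(mass, emptying, KineticsParams.from_mM(float(vm), km),
                              fluid=fluid, grid_spec=grid_spec, horizon=horizon)
        fracs[i] = res.fraction_absorbed[-1]
        times = res.times
        absorbed_curves.append(res.absorbed)
    return SweepResult(
        axes={"vmax_mM_per_min": vmaxes},
        response=fracs,
        evaluation_time=horizon,
        metadata={"model": 3, "mass_g": mass, "half_time_s": half_time,
                  "viscosity_Pa_s": mu, "km_mM": km, "horizon_s": horizon},
        curves={"times_s": times, "absorbed_g": np.array(absorbed_curves)},
    )


def load_literature_meals() -> pd.DataFrame:
    """Packaged table of literature liquid-meal gastric-emptying studies
    (meal label, half-time in minutes, kcal, viscosity class, method)."""
    with importlib.resources.files("gutsim.data").joinpath(
        "literature_meals.csv"
    ).open("r") as fh:
        return pd.read_csv(fh)


def meals_to_groups(
    meals: pd.DataFrame | None = None,
    geometry: Geometry | None = None,
    solute: SoluteProperties | None = None,
    viscosity_by_class: dict | None = None,
) -> pd.DataFrame:
    """Map literature meals onto (tau_emptying, tau_transfer) for map overlays.

    Each meal's half-time gives tau_emptying = gamma L / u_bar; its
    viscosity class is mapped to a representative viscosity (defaults:
    LV -> 1 mPa s, HV -> 0.1 Pa s) to place it on the tau_transfer axis.
    """
    meals = load_literature_meals() if meals is None else meals.copy()
    geometry = geometry or Geometry()
    solute = solute or SoluteProperties()
    viscosity_by_class = viscosity_by_class or {"LV": 1e-3, "HV": 0.1}
    residence = geometry.residence_time
    meals["tau_emptying"] = [
        gamma_from_half_time(60.0 * ht) * residence for ht in meals["half_time_min"]
    ]
    tau_ts = []
    for cls in meals["viscosity_class"]:
        mu = viscosity_by_class.get(cls)
        if mu is None:
            tau_ts.append(np.nan)
        else:
            fluid = FluidProperties(viscosity=mu)
            tau_ts.append(characteristic_times(geometry, fluid, solute).tau_transfer)
    meals["tau_transfer"] = tau_ts
    return meals
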