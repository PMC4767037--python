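"""Grid-free reference solutions used to verify the PDE solver.

The advection equation is hyperbolic, so every fluid parcel travels at
u_bar and its chemistry reduces to an ODE along the characteristic.
That yields closed forms for the linear models and a per-parcel ODE
ensemble for the nonlinear one:

* model 1 — a bolus parcel starting at z0 is absorbed first-order while
  in the gut, so the absorbed fraction is 1 - exp(-k_a min(t, (L-z0)/u));
  averaging over the slug gives a piecewise closed form;
* model 2 — parcels enter at l0 at the gastric rate gamma e^(-gamma s);
  superposition gives a closed form while no parcel has exited and an
  entry-time quadrature afterwards;
* model 3 — each entering parcel carries starch at the plug-flow inlet
  concentration gamma M_S(s)/(u A) and obeys
  dS/dt = -MM(S), dG/dt = MM(S) - k_a G along its characteristic;
  the ensemble is integrated as one ODE system and mass-weighted.

None of these share discretisation code with :mod:`gutsim.solver`;
agreement between the two routes is the primary correctness gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp

from .exceptions import DomainError
from .properties import Geometry, KineticsParams


@dataclass(frozen=True)
class OracleResult:
    times: np.ndarray
    fraction_absorbed: np.ndarray
    method: str


def _geometry_scalars(geometry: Geometry | None):
    g = geometry or Geometry()
    return g.length, g.mean_velocity, g.cross_section


def model1_closed_form(t, k_a: float, geometry: Geometry | None = None,
                       l0: float | None = None) -> np.ndarray | float:
    """Fraction of a bolus absorbed by time t (piecewise closed form)."""
    L, u, _ = _geometry_scalars(geometry)
    from .solver import DEFAULT_L0

    l0 = DEFAULT_L0 if l0 is None else l0
    if not (0.0 < l0 < L):
        raise DomainError(f"l0 must lie in (0, {L}), got {l0!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError(f"t must be non-negative, got {t!r}")
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _model1_scalar(ti, k_a, L, u, l0)
    return out if np.ndim(t) else float(out[0])


def _model1_scalar(t: float, k_a: float, L: float, u: float, l0: float) -> float:
    if k_a <= 0.0 or t == 0.0:
        return 0.0
    first_exit = (L - l0) / u
    if t <= first_exit:
        return 1.0 - math.exp(-k_a * t)
    # parcels with initial position z0 >= a = L - u t have exited, frozen at
    # absorbed fraction 1 - exp(-k_a (L - z0)/u); the rest are still absorbing.
    a = max(L - u * t, 0.0)
    in_gut = (a / l0) * (1.0 - math.exp(-k_a * t)) if a > 0 else 0.0
    # integral of exp(-k_a (L - z0)/u) dz0 over [a, l0]
    anti = (u / k_a) * (
        math.exp(-k_a * (L - l0) / u) - math.exp(-k_a * (L - a) / u)
    )
    exited = ((l0 - a) - anti) / l0
    return in_gut + exited


def model2_quadrature(t, k_a: float, gamma: float,
                      geometry: Geometry | None = None,
                      l0: float | None = None) -> np.ndarray | float:
    """Fraction absorbed for the stomach-fed linear model.

    Closed-form superposition while every emptied parcel is still in the
    gut; adaptive entry-time quadrature once parcels start exiting or
    when gamma ~ k_a makes the closed form ill-conditioned.
    """
    L, u, _ = _geometry_scalars(geometry)
    from .solver import DEFAULT_L0

    l0 = DEFAULT_L0 if l0 is None else l0
    residence = (L - l0) / u
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError(f"t must be non-negative, got {t!r}")
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _model2_scalar(ti, k_a, gamma, residence)
    return out if np.ndim(t) else float(out[0])


def _model2_scalar(t: float, k_a: float, gamma: float, residence: float) -> float:
    if k_a <= 0.0 or gamma <= 0.0 or t == 0.0:
        return 0.0

    def parcel(s):
        return gamma * math.exp(-gamma * s) * (
            1.0 - math.exp(-k_a * min(t - s, residence))
        )

    ill_conditioned = abs(gamma - k_a) < 1e-6 * max(gamma, k_a)
    if t <= residence and not ill_conditioned:
        return (1.0 - math.exp(-gamma * t)) - gamma / (gamma - k_a) * (
            math.exp(-k_a * t) - math.exp(-gamma * t)
        )
    val, _ = quad(parcel, 0.0, t, limit=200, points=[max(t - residence, 0.0)])
    return val


def model3_characteristics(
    t,
    kinetics: KineticsParams,
    k_a: float,
    gamma: float,
    input_mass: float,
    geometry: Geometry | None = None,
    l0: float | None = None,
    solute_molar_mass: float = 180.0,
    parcel_count: int = 500,
    rtol: float = 1e-8,
) -> np.ndarray | float:
    """Fraction absorbed for the starch model via a parcel ensemble.

    Each parcel enters at l0 with starch concentration
    gamma M_S(s) / (u A) (the plug-flow inlet concentration, in g/m^3)
    and is integrated along its characteristic; absorbed fractions are
    mass-weighted by the emptying curve.  Grid-free; converges as
    parcel_count grows.
    """
    if parcel_count < 100:
        raise DomainError(f"parcel_count must be >= 100, got {parcel_count!r}")
    L, u, A = _geometry_scalars(geometry)
    from .solver import DEFAULT_L0

    l0 = DEFAULT_L0 if l0 is None else l0
    residence = (L - l0) / u
    to_gm3 = solute_molar_mass * 1000.0
    vmax_c = kinetics.vmax * to_gm3  # g/m^3/s
    km_c = kinetics.km * to_gm3

    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _model3_scalar(
            ti, vmax_c, km_c, k_a, gamma, input_mass, u, A, residence,
            parcel_count, rtol,
        )
    return out if np.ndim(t) else float(out[0])


def _model3_scalar(t, vmax_c, km_c, k_a, gamma, input_mass, u, A, residence,
                   n_parcels, rtol) -> float:
    if t == 0.0 or gamma <= 0.0:
        return 0.0
    emptied = 1.0 - math.exp(-gamma * t)
    # entry times at the mid-quantiles of the emptied-mass distribution
    q = (np.arange(n_parcels) + 0.5) / n_parcels * emptied
    s = -np.log1p(-q) / gamma
    weight = emptied / n_parcels  # mass fraction per parcel
    c0 = gamma * input_mass * np.exp(-gamma * s) / (u * A)  # g/m^3
    duration = np.minimum(t - s, residence)

    # parcel-local time sigma in [0, 1]; y = [S(n), G(n), absorbed(n)]
    def rhs(_, y):
        S = np.maximum(y[:n_parcels], 0.0)
        G = np.maximum(y[n_parcels : 2 * n_parcels], 0.0)
        hyd = vmax_c * S / (km_c + S)
        dS = -hyd * duration
        dG = (hyd - k_a * G) * duration
        dAbs = k_a * G * duration
        return np.concatenate([dS, dG, dAbs])

    y0 = np.concatenate([c0, np.zeros(n_parcels), np.zeros(n_parcels)])
    sol = solve_ivp(rhs, (0.0, 1.0), y0, method="LSODA", rtol=rtol, atol=1e-12)
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"characteristics oracle failed: {sol.message}")
    absorbed = sol.y[2 * n_parcels :, -1]
    frac_per_parcel = absorbed / c0
    return float(np.sum(weight * frac_per_parcel))


def oracle_curve(method: str, times, **kwargs) -> OracleResult:
    """Evaluate one of the oracles on a time grid."""
    times = np.asarray(times, dtype=float)
    if method == "closed_form_m1":
        frac = model1_closed_form(times, **kwargs)
    elif method == "quadrature_m2":
        frac = model2_quadrature(times, **kwargs)
    elif method == "characteristics_m3":
        frac = model3_characteristics(times, **kwargs)
    else:
        raise DomainError(f"unknown oracle method {method!r}")
    return OracleResult(times=times, fraction_absorbed=np.asarray(frac), method=method)
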