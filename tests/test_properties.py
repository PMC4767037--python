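"""The viscosity -> diffusivity -> mass-transfer chain and the
characteristic-time calculators."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gutsim as g
from gutsim import DomainError

SETTINGS = dict(deadline=None, max_examples=50, derandomize=True)

viscosities = st.floats(min_value=1e-3, max_value=10.0)


def test_diffusivity_stokes_einstein_value(water, glucose):
    # hand evaluation of k_B T / (6 pi mu r0) at body temperature
    assert g.diffusivity(water, glucose) == pytest.approx(5.98e-10, rel=5e-3)
    honey = g.FluidProperties(viscosity=10.0)
    assert g.diffusivity(honey, glucose) == pytest.approx(5.98e-14, rel=5e-3)


@given(mu=viscosities)
@settings(**SETTINGS)
def test_diffusivity_inverse_in_viscosity(mu, glucose):
    lo = g.FluidProperties(viscosity=mu)
    hi = g.FluidProperties(viscosity=10.0 * mu)
    assert g.diffusivity(hi, glucose) == pytest.approx(
        g.diffusivity(lo, glucose) / 10.0, rel=1e-12
    )


def test_mass_transfer_coefficient_value(geometry, water, glucose):
    K = g.mass_transfer_coefficient(geometry, water, glucose)
    assert K == pytest.approx(1.36e-7, rel=5e-3)
    # watery chyme sits above the fast-absorption threshold
    assert K >= 1e-7


@given(mu=viscosities)
@settings(**SETTINGS)
def test_mass_transfer_viscosity_power_law(mu, geometry, glucose):
    """K mu^(2/3) is constant: the -2/3 viscosity exponent is exact."""
    K1 = g.mass_transfer_coefficient(geometry, g.FluidProperties(viscosity=mu), glucose)
    Kref = g.mass_transfer_coefficient(geometry, g.FluidProperties(viscosity=1e-3), glucose)
    assert K1 * mu ** (2.0 / 3.0) == pytest.approx(Kref * 1e-3 ** (2.0 / 3.0), rel=1e-12)


def test_mass_transfer_diameter_scaling(geometry, water, glucose):
    halved = geometry.with_diameter(geometry.diameter / 2.0)
    assert g.mass_transfer_coefficient(halved, water, glucose) == pytest.approx(
        2.0 ** (1.0 / 3.0) * g.mass_transfer_coefficient(geometry, water, glucose),
        rel=1e-12,
    )


def test_dimensionless_numbers(geometry, water, glucose):
    assert g.reynolds(geometry, water) == pytest.approx(6.12, rel=1e-3)
    assert g.schmidt(water, glucose) == pytest.approx(1.67e3, rel=5e-3)


@given(mu=viscosities)
@settings(**SETTINGS)
def test_sherwood_consistency(mu, geometry, glucose):
    """Sh D / d recovers K for every viscosity (definitional identity)."""
    fluid = g.FluidProperties(viscosity=mu)
    Sh = g.sherwood(geometry, fluid, glucose)
    D = g.diffusivity(fluid, glucose)
    assert Sh * D / geometry.diameter == pytest.approx(
        g.mass_transfer_coefficient(geometry, fluid, glucose), rel=1e-12
    )


@pytest.mark.parametrize(
    "half_time, expected",
    [(3600.0, 1.925e-4), (120.0, 5.78e-3)],
)
def test_gamma_from_half_time(half_time, expected):
    assert g.gamma_from_half_time(half_time) == pytest.approx(expected, rel=1e-3)


@given(ht=st.floats(min_value=60.0, max_value=7200.0))
@settings(**SETTINGS)
def test_gamma_half_time_round_trip(ht):
    assert g.half_time_from_gamma(g.gamma_from_half_time(ht)) == pytest.approx(ht, rel=1e-12)


def test_characteristic_times_defaults(geometry, water, glucose):
    groups = g.characteristic_times(geometry, water, glucose,
                                    g.EmptyingParams(half_time=3600.0))
    assert groups.tau_emptying == pytest.approx(3.2, abs=0.1)
    assert groups.tau_transfer == pytest.approx(3.0, abs=0.1)


def test_characteristic_times_no_emptying(geometry, water, glucose):
    groups = g.characteristic_times(geometry, water, glucose,
                                    g.EmptyingParams(gamma=0.0))
    assert groups.tau_emptying == 0.0


def test_km_normalisation_identity(geometry, water, glucose, amylase):
    groups = g.characteristic_times(geometry, water, glucose,
                                    g.EmptyingParams(half_time=3600.0),
                                    amylase, ref_conc=amylase.km)
    assert groups.km_scaled == pytest.approx(1.0, rel=1e-12)


def test_tau_transfer_scale_free(geometry, water, glucose):
    """tau_transfer never depends on how much glucose is fed (linearity)."""
    a = g.characteristic_times(geometry, water, glucose)
    b = g.characteristic_times(geometry, water, glucose)
    assert a.tau_transfer == b.tau_transfer  # pure, deterministic


def test_reference_concentration(glucose):
    # 50 g in 0.5 L of 180 g/mol solute -> 0.5556 mol/L
    assert g.reference_concentration(50.0, 0.5, glucose) == pytest.approx(0.5556, rel=1e-3)


@pytest.mark.parametrize(
    "ctor, kwargs, field",
    [
        (g.FluidProperties, {"viscosity": -1.0}, "viscosity"),
        (g.FluidProperties, {"viscosity": 1e3}, "viscosity"),
        (g.Geometry, {"length": 0.0}, "length"),
        (g.SoluteProperties, {"molecular_radius": 1e-7}, "molecular_radius"),
        (g.EmptyingParams, {"half_time": -60.0}, "half_time"),
    ],
)
def test_domain_errors_name_offending_field(ctor, kwargs, field):
    with pytest.raises(DomainError, match=field):
        ctor(**kwargs)


def test_missing_ref_conc_with_kinetics_raises(geometry, water, glucose, amylase):
    with pytest.raises(DomainError, match="ref_conc"):
        g.characteristic_times(geometry, water, glucose,
                               g.EmptyingParams(half_time=3600.0), amylase)


def test_kinetics_unit_ingest():
    k = g.KineticsParams.from_mM(9.0, 9.0)
    assert k.vmax == pytest.approx(1.5e-4, rel=1e-12)  # mol/L/s
    assert k.km == pytest.approx(9e-3, rel=1e-12)
    assert k.vmax_mM_per_min == pytest.approx(9.0, rel=1e-12)


def test_emptying_inconsistent_pair_rejected():
    with pytest.raises(DomainError, match="inconsistent"):
        g.EmptyingParams(gamma=1e-3, half_time=3600.0)


def test_geometry_default_diameter(geometry):
    assert geometry.diameter == pytest.approx(2 * geometry.radius)
    assert math.isfinite(geometry.residence_time) and geometry.residence_time > 0
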