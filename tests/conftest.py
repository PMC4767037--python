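import pytest

from gutsim import (
    EmptyingParams,
    FluidProperties,
    Geometry,
    GridSpec,
    KineticsParams,
    SoluteProperties,
)


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def water():
    return FluidProperties(viscosity=1e-3)


@pytest.fixture(scope="session")
def glucose():
    return SoluteProperties()


@pytest.fixture(scope="session")
def emptying_30min():
    return EmptyingParams(half_time=1800.0)


@pytest.fixture(scope="session")
def amylase():
    return KineticsParams.from_mM(9.0, 9.0)


@pytest.fixture(scope="session")
def default_grid():
    return GridSpec()
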