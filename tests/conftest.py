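import numpy as np
import pytest

from thermogate.parameters import (
    CouplingParams,
    GatingParameters,
    ThermoSensorParams,
    VoltageSensorParams,
)


def random_params(rng: np.random.Generator, extreme: bool = False) -> GatingParameters:
    """Draw a random but valid gating-parameter set.

    With ``extreme=True`` the draws deliberately push the underlying
    Boltzmann exponents to the ±hundreds range.
    """
    scale = 3.0 if not extreme else 80.0
    return GatingParameters(
        L=10.0 ** rng.uniform(-scale, scale),
        tsensor=ThermoSensorParams(
            dH=rng.uniform(-1, 1) * (150 if extreme else 100),
            dS=rng.uniform(-0.2, 0.5 if not extreme else 1.2),
        ),
        vsensor=VoltageSensorParams(
            K0=10.0 ** rng.uniform(-4, 1), z=rng.uniform(-3.5, 3.5)
        ),
        coupling=CouplingParams(
            D=10.0 ** rng.uniform(-scale, scale),
            E=10.0 ** rng.uniform(-scale, scale),
            dHc=rng.uniform(-1, 1) * (60 if extreme else 15),
            dSc=rng.uniform(-0.1, 0.1),
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def simple_params():
    """A moderate parameter set used across kinetics tests."""
    return GatingParameters(
        L=0.2,
        tsensor=ThermoSensorParams(dH=20.0, dS=0.065),
        vsensor=VoltageSensorParams(K0=0.01, z=0.9),
        coupling=CouplingParams(D=30.0, E=2.0, dHc=3.0, dSc=0.012),
    )
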