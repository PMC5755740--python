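import numpy as np
import pytest

from phenorisk import (
    ImmatureStage,
    PhenologyModel,
    TemperatureSeries,
    ThermalFunctionSpec,
    reference_models,
)


@pytest.fixture(scope="session")
def models():
    return reference_models()


@pytest.fixture(scope="session")
def viable_model(models):
    return models["synthetic_viable"]


@pytest.fixture
def const25():
    return TemperatureSeries.constant(25.0)


def make_simple_model(
    rate=0.1,
    mortality_b=(-50.0, 0.0, 1e-9),
    senescence=0.05,
    ovip=("ovip_logistic", {"a": 2.0, "b": -4.0}),
    fecundity=("fecundity_exppoly", {"b1": 4.0, "b2": 0.0, "b3": 0.0}),
    devtime_slope=np.inf,
    adult_slope=np.inf,
):
    """A minimal model with the same constant development rate ``rate`` per
    stage at 25 °C, configurable mortality and reproduction; handy for
    closed-form checks."""
    a = rate / (25.0 * 15.0 * np.sqrt(10.0))  # r(25) == rate with (10, 35)
    dev = ThermalFunctionSpec("briere1", {"a": a, "Tmin": 10.0, "Tmax": 35.0})
    b1, b2, b3 = mortality_b
    mort = ThermalFunctionSpec("mortality_expquad", {"b1": b1, "b2": b2, "b3": b3})
    stages = [
        ImmatureStage(name, dev, devtime_slope, mort)
        for name in ("egg", "larva", "pupa")
    ]
    sen = ThermalFunctionSpec("senescence_exponential", {"b1": senescence, "b2": 0.0})
    return PhenologyModel(
        stages=stages,
        senescence_female=sen,
        senescence_male=sen,
        fecundity=ThermalFunctionSpec(*fecundity),
        oviposition=ThermalFunctionSpec(*ovip),
        adult_slope=adult_slope,
    )


@pytest.fixture
def simple_model():
    return make_simple_model()
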