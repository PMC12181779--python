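import pytest

from co2loop import GasPlantParams, NdirSensorParams


@pytest.fixture
def reference_plant() -> GasPlantParams:
    """55 L incubator, pure-CO2 feed at 0.012 L/s, slow room exchange."""
    return GasPlantParams()


@pytest.fixture
def ideal_sensor() -> NdirSensorParams:
    """Lag-free, noise-free sensor for tests that isolate other components."""
    return NdirSensorParams(t90_s=0.0, min_read_interval_ms=0.0)
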