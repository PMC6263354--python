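import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def batch():
    """Default synthetic batch fermentation (27 h)."""
    from fermlogic.synth import BatchParams, simulate_batch

    return simulate_batch(BatchParams())


@pytest.fixture(scope="session")
def sensor_wires(batch):
    """Calibrated sensor RPU time courses driven by the default batch."""
    from fermlogic.sensors import (
        DEFAULT_CALIBRATION,
        acetate_sensor,
        glucose_sensor,
        low_oxygen_sensor,
    )
    from fermlogic.synth import sensor_outputs_from_batch

    return sensor_outputs_from_batch(
        [glucose_sensor(), low_oxygen_sensor(), acetate_sensor()],
        batch,
        DEFAULT_CALIBRATION,
    )


@pytest.fixture(scope="session")
def default_library():
    """The shipped default promoter library (built once per session)."""
    from fermlogic.promoters import build_library, default_design_spec

    spec = default_design_spec(seed=7)
    members, summary = build_library(spec)
    return spec, members, summary


@pytest.fixture
def rng():
    return np.random.default_rng(0)
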