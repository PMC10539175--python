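import pytest
from hypothesis import HealthCheck, settings

import graftdose as gd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def plateau_cohort():
    """Default synthetic cohort: plateau (no-threshold) scenario, n=619."""
    cfg = gd.SimulationConfig(n=619, seed=11)
    return gd.add_dose_columns(gd.simulate_cohort(cfg))


@pytest.fixture(scope="session")
def flat_cohort():
    """Null cohort: dose carries no signal, n=619."""
    cfg = gd.SimulationConfig(n=619, seed=12, scenario=gd.ScenarioCurve(kind="flat"))
    return gd.add_dose_columns(gd.simulate_cohort(cfg))
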