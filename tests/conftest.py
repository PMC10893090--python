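import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def water_like():
    from spherodrop import LiquidProperties

    return LiquidProperties(density=1000.0, surface_tension=0.058, viscosity=0.9e-3)


@pytest.fixture
def default_rotor():
    from spherodrop import RotorConfig

    return RotorConfig(rotor_radius=0.15, rcf=25.0)


@pytest.fixture
def well_opening_pose():
    from spherodrop import PlatePose

    return PlatePose.from_gap_mm(0.8)
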