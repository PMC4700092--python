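import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_pair():
    """Default geometry plus ideal-background kinetics (session-wide)."""
    from mibgkit import default_phantom

    return default_phantom()


@pytest.fixture(scope="session")
def calibrated(phantom_pair):
    """Kinetics calibrated to the late H/M targets 1.60/1.56/1.53/1.52."""
    from mibgkit import calibrate_to_hm_targets

    geometry, kinetics = phantom_pair
    return calibrate_to_hm_targets(
        {60.0: 1.60, 120.0: 1.56, 180.0: 1.53, 240.0: 1.52}, geometry, kinetics
    )
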