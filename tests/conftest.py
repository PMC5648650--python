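import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def models():
    import treestrike as ts

    return ts.species_models()


@pytest.fixture(scope="session")
def reference():
    import treestrike as ts

    return ts.load_reference_energetics()


@pytest.fixture(scope="session")
def constants():
    import treestrike as ts

    return ts.default_constants()


@pytest.fixture(scope="session")
def liana_calibration():
    import treestrike as ts

    return ts.calibrate_liana_resistances()


@pytest.fixture(scope="session")
def reference_stem():
    from treestrike import build_tapered_stem, registry

    return build_tapered_stem(
        registry.REFERENCE_HEIGHT_M,
        registry.REFERENCE_BASAL_DIAMETER_M,
        registry.TOP_DIAMETER_M,
        registry.SEGMENT_LENGTH_M,
    )
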