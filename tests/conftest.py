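import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_catalog():
    from hypermut.synthetic_fixture import evolved_strain_catalog

    return evolved_strain_catalog()


@pytest.fixture(scope="session")
def reference_annotation():
    from hypermut.synthetic_fixture import synthetic_reference

    return synthetic_reference()


@pytest.fixture(scope="session")
def small_toy_genome():
    from hypermut.synthgen import toy_genome

    return toy_genome(length=120_000, seed=99)
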