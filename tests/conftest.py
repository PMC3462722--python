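import pytest
from hypothesis import HealthCheck, settings

from xenomir import datasets, make_toy_catalog

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def species_meta():
    return datasets.species_meta()


@pytest.fixture(scope="session")
def mir168_catalog():
    """The two miR168 variants under 3 monocot and 3 dicot species."""
    return datasets.mir168_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Random 100-ish record catalog with the mandated miR168 variants."""
    return make_toy_catalog(n_animal_families=48, n_plant_families=48, seed=11)


@pytest.fixture(scope="session")
def library_table():
    return datasets.public_library_table()
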