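import pytest

from scavkin import dataset as ds
from scavkin.synthetic import GeneratorSpec, generate


@pytest.fixture(scope="session")
def fixture():
    """The bundled reference dataset (checksummed, calibrated at load)."""
    return ds.load_fixture()


@pytest.fixture(scope="session")
def reproduction(fixture):
    """Reproduction diff of the published rate tables."""
    return ds.reproduce_tables(fixture)


@pytest.fixture(scope="session")
def synthetic_large():
    """~1000-channel seeded synthetic dataset with oracle ground truth."""
    return generate(GeneratorSpec(seed=1234, n_antioxidants=20))


@pytest.fixture(scope="session")
def synthetic_small():
    return generate(GeneratorSpec(seed=7, n_antioxidants=2))
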