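import pytest

from gqdsense.fixtures import reference_fixture_set
from gqdsense.synthetic import GeneratorSpec, generate_sensor_set


@pytest.fixture(scope="session")
def golden():
    """The bundled printed-table fixture set."""
    return reference_fixture_set()


@pytest.fixture(scope="session")
def synthetic_set():
    """A moderate noiseless synthetic study, shared across tests."""
    return generate_sensor_set(GeneratorSpec(seed=7, n_systems=20))
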