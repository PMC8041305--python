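import pytest
from hypothesis import settings

from patchyllps import ProteinModel, buffer_fixtures, hewl_model

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hewl() -> ProteinModel:
    """Packaged HEWL geometry: sigma=3.43 nm, omega=0.18 nm, M=10, M2=14300."""
    return hewl_model()


@pytest.fixture(scope="session")
def buffers():
    """Packaged buffer parameter sets keyed by name."""
    return {b.name: b for b in buffer_fixtures()}
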