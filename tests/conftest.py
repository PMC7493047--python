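import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from lampspk.geometry import AssayGeometry, load_bundled_config
from lampspk.rules import KineticParams


@pytest.fixture(scope="session")
def geometry() -> AssayGeometry:
    return AssayGeometry()


@pytest.fixture(scope="session")
def params() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def reference():
    """(geometry, params, payload) of the bundled reference assay config."""
    payload = load_bundled_config("reference")
    return (
        AssayGeometry.from_dict(payload["geometry"]),
        KineticParams.from_dict(payload["params"]),
        payload,
    )
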