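import pytest
from hypothesis import settings

from capetwin import load_parameters

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bundle():
    """Shipped defaults; treat as read-only (copy before mutating)."""
    return load_parameters()


@pytest.fixture()
def fresh_bundle(bundle):
    return bundle.copy()
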