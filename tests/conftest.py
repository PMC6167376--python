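import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from reamp.bundle import build_bundle
from reamp.design import default_construct


@pytest.fixture(scope="session")
def protein():
    """The default designed construct (V5 epitope, His10 tag, W50)."""
    return default_construct()


@pytest.fixture(scope="session")
def bundle(protein):
    """The default idealized four-helix bundle."""
    return build_bundle(protein=protein)
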