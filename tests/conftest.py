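import pytest
from hypothesis import settings

from iddi.integration import build_gsp, integrate
from iddi.synthgen import simulate_corpus

from _util import small_spec

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """A miniature synthetic corpus shared across tests (seed-fixed)."""
    return simulate_corpus(small_spec(seed=42))


@pytest.fixture(scope="session")
def small_integration(small_corpus):
    """The integrated table of the miniature corpus."""
    return integrate(small_corpus.predicted, build_gsp(small_corpus.structural))
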