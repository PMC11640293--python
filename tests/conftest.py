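import numpy as np
import pytest

from altprot_curator import fixtures as fx
from altprot_curator import merge_databases


@pytest.fixture(scope="session")
def fixture_spec():
    return fx.FixtureSpec(seed=0)


@pytest.fixture(scope="session")
def proteome(fixture_spec):
    return fx.make_proteome(fixture_spec)


@pytest.fixture(scope="session")
def database(proteome):
    return merge_databases(
        proteome.canonical, proteome.altprot, proteome.contaminants
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
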