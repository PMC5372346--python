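import numpy as np
import pytest

from amst import (
    foreground_mask,
    render_phantom,
    standard_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    return standard_fixtures(seed=0)


@pytest.fixture(scope="session")
def phantoms(fixtures):
    """name -> (Volume, truth SWCTree), rendered once per session."""
    return {name: render_phantom(spec) for name, spec in fixtures.items()}


@pytest.fixture(scope="session")
def masks(phantoms):
    """name -> ForegroundMask at default binarization thresholds."""
    return {name: foreground_mask(vol) for name, (vol, _) in phantoms.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
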