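import numpy as np
import pytest

from ctisim import build_default_atlas, build_sigma_h


@pytest.fixture(scope="session")
def atlas():
    """Default 64^3 phantom atlas (shared; treated as read-only)."""
    return build_default_atlas((64, 64, 64))


@pytest.fixture(scope="session")
def sigma_h(atlas):
    return build_sigma_h(atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
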