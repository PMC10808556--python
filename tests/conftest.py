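"""Shared fixtures: phantom data generated on the fly, nothing stored on disk."""

import numpy as np
import pytest

from slicemapper import PhantomSpec, make_phantom_atlas

# The standard study conditions: 60-slice template, 96x96 px at 25 µm
# in-plane, 100 µm slice thickness.
STUDY_SPEC = PhantomSpec(N=60, shape=(96, 96), pixel_size=25.0, e_t=100.0,
                         seed=1)


@pytest.fixture(scope="session")
def atlas60():
    """Full-size phantom atlas used by the acceptance batteries."""
    return make_phantom_atlas(STUDY_SPEC)


@pytest.fixture(scope="session")
def atlas_small():
    """A small, fast atlas for unit tests."""
    return make_phantom_atlas(PhantomSpec(N=20, shape=(64, 64), seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
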