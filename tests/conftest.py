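import numpy as np
import pytest

from critb.geodesy import LocalProjection
from critb.occ_io import taxa_from_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20121)


@pytest.fixture
def equator_proj():
    """Local equal-area frame centred on the equator/prime-meridian corner of
    the test region; planar km coordinates map back through `inverse`."""
    return LocalProjection(0.0, 25.0)


def latlon_from_km(xy, proj=None):
    """Convert planar-km test coordinates to (lat, lon) via a local frame."""
    proj = proj or LocalProjection(0.0, 25.0)
    return proj.inverse(np.atleast_2d(xy))


@pytest.fixture
def make_taxa():
    return taxa_from_frame
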