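import numpy as np
import pytest

from pmsurface import sabzevar_fixture
from pmsurface.geostat import VariogramModel


@pytest.fixture(scope="session")
def sabzevar():
    return sabzevar_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160401)


@pytest.fixture()
def scattered(rng):
    """A small generic scattered layout: 8 points, positive values."""
    locations = rng.uniform(0.0, 1000.0, size=(8, 2))
    values = rng.uniform(20.0, 120.0, size=8)
    return locations, values


@pytest.fixture()
def gaussian_variogram():
    return VariogramModel("gaussian", nugget=0.0, partial_sill=1.0, range_=300.0)
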