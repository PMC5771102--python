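import warnings

import numpy as np
import pytest

import cryovessel as cv


@pytest.fixture(scope="session")
def props():
    return cv.MaterialProperties()


@pytest.fixture(scope="session")
def default_geometry():
    return cv.build_geometry(cv.BifurcationParams())


@pytest.fixture(scope="session")
def probe_geometry():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cv.build_geometry(cv.BifurcationParams(),
                                 [cv.ProbeSpec.horizontal(20.0)])


@pytest.fixture(scope="session")
def desk_grid(probe_geometry):
    return cv.voxelize(probe_geometry, 2.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
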