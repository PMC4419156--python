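import numpy as np
import pytest

from floodmmi import (
    CategoricalRaster,
    SyntheticLandscapeConfig,
    generate_landscape,
    landuse_scheme,
)


@pytest.fixture(scope="session")
def landuse():
    return landuse_scheme()


@pytest.fixture(scope="session")
def patchy_landscape():
    """128x128 five-class landscape with contiguous patches (group codes)."""
    return generate_landscape(SyntheticLandscapeConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def raster_from_rows(rows, nodata=-9999):
    return CategoricalRaster(np.array(rows, dtype=np.int32), nodata=nodata)
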