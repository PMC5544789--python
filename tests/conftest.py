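import numpy as np
import pytest

from lucsim.grids import GridMap, LandCover
from lucsim.synth import SynthConfig, generate_landscape


def make_grid(values, role="landcover", cell_size=30.0, nodata=-9999):
    values = np.asarray(values, dtype=np.int64)
    return GridMap(
        values,
        cell_size=cell_size,
        origin=(0.0, values.shape[0] * cell_size),
        nodata=nodata,
        role=role,
    )


def uniform_landcover(n_rows, n_cols, code=LandCover.FOREST, **kw):
    return make_grid(np.full((n_rows, n_cols), int(code)), **kw)


@pytest.fixture(scope="session")
def small_land():
    """One 80x80 synthetic study area shared by read-only tests."""
    return generate_landscape(SynthConfig(n_rows=80, n_cols=80, seed=3))


@pytest.fixture(scope="session")
def medium_land():
    """160x160 study area for allocation/scenario tests needing room."""
    return generate_landscape(SynthConfig(n_rows=160, n_cols=160, seed=11))
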