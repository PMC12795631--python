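import numpy as np
import pytest

from plateausdm import GridRaster, RunConfig, align_stack, generate_env_stack


@pytest.fixture
def small_stack():
    """Two continuous layers + LUCC on a 40x40 grid, fixed seed."""
    return generate_env_stack((40, 40), ["Bio12", "ELE", "LUCC"], 4.0, seed=11)


@pytest.fixture
def cont_stack():
    """Continuous-only stack for correlation / fitting tests."""
    return generate_env_stack((40, 40), ["Bio12", "ELE"], 4.0, seed=11)


@pytest.fixture
def fast_config():
    return RunConfig(random_seed=1, background_n=800, replicates=3)


def make_raster(values, mask=None, **kw):
    values = np.asarray(values)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    kw.setdefault("origin_y", values.shape[0] * kw.get("cell_size", 1.0))
    return GridRaster(values=values, nodata_mask=np.asarray(mask, dtype=bool), **kw)


@pytest.fixture
def make_grid():
    return make_raster
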