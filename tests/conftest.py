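import numpy as np
import pytest

import hypercell as hc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_cube(rng):
    """A small random cube for window/distance oracles."""
    return hc.HSCube(rng.uniform(0.0, 100.0, size=(7, 7, 4)))


@pytest.fixture
def zero_noise_cube():
    """Noiseless labeled cube: every pixel equals its class signature."""
    params = hc.SynthParams(
        height=32, width=32, n_cells=5, cell_axes_range=(3.0, 6.0),
        noise_sd=0.0, seed=11,
    )
    cube, mask = hc.generate_cube(params)
    return params, cube, mask


@pytest.fixture
def easy_task_cube():
    params = hc.task_params(
        "easy", seed=21, height=40, width=40, n_cells=6, cell_axes_range=(3.0, 6.0)
    )
    cube, mask = hc.generate_cube(params)
    return params, cube, mask


@pytest.fixture
def fast_config():
    return hc.PipelineConfig(ws=5, k_ssn=0, epochs=15, seed=0)
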