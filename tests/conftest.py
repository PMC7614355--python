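import numpy as np
import pytest

from metareg.core_spatial import Volume
from metareg.synthetic_data import GeneratorParams, generate_task

SMALL_GRID = (16, 16, 16)


@pytest.fixture(scope="session")
def small_params() -> GeneratorParams:
    return GeneratorParams(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def small_task(small_params):
    return generate_task(7, small_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def blob_volume():
    """A centred soft blob label on an 8^3 grid."""
    idx = np.indices((8, 8, 8), dtype=float)
    d2 = sum((idx[a] - 3.5) ** 2 for a in range(3))
    return Volume(np.exp(-d2 / 6.0), spacing_mm=1.0, is_label=True)
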