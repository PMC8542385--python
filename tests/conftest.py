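import numpy as np
import pytest

from aggscreen import GenerationConfig, generate_reporter_field

# A small, fast field for unit tests: sparse enough to segment trivially,
# dense enough to leave interior (analyzable) regions.
SMALL = GenerationConfig(
    image_height=224, image_width=224, n_cells=20, cell_radius_mean=22.0, seed=7
)


@pytest.fixture(scope="session")
def small_field():
    return generate_reporter_field(SMALL)


@pytest.fixture(scope="session")
def default_field():
    return generate_reporter_field(GenerationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
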