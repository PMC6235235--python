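import numpy as np
import pytest

from larvalight import VoxelGrid
from larvalight.synthetic import cohort_stack_recipe

INSTRUMENT_SPACING = (2.5, 0.325, 0.325)

# study-condition stack used throughout the segmentation suites
separated_blob_recipe = cohort_stack_recipe


@pytest.fixture
def tiny_grid() -> VoxelGrid:
    data = np.zeros((3, 3, 3))
    data[1, 1, 1] = 10.0
    return VoxelGrid(data, (1.0, 1.0, 1.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
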