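import numpy as np
import pytest

from mptrans.phantom import PhantomConfig
from mptrans.stacks import ImageStack


@pytest.fixture
def desk_config():
    """Small phantom geometry used throughout the suite."""
    return PhantomConfig(
        matrix_size=64,
        lv_length_mm=38.4,
        endo_radius_mm=12.0,
        epi_radius_mm=20.0,
        baseline_uptake=80.0,
    )


@pytest.fixture
def uniform_stack():
    """8-slice stack of constant uptake 50."""
    return ImageStack(
        voxels=np.full((8, 32, 32), 50.0),
        pixel_mm=2.4,
        slice_mm=2.4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
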