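import numpy as np
import pytest

from c3morph import PhantomSpec, generate_neck_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Default-geometry phantom with a short stack; shared read-only."""
    return generate_neck_phantom(PhantomSpec(seed=1, n_slices=16, mid_c3_index=8))


@pytest.fixture(scope="session")
def default_phantom():
    """The documented example phantom: seed 1, 40 slices, mid-C3 at 20, 38 cm²."""
    return generate_neck_phantom(
        PhantomSpec(seed=1, n_slices=40, mid_c3_index=20, muscle_area_target=38.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
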