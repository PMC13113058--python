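import numpy as np
import pytest

from pvlkit.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One desk-scale phantom reused by read-only tests."""
    return generate_phantom(
        PhantomParams.desk_scale(target_calc_volume=600.0, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
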