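import numpy as np
import pytest

from ifmtl import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """20 sharp cases (5 per class) at 32 px — cheap shared fixture."""
    return generate_dataset(SynthSpec(n_per_class=5, image_size=32, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
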