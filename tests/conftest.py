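import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny well-separated phantom dataset shared by mechanical tests."""
    from slicegru.synthetic import PhantomSpec, generate_dataset

    spec = PhantomSpec(shape=(32, 32, 32), n_per_class=6, effect_size=1.0, noise_sd=0.2,
                       region_radii=(5, 5, 5), jitter=1, seed=99)
    return generate_dataset(spec)
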