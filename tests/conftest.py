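import numpy as np
import pytest

from nwuct import CohortSpec, PhantomSpec, generate_cohort, generate_phantom

SMALL_SHAPE = (6, 192, 192)


def make_phantom(w=0.0, noise=0.0, seed=None, shape=SMALL_SHAPE, **kwargs):
    spec = PhantomSpec(
        image_shape=shape,
        noise_sigma=noise,
        water_uptake_w=w,
        lesion_slice_range=(0, shape[0]),
        seed=seed,
        **kwargs,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Noise-free, lesion-free (w=0) head: exactly mirror-symmetric."""
    return make_phantom(w=0.0, noise=0.0)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Noise-free phantom with true uptake w = 0.2."""
    return make_phantom(w=0.2, noise=0.0)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Noise-SD-2 phantom with true uptake w = 0.182."""
    return make_phantom(w=0.182, noise=2.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but two-class cohort for fast model tests."""
    spec = CohortSpec(n_mce=8, n_non_mce=12, seed=11)
    return generate_cohort(spec)
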