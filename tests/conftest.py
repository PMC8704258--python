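import numpy as np
import pytest
from hypothesis import settings

from rededgecal import RadiometricTags, Scenario, default_scene

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


def make_tags(
    width=64,
    height=48,
    a1=2.0,
    a2=0.0,
    a3=0.0,
    te=1e-3,
    g=1.0,
    black=4096.0,
    k=(0.0,) * 6,
    center=None,
) -> RadiometricTags:
    if center is None:
        center = ((width - 1) / 2.0, (height - 1) / 2.0)
    return RadiometricTags(
        a1=a1, a2=a2, a3=a3, te=te, g=g, dn_black_level=black,
        vignette_center=center, vignette_coeffs=k,
    )


@pytest.fixture
def tags():
    return make_tags()


@pytest.fixture
def scene():
    return default_scene(96, 72)


@pytest.fixture
def noise_free_sunny():
    """Stationary sunny illumination, no read noise: the exact-recovery regime."""
    return Scenario(name="sunny", seed=7, noise_dn=0.0,
                    irradiance_profile=lambda t: 1.8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
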