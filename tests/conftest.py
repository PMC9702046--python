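import math

import numpy as np
import pytest

from dwiadc import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small, noisy cohort: fast enough for end-to-end tests."""
    return PhantomConfig(
        n_responders=6,
        n_poor=3,
        volume_shape=(16, 16, 16),
        lesion_radius_vox=3,
        seed=7,
    )


@pytest.fixture
def noiseless_config():
    """Noise-free, perfusion-free phantom with homogeneous lesion D and a
    fixed treatment effect: every fitted quantity is exact."""
    return PhantomConfig(
        n_responders=2,
        n_poor=1,
        volume_shape=(16, 16, 16),
        lesion_radius_vox=3,
        perfusion_fraction=0.0,
        voxel_D_cv=0.0,
        response_effect=0.25,
        poor_effect=0.10,
        response_effect_sd=0.0,
        poor_effect_sd=0.0,
        snr=math.inf,
        seed=3,
    )
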