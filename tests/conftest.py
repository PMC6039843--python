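import numpy as np
import pytest

from svdstrat.io_core import Volume
from svdstrat.synthetic import EffectSpec, make_atlas, make_template


@pytest.fixture(scope="session")
def atlas():
    return make_atlas()


@pytest.fixture(scope="session")
def template(atlas):
    return make_template(atlas)


@pytest.fixture
def noiseless_effects():
    """Effect spec with every stochastic imaging component switched off."""
    return EffectSpec(noise_sd=0.0, subject_scale_sd=0.0,
                      jacobian_noise_sd=0.0, divergence_noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_volume(data, voxel_size_mm=2.0):
    return Volume(np.asarray(data, dtype=float), voxel_size_mm)
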