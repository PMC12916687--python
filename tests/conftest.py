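import numpy as np
import pytest

from msgm.features import SegmentationConfig
from msgm.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_sim_cfg():
    """Smallest dataset that still exercises two scales and LOSO."""
    return SimConfig(n_subjects=3, trials_per_subject=2, c=6, fs=128,
                     duration_s=24, effect_size=1.0,
                     region_map=(0, 0, 0, 1, 1, 1), within_region_corr=0.6,
                     seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_sim_cfg):
    return generate_dataset(tiny_sim_cfg)


@pytest.fixture(scope="session")
def two_scale_seg_cfg():
    return SegmentationConfig(l_s=20.0, s_s=4.0, scales=((4.0, 2.0), (8.0, 4.0)))
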